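"""Segmented recurrent-CNV loci and locus-level genotype assignment.

Recurrent CNVs arise by non-allelic homologous recombination between
segmental-duplication clusters, so carriers of the "same" allele share
approximately the same breakpoints.  A hotspot is modelled as an ordered run
of breakpoint segments (a single segment for simple loci; A-B .. G-H for a
22q11.2-like locus), and each testable allele is a contiguous span of
segments.  A sample is genotyped at a span from its raw interval calls: the
span is positive for a state (DEL or DUP) when the merged calls of that state
cover at least ``min_fraction`` of every segment in the span while covering
no flanking segment to that threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEL = "DEL"
DUP = "DUP"
REF = "REF"
NO_CALL = "NO_CALL"

STATES = (DEL, DUP)
GENOTYPE_VALUES = (DEL, DUP, REF, NO_CALL)

DEFAULT_MIN_FRACTION = 0.5


@dataclass(frozen=True)
class Segment:
    """A breakpoint-delimited sub-interval of a hotspot (0-based, half-open)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.name}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlleleSpan:
    """A contiguous run of segments defining one testable allele span."""

    name: str
    segments: tuple[str, ...]
    flanking: tuple[str, ...] = ()


@dataclass(frozen=True)
class SegmentedLocus:
    locus_id: str
    chrom: str
    segments: tuple[Segment, ...]
    spans: tuple[AlleleSpan, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.locus_id}: duplicate segment names")
        ordered = sorted(self.segments, key=lambda s: s.start)
        if list(ordered) != list(self.segments):
            raise ValueError(f"{self.locus_id}: segments not ordered by start")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.locus_id}: segments {a.name} and {b.name} overlap"
                )
        by_name = {s.name: i for i, s in enumerate(self.segments)}
        for span in self.spans:
            idx = []
            for seg in span.segments:
                if seg not in by_name:
                    raise ValueError(
                        f"{self.locus_id}: span {span.name} names unknown segment {seg}"
                    )
                idx.append(by_name[seg])
            if idx != list(range(idx[0], idx[0] + len(idx))):
                raise ValueError(
                    f"{self.locus_id}: span {span.name} is not a contiguous run"
                )
            overlap = set(span.segments) & set(span.flanking)
            if overlap:
                raise ValueError(
                    f"{self.locus_id}: span {span.name} flanking overlaps span: {overlap}"
                )
            for seg in span.flanking:
                if seg not in by_name:
                    raise ValueError(
                        f"{self.locus_id}: span {span.name} flanking names unknown "
                        f"segment {seg}"
                    )

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def span(self, name: str) -> AlleleSpan:
        for s in self.spans:
            if s.name == name:
                return s
        raise KeyError(f"{self.locus_id}: unknown span {name!r}")


@dataclass(frozen=True)
class CnvCall:
    """One raw CNV call interval (BED semantics, 0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"call {self.sample_id}: start >= end")
        if self.state not in STATES:
            raise ValueError(f"call state must be DEL or DUP, got {self.state!r}")


@dataclass(frozen=True)
class CnvGenotype:
    sample_id: str
    locus_id: str
    span_name: str
    call: str

    def __post_init__(self) -> None:
        if self.call not in GENOTYPE_VALUES:
            raise ValueError(f"invalid genotype call {self.call!r}")


# ---------------------------------------------------------------------------
# catalog i/o


def _parse_locus(entry: dict, one_based: bool) -> SegmentedLocus:
    off = 1 if one_based else 0
    segments = tuple(
        Segment(
            name=s["name"],
            chrom=entry["chrom"],
            start=int(s["start"]) - off,
            end=int(s["end"]),
        )
        for s in entry["segments"]
    )
    spans = tuple(
        AlleleSpan(
            name=sp["name"],
            segments=tuple(sp["segments"]),
            flanking=tuple(sp.get("flanking", ())),
        )
        for sp in entry["spans"]
    )
    return SegmentedLocus(
        locus_id=entry["locus_id"], chrom=entry["chrom"], segments=segments, spans=spans
    )


def load_catalog(path=None, one_based: bool = False) -> list[SegmentedLocus]:
    """Load a recurrent-locus catalog.

    Parameters
    ----------
    path
        JSON catalog file.  ``None`` loads the packaged default catalog
        (synthetic-coordinate stand-in for a published recurrent-CNV list).
    one_based
        If True, catalog coordinates are 1-based inclusive and are converted
        to 0-based half-open on read.
    """
    if path is None:
        text = (
            resources.files("cnvdose.data")
            .joinpath("catalog_default_synthetic.json")
            .read_text()
        )
        raw = json.loads(text)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    loci = [_parse_locus(entry, one_based) for entry in raw["loci"]]
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus_id in catalog")
    return loci


def enumerate_alleles(catalog: Iterable[SegmentedLocus]) -> list[tuple[str, str, str]]:
    """Deterministic ordered enumeration of (locus_id, span_name, state) alleles."""
    out = []
    for locus in catalog:
        for span in locus.spans:
            for state in STATES:
                out.append((locus.locus_id, span.name, state))
    return out


# ---------------------------------------------------------------------------
# genotype assignment


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def segment_overlap_fraction(call: CnvCall, segment: Segment) -> float:
    """Fraction of the target segment covered by the call (0 if chrom differs)."""
    if call.chrom != segment.chrom:
        return 0.0
    ov = min(call.end, segment.end) - max(call.start, segment.start)
    return max(ov, 0) / segment.length


def _coverage_fraction(merged: Sequence[tuple[int, int]], segment: Segment) -> float:
    cov = 0
    for s, e in merged:
        cov += max(0, min(e, segment.end) - max(s, segment.start))
    return cov / segment.length


def _span_positive(
    merged: Sequence[tuple[int, int]],
    locus: SegmentedLocus,
    span: AlleleSpan,
    min_fraction: float,
    overlap_mode: str,
) -> bool:
    if overlap_mode == "target":
        for seg in span.segments:
            if _coverage_fraction(merged, locus.segment(seg)) < min_fraction:
                return False
    elif overlap_mode == "call":
        # bedtools -f semantics: fraction is of the call; require that some
        # merged call interval devotes >= min_fraction of itself to each
        # target segment.
        for seg in span.segments:
            segment = locus.segment(seg)
            ok = False
            for s, e in merged:
                ov = max(0, min(e, segment.end) - max(s, segment.start))
                if ov / (e - s) >= min_fraction:
                    ok = True
                    break
            if not ok:
                return False
    else:
        raise ValueError(f"overlap_mode must be 'target' or 'call', got {overlap_mode!r}")
    for seg in span.flanking:
        if _coverage_fraction(merged, locus.segment(seg)) >= min_fraction:
            return False
    return True


def assign_genotype(
    calls_for_sample: Sequence[CnvCall],
    locus: SegmentedLocus,
    span_name: str,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    overlap_mode: str = "target",
) -> CnvGenotype:
    """Assign one sample's genotype at one allele span.

    Same-state calls are merged (union) first so fragmented caller output is
    not penalized.  A span is state-positive iff every span segment reaches
    ``min_fraction`` coverage and no flanking segment does.  Conflicting DEL
    and DUP positivity yields NO_CALL.
    """
    span = locus.span(span_name)
    sample_ids = {c.sample_id for c in calls_for_sample}
    if len(sample_ids) > 1:
        raise ValueError(f"calls from multiple samples: {sorted(sample_ids)}")
    sample_id = next(iter(sample_ids)) if sample_ids else ""

    positive = {}
    for state in STATES:
        merged = merge_intervals(
            [
                (c.start, c.end)
                for c in calls_for_sample
                if c.state == state and c.chrom == locus.chrom
            ]
        )
        positive[state] = _span_positive(merged, locus, span, min_fraction, overlap_mode)

    if positive[DEL] and positive[DUP]:
        log.warning(
            "sample %s: DEL and DUP both positive at %s %s -> NO_CALL",
            sample_id, locus.locus_id, span_name,
        )
        call = NO_CALL
    elif positive[DEL]:
        call = DEL
    elif positive[DUP]:
        call = DUP
    else:
        call = REF
    return CnvGenotype(sample_id, locus.locus_id, span_name, call)


def genotype_matrix(
    callset: Iterable[CnvCall],
    catalog: Iterable[SegmentedLocus],
    sample_ids: Sequence[str] | None = None,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    overlap_mode: str = "target",
) -> pd.DataFrame:
    """Genotype every sample at every allele span of the catalog.

    Returns a long-format DataFrame (sample_id, locus_id, span, call) with one
    row per sample x span, REF where no calls are near a locus.  Output is
    invariant to the ordering of the input callset.
    """
    callset = list(callset)
    by_sample: dict[str, list[CnvCall]] = {}
    for c in callset:
        by_sample.setdefault(c.sample_id, []).append(c)
    if sample_ids is None:
        samples = sorted(by_sample)
    else:
        samples = list(sample_ids)
    catalog = list(catalog)
    span_keys = [(l, sp) for l in catalog for sp in l.spans]
    n, m = len(samples), len(span_keys)
    # samples without any call are REF everywhere; genotype only the rest
    sid_arr = np.repeat(np.asarray(samples, dtype=object), m)
    locus_arr = np.tile(np.array([l.locus_id for l, _ in span_keys], dtype=object), n)
    span_arr = np.tile(np.array([sp.name for _, sp in span_keys], dtype=object), n)
    call_arr = np.full(n * m, REF, dtype=object)
    pos = {sid: i for i, sid in enumerate(samples)}
    for sid, calls in by_sample.items():
        if sid not in pos:
            continue
        base = pos[sid] * m
        chroms = {c.chrom for c in calls}
        for j, (locus, span) in enumerate(span_keys):
            if locus.chrom not in chroms:
                continue
            gt = assign_genotype(
                calls, locus, span.name,
                min_fraction=min_fraction, overlap_mode=overlap_mode,
            )
            call_arr[base + j] = gt.call
    return pd.DataFrame(
        {"sample_id": sid_arr, "locus_id": locus_arr, "span": span_arr,
         "call": call_arr}
    )


# ---------------------------------------------------------------------------
# file dialects


CALL_COLUMNS = ["chrom", "start", "end", "sample_id", "state", "quality"]


def read_calls(path) -> list[CnvCall]:
    """Read BED-like TSV calls (chrom, start, end, sample_id, state, quality)."""
    df = pd.read_csv(path, sep="\t", header=None, names=CALL_COLUMNS, comment="#")
    calls = []
    for row in df.itertuples(index=False):
        q = None if pd.isna(row.quality) else float(row.quality)
        calls.append(
            CnvCall(str(row.sample_id), str(row.chrom), int(row.start), int(row.end),
                    str(row.state), q)
        )
    return calls


def write_calls(calls: Iterable[CnvCall], path) -> None:
    df = pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.sample_id, c.state,
             "" if c.quality is None else c.quality)
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def write_genotypes(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})
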