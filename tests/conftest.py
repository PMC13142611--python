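"""Shared fixtures: a small segmented test locus, random genotyper instances,
and the brute-force base-wise coverage oracle used to validate genotype
assignment."""

from __future__ import annotations

import numpy as np
import pytest

from cnvdose.locus_model import (
    DEL, DUP, REF, NO_CALL, AlleleSpan, CnvCall, Segment, SegmentedLocus,
)


@pytest.fixture
def simple_locus() -> SegmentedLocus:
    return SegmentedLocus(
        locus_id="toy",
        chrom="chr1",
        segments=(Segment("toy", "chr1", 1000, 2000),),
        spans=(AlleleSpan("toy", ("toy",)),),
    )


@pytest.fixture
def segmented_locus() -> SegmentedLocus:
    """A 22q11.2-like locus: segments A-B..G-H, spans incl. composite A-D."""
    names = ["A-B", "B-C", "C-D", "D-E", "E-F", "F-G", "G-H"]
    segs, start = [], 1000
    for name, length in zip(names, [1200, 600, 400, 450, 300, 400, 300]):
        segs.append(Segment(name, "chr22", start, start + length))
        start += length + 100
    span_defs = {
        "A-B": ["A-B"], "B-C": ["B-C"], "C-D": ["C-D"],
        "A-C": ["A-B", "B-C"], "B-D": ["B-C", "C-D"],
        "A-D": ["A-B", "B-C", "C-D"],
    }
    spans = tuple(
        AlleleSpan(n, tuple(m), tuple(x for x in names if x not in m))
        for n, m in span_defs.items()
    )
    return SegmentedLocus("22q-like", "chr22", tuple(segs), spans)


def oracle_genotype(calls, locus, span_name, min_fraction=0.5):
    """Brute-force oracle: base-wise boolean coverage counting per state."""
    span = locus.span(span_name)
    lo = min(s.start for s in locus.segments)
    hi = max(s.end for s in locus.segments)
    positive = {}
    for state in (DEL, DUP):
        cov = np.zeros(hi - lo, dtype=bool)
        for c in calls:
            if c.state != state or c.chrom != locus.chrom:
                continue
            a, b = max(c.start, lo), min(c.end, hi)
            if b > a:
                cov[a - lo: b - lo] = True

        def frac(seg):
            return cov[seg.start - lo: seg.end - lo].mean()

        ok = all(frac(locus.segment(n)) >= min_fraction for n in span.segments)
        ok = ok and not any(
            frac(locus.segment(n)) >= min_fraction for n in span.flanking
        )
        positive[state] = ok
    if positive[DEL] and positive[DUP]:
        return NO_CALL
    if positive[DEL]:
        return DEL
    if positive[DUP]:
        return DUP
    return REF


def random_instance(rng: np.random.Generator):
    """A random locus (1-4 segments + optional flanks) and random calls."""
    n_seg = int(rng.integers(1, 5))
    n_flank = int(rng.integers(0, 3))
    segs, start = [], int(rng.integers(0, 50))
    for i in range(n_seg + n_flank):
        length = int(rng.integers(50, 400))
        segs.append(Segment(f"s{i}", "chrT", start, start + length))
        start += length + int(rng.integers(0, 60))
    core = [s.name for s in segs[:n_seg]]
    flanks = [s.name for s in segs[n_seg:]]
    # spans: every contiguous run of core segments
    spans = []
    for i in range(n_seg):
        for j in range(i + 1, n_seg + 1):
            spans.append(
                AlleleSpan(f"sp{i}_{j}", tuple(core[i:j]), tuple(flanks))
            )
    locus = SegmentedLocus("rand", "chrT", tuple(segs), tuple(spans))
    n_calls = int(rng.integers(0, 6))
    calls = []
    extent = segs[-1].end + 100
    for _ in range(n_calls):
        a = int(rng.integers(0, extent))
        b = int(rng.integers(a + 1, extent + 200))
        state = DEL if rng.random() < 0.5 else DUP
        calls.append(CnvCall("sample", "chrT", a, b, state))
    return locus, calls
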