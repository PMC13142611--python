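"""Multi-cohort synthetic data with fully specified generative structure.

The generator emulates the structure of a federated biobank study of
recurrent CNVs: several cohorts of differing size, sex ratio and age
distribution; rare carriers assigned per allele at segmented loci; raw
interval calls with breakpoint jitter and fragmentation; standard-normal PGS
with additive effects; sex-, age- and PGS-dependent CNV effects; BMI-mediated
height effects in pediatric cohorts; and medication assignment correlated
with carrier status.  Every draw descends from one master seed through
per-cohort spawned streams, so outputs are bit-reproducible and stable under
appending cohorts.

Planted effects are expressed in SD units of the latent (sex/age-corrected)
trait; residual noise is scaled so the latent trait has unit variance, which
makes the scaled-trait regression coefficient directly comparable to the
planted value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .locus_model import DEL, DUP, REF, CnvCall, SegmentedLocus, load_catalog
from .phenotypes import LmsReference, lms_value_from_z

log = logging.getLogger(__name__)

AlleleKey = tuple[str, str, str]  # (locus_id, span, state)


def allele_key_str(key: AlleleKey) -> str:
    return ":".join(key)


def parse_allele_key(s: str) -> AlleleKey:
    locus, span, state = s.split(":")
    return locus, span, state


@dataclass
class CohortSpec:
    cohort_id: str
    n: int
    female_fraction: float = 0.5
    age_min: float = 25.0
    age_max: float = 75.0
    kind: str = "adult"  # adult | pediatric
    # carrier-frequency multiplier emulating clinical ascertainment
    # (pediatric CNV cohorts are recruited on carrier status)
    carrier_enrichment: float = 1.0


@dataclass
class AlleleEffect:
    """Generative parameters for one allele (locus, span, DEL/DUP)."""

    beta_height: float = 0.0
    beta_bmi: float = 0.0
    sex_delta_height: float = 0.0   # added effect in females
    sex_delta_bmi: float = 0.0
    pgs_gamma_height: float = 0.0   # interaction per PGS-height SD
    pgs_gamma_bmi: float = 0.0
    # pediatric age trajectories: piecewise-linear (age, z) anchor points;
    # None falls back to the constant beta
    traj_height: list | None = None
    traj_bmi: list | None = None
    med_or: float = 1.0             # carrier odds ratio for medication use

    def height_effect_at(self, age: np.ndarray) -> np.ndarray:
        if self.traj_height is None:
            return np.full_like(age, self.beta_height, dtype=float)
        pts = np.asarray(self.traj_height, dtype=float)
        return np.interp(age, pts[:, 0], pts[:, 1])

    def bmi_effect_at(self, age: np.ndarray) -> np.ndarray:
        if self.traj_bmi is None:
            return np.full_like(age, self.beta_bmi, dtype=float)
        pts = np.asarray(self.traj_bmi, dtype=float)
        return np.interp(age, pts[:, 0], pts[:, 1])


@dataclass
class MedicationModel:
    base_rates: dict = field(
        default_factory=lambda: {
            "antidepressant": 0.12, "antipsychotic": 0.03, "mood_stabilizer": 0.04
        }
    )
    bmi_side_logodds: float = 0.25  # feed-forward: higher BMI-z, more use


@dataclass
class SimConfig:
    seed: int = 0
    cohorts: list = field(default_factory=list)
    frequencies: dict = field(default_factory=dict)   # AlleleKey -> freq
    effects: dict = field(default_factory=dict)       # AlleleKey -> AlleleEffect
    pgs_beta_height: float = 0.55
    pgs_beta_bmi: float = 0.35
    bmi_to_height_b: float = 0.0    # pediatric BMI-z -> height-z coupling
    jitter_sd: float = 10_000.0     # bp on call endpoints
    fragmentation_prob: float = 0.0
    false_call_rate: float = 0.0
    pc_confound: dict | None = None  # {"allele": key, "pc_shift": x, "trait_loading": y, "trait": "height"}
    medication: MedicationModel = field(default_factory=MedicationModel)
    catalog_path: str | None = None  # None = packaged default

    def __post_init__(self) -> None:
        for key, f in self.frequencies.items():
            if not (0.0 < f <= 0.05):
                raise ValueError(f"frequency for {key} must lie in (0, 0.05]")

    def validate_against(self, catalog: list[SegmentedLocus]) -> None:
        spans = {
            (l.locus_id, sp.name) for l in catalog for sp in l.spans
        }
        for locus, span, state in list(self.frequencies) + list(self.effects):
            if (locus, span) not in spans:
                raise ValueError(f"allele ({locus}, {span}) not in catalog")
            if state not in (DEL, DUP):
                raise ValueError(f"bad state {state}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["cohorts"] = [CohortSpec(**c) for c in d.get("cohorts", [])]
        d["frequencies"] = {
            parse_allele_key(k): v for k, v in d.get("frequencies", {}).items()
        }
        d["effects"] = {
            parse_allele_key(k): AlleleEffect(**v)
            for k, v in d.get("effects", {}).items()
        }
        if "medication" in d and isinstance(d["medication"], dict):
            d["medication"] = MedicationModel(**d["medication"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohorts"] = [asdict(c) if not isinstance(c, dict) else c for c in self.cohorts]
        d["frequencies"] = {allele_key_str(k): v for k, v in self.frequencies.items()}
        d["effects"] = {allele_key_str(k): asdict(v) for k, v in self.effects.items()}
        return d


@dataclass
class SyntheticTruth:
    """Generative ground truth: per-cohort carrier ids per allele + the config."""

    config: SimConfig
    carriers: dict  # (cohort_id, AlleleKey) -> np.ndarray of sample_ids

    def carrier_ids(self, allele: AlleleKey) -> set[str]:
        out: set[str] = set()
        for (_, key), ids in self.carriers.items():
            if key == allele:
                out.update(ids)
        return out


@dataclass
class SimResult:
    samples: dict            # cohort_id -> DataFrame
    calls: dict              # cohort_id -> list[CnvCall]
    truth: SyntheticTruth
    catalog: list


# ---------------------------------------------------------------------------


def _assign_carriers(
    rng: np.random.Generator,
    n: int,
    catalog: list[SegmentedLocus],
    frequencies: dict,
    enrichment: float = 1.0,
) -> dict:
    """Mutually exclusive allele assignment per locus (NAHR events at these
    frequencies essentially never co-occur)."""
    carriers: dict[AlleleKey, np.ndarray] = {}
    by_locus: dict[str, list[AlleleKey]] = {}
    for key in sorted(frequencies):
        by_locus.setdefault(key[0], []).append(key)
    for locus_id in sorted(by_locus):
        keys = by_locus[locus_id]
        freqs = np.array([frequencies[k] for k in keys]) * enrichment
        if freqs.sum() >= 1:
            raise ValueError(f"locus {locus_id}: allele frequencies sum >= 1")
        u = rng.random(n)
        edges = np.concatenate([[0.0], np.cumsum(freqs)])
        for k, f, lo, hi in zip(keys, freqs, edges[:-1], edges[1:]):
            if f * n < 1:
                log.warning(
                    "allele %s: expected carriers %.2f < 1 at n=%d",
                    allele_key_str(k), f * n, n,
                )
            carriers[k] = (u >= lo) & (u < hi)
    return carriers


def simulate_raw_calls(
    rng: np.random.Generator,
    carrier_ids: np.ndarray,
    locus: SegmentedLocus,
    span_name: str,
    state: str,
    jitter_sd: float = 10_000.0,
    fragmentation_prob: float = 0.0,
) -> list[CnvCall]:
    """Emit one (or two, if fragmented) jittered interval call per carrier."""
    span = locus.span(span_name)
    start = locus.segment(span.segments[0]).start
    end = locus.segment(span.segments[-1]).end
    calls = []
    for sid in carrier_ids:
        s = int(round(start + rng.normal(0.0, jitter_sd)))
        e = int(round(end + rng.normal(0.0, jitter_sd)))
        if e <= s:
            s, e = start, end
        if fragmentation_prob > 0 and rng.random() < fragmentation_prob:
            # split into two abutting-ish fragments with a tiny gap
            mid = (s + e) // 2
            gap = max(1, int(0.002 * (e - s)))
            calls.append(CnvCall(str(sid), locus.chrom, s, mid, state))
            calls.append(CnvCall(str(sid), locus.chrom, mid + gap, e, state))
        else:
            calls.append(CnvCall(str(sid), locus.chrom, s, e, state))
    return calls


def _false_calls(
    rng: np.random.Generator,
    sample_ids: np.ndarray,
    catalog: list[SegmentedLocus],
    rate: float,
) -> list[CnvCall]:
    """Spurious calls covering one random segment of a random locus."""
    calls = []
    if rate <= 0:
        return calls
    hit = rng.random(len(sample_ids)) < rate
    for sid in sample_ids[hit]:
        locus = catalog[rng.integers(len(catalog))]
        seg = locus.segments[rng.integers(len(locus.segments))]
        state = DEL if rng.random() < 0.5 else DUP
        calls.append(CnvCall(str(sid), locus.chrom, seg.start, seg.end, state))
    return calls


def _latent_trait(
    rng, spec, cfg, carriers, sex_f, age, pgs_h, pgs_b, pcs
) -> tuple[np.ndarray, np.ndarray]:
    """Latent unit-variance z for BMI and height (BMI first: mediation)."""
    n = spec.n
    noise_b = np.sqrt(max(1e-6, 1.0 - cfg.pgs_beta_bmi**2))
    noise_h = np.sqrt(max(1e-6, 1.0 - cfg.pgs_beta_height**2 - cfg.bmi_to_height_b**2))
    z_bmi = cfg.pgs_beta_bmi * pgs_b + noise_b * rng.standard_normal(n)
    z_hei = cfg.pgs_beta_height * pgs_h + noise_h * rng.standard_normal(n)
    pediatric = spec.kind == "pediatric"
    for key, mask in carriers.items():
        eff = cfg.effects.get(key)
        if eff is None or not mask.any():
            continue
        a = age[mask]
        if pediatric:
            z_bmi[mask] += eff.bmi_effect_at(a)
        else:
            z_bmi[mask] += (
                eff.beta_bmi
                + eff.sex_delta_bmi * sex_f[mask]
                + eff.pgs_gamma_bmi * pgs_b[mask]
            )
    z_hei += cfg.bmi_to_height_b * z_bmi
    for key, mask in carriers.items():
        eff = cfg.effects.get(key)
        if eff is None or not mask.any():
            continue
        a = age[mask]
        if pediatric:
            z_hei[mask] += eff.height_effect_at(a)
        else:
            z_hei[mask] += (
                eff.beta_height
                + eff.sex_delta_height * sex_f[mask]
                + eff.pgs_gamma_height * pgs_h[mask]
            )
    if cfg.pc_confound is not None:
        key = tuple(cfg.pc_confound["allele"])
        mask = carriers.get(key)
        if mask is not None and mask.any():
            pcs[mask, 0] += cfg.pc_confound["pc_shift"]
        loading = cfg.pc_confound["trait_loading"]
        if cfg.pc_confound.get("trait", "height") == "height":
            z_hei += loading * pcs[:, 0]
        else:
            z_bmi += loading * pcs[:, 0]
    return z_bmi, z_hei


def _medications(rng, cfg, carriers, z_bmi) -> pd.DataFrame:
    n = len(z_bmi)
    carrier_logodds = np.zeros(n)
    for key, mask in carriers.items():
        eff = cfg.effects.get(key)
        if eff is not None and eff.med_or != 1.0:
            carrier_logodds[mask] += np.log(eff.med_or)
    flags = {}
    for cat, base in cfg.medication.base_rates.items():
        logit = (
            np.log(base / (1 - base))
            + carrier_logodds
            + cfg.medication.bmi_side_logodds * z_bmi
        )
        p = 1.0 / (1.0 + np.exp(-logit))
        flags[cat] = rng.random(n) < p
    df = pd.DataFrame(flags)
    df["any"] = df.any(axis=1)
    return df


def simulate_cohorts(config: SimConfig, lms: LmsReference | None = None,
                     lms_bmi: LmsReference | None = None) -> SimResult:
    """Generate all cohorts, raw CNV calls and the truth table.

    Adult cohorts get raw height (cm) and BMI (kg/m^2) with sex- and
    age-dependent means, to be scaled by the phenotype pipeline.  Pediatric
    cohorts are generated on the LMS z scale (non-carrier z ~ N(0,1) at every
    age) and converted to raw measurements via the inverse LMS transform.
    """
    catalog = load_catalog(config.catalog_path)
    config.validate_against(catalog)
    loci_by_id = {l.locus_id: l for l in catalog}
    if lms is None:
        lms = LmsReference.packaged("height")
    if lms_bmi is None:
        lms_bmi = LmsReference.packaged("bmi")

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(len(config.cohorts))
    samples: dict[str, pd.DataFrame] = {}
    calls: dict[str, list[CnvCall]] = {}
    truth_carriers: dict = {}

    for spec, ss in zip(config.cohorts, streams):
        rng = np.random.default_rng(ss)
        n = spec.n
        sample_ids = np.array([f"{spec.cohort_id}_{i:07d}" for i in range(n)])
        sex_f = (rng.random(n) < spec.female_fraction).astype(float)
        age = rng.uniform(spec.age_min, spec.age_max, size=n)
        pcs = rng.standard_normal((n, 10))
        pgs_h = rng.standard_normal(n)
        pgs_b = rng.standard_normal(n)
        carriers = _assign_carriers(
            rng, n, catalog, config.frequencies,
            enrichment=spec.carrier_enrichment,
        )
        z_bmi, z_hei = _latent_trait(
            rng, spec, config, carriers, sex_f, age, pgs_h, pgs_b, pcs
        )
        meds = _medications(rng, config, carriers, z_bmi)

        if spec.kind == "pediatric":
            sex_lab = np.where(sex_f > 0, "F", "M")
            height = lms_value_from_z(z_hei, age, sex_lab, lms)
            bmi = lms_value_from_z(z_bmi, age, sex_lab, lms_bmi)
        else:
            height = (
                176.0 - 13.0 * sex_f - 0.03 * (age - 40.0) + 6.5 * z_hei
            )
            bmi = 26.5 + 1.2 * sex_f + 0.05 * (age - 50.0) + 4.3 * z_bmi

        df = pd.DataFrame({
            "sample_id": sample_ids,
            "cohort_id": spec.cohort_id,
            "sex": np.where(sex_f > 0, "F", "M"),
            "age": age,
            "height": height,
            "bmi": bmi,
            "PGS_height": pgs_h,
            "PGS_bmi": pgs_b,
        })
        for j in range(10):
            df[f"PC{j+1}"] = pcs[:, j]
        for cat in meds.columns:
            df[f"med_{cat}"] = meds[cat].to_numpy()

        cohort_calls: list[CnvCall] = []
        for key in sorted(carriers):
            mask = carriers[key]
            truth_carriers[(spec.cohort_id, key)] = sample_ids[mask]
            locus_id, span, state = key
            cohort_calls.extend(
                simulate_raw_calls(
                    rng, sample_ids[mask], loci_by_id[locus_id], span, state,
                    jitter_sd=config.jitter_sd,
                    fragmentation_prob=config.fragmentation_prob,
                )
            )
        cohort_calls.extend(
            _false_calls(rng, sample_ids, catalog, config.false_call_rate)
        )
        samples[spec.cohort_id] = df
        calls[spec.cohort_id] = cohort_calls

    truth = SyntheticTruth(config=config, carriers=truth_carriers)
    return SimResult(samples=samples, calls=calls, truth=truth, catalog=catalog)


def truth_genotypes(
    truth: SyntheticTruth, cohort_id: str, sample_ids: np.ndarray,
    alleles: list[AlleleKey],
) -> pd.DataFrame:
    """Genotype columns straight from the truth table (bypassing interval
    calls); column name '<locus>:<span>'."""
    idx = pd.Index(sample_ids)
    out = pd.DataFrame(index=idx)
    cols: dict[str, np.ndarray] = {}
    for locus, span, state in alleles:
        col = f"{locus}:{span}"
        if col not in cols:
            cols[col] = np.full(len(idx), REF, dtype=object)
        ids = truth.carriers.get((cohort_id, (locus, span, state)))
        if ids is not None and len(ids):
            cols[col][idx.get_indexer(ids)] = state
    for col, vals in cols.items():
        out[col] = vals
    return out.reset_index(names="sample_id")


# ---------------------------------------------------------------------------
# recovery metrics


def truth_report(
    truth: SyntheticTruth,
    meta_frame: pd.DataFrame,
    trait: str,
) -> pd.DataFrame:
    """Per planted allele: generative beta, estimate, bias, CI coverage flag."""
    rows = []
    for key, eff in truth.config.effects.items():
        locus, span, state = key
        planted = eff.beta_height if trait == "height" else eff.beta_bmi
        hit = meta_frame[
            (meta_frame["span"] == f"{locus}:{span}")
            & (meta_frame["allele"] == state)
            & (meta_frame["trait"].str.contains(trait))
        ]
        if hit.empty:
            rows.append({
                "allele": allele_key_str(key), "planted": planted,
                "estimate": np.nan, "se": np.nan, "bias": np.nan,
                "covered": np.nan,
            })
            continue
        est = float(hit["beta"].iloc[0])
        se = float(hit["se"].iloc[0])
        rows.append({
            "allele": allele_key_str(key),
            "planted": planted,
            "estimate": est,
            "se": se,
            "bias": est - planted,
            "covered": bool(abs(est - planted) <= 1.96 * se),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default demo configuration (headline-locus archetypes)


def default_effects() -> dict:
    """Effect map imitating the field's headline loci.

    A 16p11.2-like mirror pair (DEL raises BMI / lowers height, DUP the
    reverse with a child-short/adult-tall height trajectory), a 22q11.2-like
    segmented locus with opposing A-B / C-D DUP effects and a sub-additive
    A-D DEL, and a 15q11.2-like female-biased BMI allele.
    """
    e: dict[AlleleKey, AlleleEffect] = {}
    e[("16p11.2_BP4-BP5", "BP4-BP5", DEL)] = AlleleEffect(
        beta_height=-0.55, beta_bmi=0.75, med_or=2.0,
        traj_height=[(2, -0.5), (8, -0.2), (11, 0.5), (13, 0.3), (18, -0.4)],
        traj_bmi=[(2, 0.3), (8, 0.9), (18, 0.8)],
    )
    e[("16p11.2_BP4-BP5", "BP4-BP5", DUP)] = AlleleEffect(
        beta_height=0.35, beta_bmi=-0.45, med_or=1.6,
        traj_height=[(2, -0.5), (10, -0.3), (18, 0.35)],
        traj_bmi=[(2, -0.2), (18, -0.45)],
    )
    # 22q11.2 DUPs: opposing A-B / C-D, neutral B-C, cancelling A-D
    e[("22q11.2", "A-B", DUP)] = AlleleEffect(beta_height=-0.30)
    e[("22q11.2", "B-C", DUP)] = AlleleEffect(beta_height=0.0)
    e[("22q11.2", "C-D", DUP)] = AlleleEffect(beta_height=0.28)
    e[("22q11.2", "A-C", DUP)] = AlleleEffect(beta_height=-0.30)
    e[("22q11.2", "B-D", DUP)] = AlleleEffect(beta_height=0.28)
    e[("22q11.2", "A-D", DUP)] = AlleleEffect(beta_height=-0.02)
    # 22q11.2 DELs: reinforcing negatives, sub-additive A-D (0.6 x sum)
    e[("22q11.2", "A-B", DEL)] = AlleleEffect(beta_height=-0.30, beta_bmi=0.25)
    e[("22q11.2", "B-C", DEL)] = AlleleEffect(beta_height=-0.12)
    e[("22q11.2", "C-D", DEL)] = AlleleEffect(beta_height=-0.18, beta_bmi=-0.20)
    e[("22q11.2", "A-C", DEL)] = AlleleEffect(beta_height=-0.42)
    e[("22q11.2", "B-D", DEL)] = AlleleEffect(beta_height=-0.30)
    e[("22q11.2", "A-D", DEL)] = AlleleEffect(beta_height=-0.36, beta_bmi=0.05)
    # 15q11.2-like female-biased BMI allele
    e[("15q11.2_BP1-BP2", "BP1-BP2", DEL)] = AlleleEffect(
        beta_bmi=0.12, sex_delta_bmi=0.10, beta_height=-0.08, med_or=1.4
    )
    # a few mirror loci to populate the dose-response scatter
    e[("1q21.1_distal", "distal", DEL)] = AlleleEffect(beta_height=-0.45, beta_bmi=0.30)
    e[("1q21.1_distal", "distal", DUP)] = AlleleEffect(beta_height=0.30, beta_bmi=-0.18)
    e[("3q29", "3q29", DEL)] = AlleleEffect(beta_height=-0.25, beta_bmi=0.20)
    e[("3q29", "3q29", DUP)] = AlleleEffect(beta_height=0.15, beta_bmi=-0.12)
    e[("17p12_HNPP", "HNPP", DEL)] = AlleleEffect(beta_height=-0.10)
    e[("17p12_HNPP", "HNPP", DUP)] = AlleleEffect(beta_height=-0.20)  # asymmetric
    e[("16p13.11", "16p13.11", DEL)] = AlleleEffect(beta_height=-0.30, beta_bmi=0.15)
    e[("16p13.11", "16p13.11", DUP)] = AlleleEffect(beta_height=0.0, beta_bmi=0.0)
    return e


def default_frequencies(effects: dict | None = None) -> dict:
    effects = default_effects() if effects is None else effects
    freqs: dict[AlleleKey, float] = {}
    for key in effects:
        if key[0] == "22q11.2" and key[1] != "A-D":
            freqs[key] = 6e-4
        elif key[0] == "22q11.2":
            freqs[key] = 1.2e-3
        elif key[0] == "15q11.2_BP1-BP2":
            freqs[key] = 5e-3
        else:
            freqs[key] = 1.0e-3
    return freqs


def demo_config(seed: int = 0, scale: float = 1.0) -> SimConfig:
    """Packaged demo: 3 adult cohorts + 1 pediatric cohort.

    ``scale`` multiplies cohort sizes (demo default keeps the full pipeline
    run on one CPU to a couple of minutes).
    """
    eff = default_effects()
    cohorts = [
        CohortSpec("biobank_a", int(20_000 * scale), 0.54, 40, 70),
        CohortSpec("biobank_b", int(12_000 * scale), 0.50, 30, 75),
        CohortSpec("biobank_c", int(8_000 * scale), 0.45, 25, 65),
        CohortSpec("pediatric_d", int(6_000 * scale), 0.50, 2, 18,
                   kind="pediatric", carrier_enrichment=50.0),
    ]
    return SimConfig(
        seed=seed,
        cohorts=cohorts,
        frequencies=default_frequencies(eff),
        effects=eff,
        bmi_to_height_b=0.25,
        jitter_sd=10_000.0,
        fragmentation_prob=0.05,
        false_call_rate=1e-4,
    )
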