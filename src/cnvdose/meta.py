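"""Fixed-effects meta-analysis of per-cohort summary statistics.

Only AssociationResult-level summaries cross cohort boundaries (the federated
pattern): inverse-variance pooling of coefficients, Fisher-transform pooling
of variance explained, and the carrier-count / multiplicity filters applied
before pooling.  Heterogeneity (Cochran's Q, I^2) is reported but never
switches the estimator to random effects: traits are scaled within cohort,
so each cohort estimates the same SD-unit quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_assoc import AssociationResult

MIN_CARRIERS_MAIN = 10
MIN_CARRIERS_INTERACTION = 200
BONFERRONI_M_MAIN = 47
BONFERRONI_M_INTERACTION = 32


@dataclass
class MetaResult:
    span: str
    allele: str
    trait: str
    beta: float
    se: float
    z: float
    p: float
    k: int
    n_carriers: int
    q_het: float
    i2: float
    cohort_betas: tuple = field(default_factory=tuple)
    cohort_ses: tuple = field(default_factory=tuple)


def fixed_effects_meta(results: list[AssociationResult]) -> MetaResult:
    """Inverse-variance fixed-effects pool of per-cohort estimates.

    Weights w_i = 1/SE_i^2; pooled beta = sum(w b)/sum(w); pooled
    SE = 1/sqrt(sum w); two-sided normal p.  Q and I^2 reported.
    """
    if not results:
        raise ValueError("no results to pool")
    spans = {(r.span, r.allele, r.trait, r.model) for r in results}
    if len(spans) > 1:
        raise ValueError(f"mixed span/allele/trait/model inputs: {spans}")
    b = np.array([r.beta for r in results], dtype=float)
    se = np.array([r.se for r in results], dtype=float)
    if (se <= 0).any():
        raise ValueError("nonpositive SE")
    w = 1.0 / se**2
    beta = float((w * b).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    z = beta / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float((w * (b - beta) ** 2).sum())
    k = len(results)
    i2 = float(max(0.0, (q - (k - 1)) / q)) if q > 0 and k > 1 else 0.0
    r0 = results[0]
    return MetaResult(
        span=r0.span,
        allele=r0.allele,
        trait=r0.trait,
        beta=beta,
        se=pooled_se,
        z=float(z),
        p=p,
        k=k,
        n_carriers=int(sum(r.n_carriers for r in results)),
        q_het=q,
        i2=i2,
        cohort_betas=tuple(b),
        cohort_ses=tuple(se),
    )


def pool_r2(per_cohort: list[tuple[float, int]]) -> float:
    """Pool variance-explained estimates via Fisher's transform of sqrt(R^2).

    z_i = atanh(sqrt(R2_i)), fixed-effects weights n_i - 3 (the Fisher-z
    sampling precision of a correlation), back-transform tanh(z_bar)^2.
    """
    if not per_cohort:
        raise ValueError("no R^2 values to pool")
    r2 = np.array([x[0] for x in per_cohort], dtype=float)
    n = np.array([x[1] for x in per_cohort], dtype=float)
    if ((r2 < 0) | (r2 >= 1)).any():
        raise ValueError("R^2 must lie in [0, 1)")
    if (n <= 3).any():
        raise ValueError("need n > 3 per cohort")
    z = np.arctanh(np.sqrt(r2))
    w = n - 3.0
    zbar = (w * z).sum() / w.sum()
    return float(np.tanh(zbar) ** 2)


def pooled_delta_r2(
    full: list[tuple[float, int]], cov_only: list[tuple[float, int]]
) -> float:
    """pool_r2(full model) - pool_r2(covariates-only model), matched cohorts."""
    if len(full) != len(cov_only):
        raise ValueError("cohort mismatch between full and covariate-only lists")
    for (_, nf), (_, nc) in zip(full, cov_only):
        if nf != nc:
            raise ValueError("cohort mismatch: unequal n in matched entries")
    return pool_r2(full) - pool_r2(cov_only)


def bonferroni(pvals, m: int) -> tuple[np.ndarray, float]:
    """Strict Bonferroni flags (p < 0.05/m) and the adjusted threshold."""
    pvals = np.asarray(pvals, dtype=float)
    if m < pvals.size:
        raise ValueError(f"m = {m} < number of tests ({pvals.size})")
    threshold = 0.05 / m
    return pvals < threshold, threshold


# ---------------------------------------------------------------------------
# pre-meta filters


def filter_main_results(
    results: list[AssociationResult], min_carriers: int = MIN_CARRIERS_MAIN
) -> list[AssociationResult]:
    """Keep alleles with >= min_carriers combined carriers across cohorts."""
    totals: dict[tuple, int] = {}
    for r in results:
        key = (r.span, r.allele, r.trait)
        totals[key] = totals.get(key, 0) + r.n_carriers
    return [r for r in results if totals[(r.span, r.allele, r.trait)] >= min_carriers]


def filter_interaction_results(
    results: list[AssociationResult],
    min_carriers: int = MIN_CARRIERS_INTERACTION,
) -> list[AssociationResult]:
    return filter_main_results(results, min_carriers=min_carriers)


def meta_by_allele(results: list[AssociationResult]) -> list[MetaResult]:
    """Group per-cohort results by (span, allele, trait, model) and pool each."""
    groups: dict[tuple, list[AssociationResult]] = {}
    for r in results:
        groups.setdefault((r.span, r.allele, r.trait, r.model), []).append(r)
    return [fixed_effects_meta(v) for _, v in sorted(groups.items())]


META_COLUMNS = [
    "span", "allele", "trait", "beta", "se", "z", "p", "k",
    "n_carriers", "q_het", "i2",
]


def meta_to_frame(metas: list[MetaResult]) -> pd.DataFrame:
    rows = []
    for m in metas:
        row = {c: getattr(m, c) for c in META_COLUMNS}
        row["cohort_betas"] = ";".join(f"{b:.6g}" for b in m.cohort_betas)
        row["cohort_ses"] = ";".join(f"{s:.6g}" for s in m.cohort_ses)
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + ["cohort_betas", "cohort_ses"])
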