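"""Breakpoint-subregion additivity: expected combined effects and deviation
tests for segmented loci.

For a composite span (e.g. A-D) built from disjoint component spans (A-B,
B-C, C-D), the additive expectation of the composite allele's effect is the
sum of the component effects, with SE by independence (component and
composite carriers are disjoint groups; the small positive covariance from
the shared REF pool is ignored, which is conservative for carrier-dominated
variances).  A deviation z-test against the observed composite effect tags
the locus sub-additive (buffered) or super-additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .meta import MetaResult


@dataclass
class AdditivityResult:
    composite_span: str
    component_spans: tuple[str, ...]
    allele: str
    trait: str
    observed_beta: float
    observed_se: float
    expected_beta: float
    expected_se: float
    z: float
    p: float
    verdict: str  # additive | sub-additive | super-additive


def expected_combined(
    components: list[MetaResult], allele: str | None = None
) -> tuple[float, float]:
    """Additive expectation over disjoint component spans: sum of betas,
    SE = sqrt(sum SE^2)."""
    if not components:
        raise ValueError("no components")
    alleles = {m.allele for m in components}
    traits = {m.trait for m in components}
    if len(alleles) > 1 or len(traits) > 1:
        raise ValueError("components mix alleles or traits")
    if allele is not None and alleles != {allele}:
        raise ValueError(f"components are {alleles}, expected {allele}")
    spans = [m.span for m in components]
    if len(set(spans)) != len(spans):
        raise ValueError(f"overlapping/duplicate component spans: {spans}")
    beta = float(sum(m.beta for m in components))
    se = float(np.sqrt(sum(m.se**2 for m in components)))
    return beta, se


def additivity_test(
    observed: MetaResult,
    expected_beta: float,
    expected_se: float,
    component_spans: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> AdditivityResult:
    """z = (observed - expected) / sqrt(SE_obs^2 + SE_exp^2), two-sided p.

    Verdict is 'additive' unless p < alpha; a significant deviation with
    |observed| < |expected| is 'sub-additive' (buffering), otherwise
    'super-additive'.
    """
    z = (observed.beta - expected_beta) / np.sqrt(
        observed.se**2 + expected_se**2
    )
    p = float(2.0 * stats.norm.sf(abs(z)))
    if p >= alpha:
        verdict = "additive"
    elif abs(observed.beta) < abs(expected_beta):
        verdict = "sub-additive"
    else:
        verdict = "super-additive"
    return AdditivityResult(
        composite_span=observed.span,
        component_spans=tuple(component_spans),
        allele=observed.allele,
        trait=observed.trait,
        observed_beta=observed.beta,
        observed_se=observed.se,
        expected_beta=float(expected_beta),
        expected_se=float(expected_se),
        z=float(z),
        p=p,
        verdict=verdict,
    )


def opposing_effect_profile(
    components: list[MetaResult], alpha: float = 0.05
) -> dict:
    """Classify a composite locus's component structure.

    Pairs of significant components with opposite signs indicate
    cancellation; same signs indicate reinforcement.  The predicted composite
    effect is the additive sum over all components.
    """
    if len(components) < 2:
        raise ValueError("need >= 2 components")
    betas = np.array([m.beta for m in components])
    sig = np.array([m.p < alpha for m in components])
    predicted, predicted_se = expected_combined(components)
    n_opp = n_reinf = 0
    for i in range(len(components)):
        for j in range(i + 1, len(components)):
            if not (sig[i] and sig[j]):
                continue
            if betas[i] * betas[j] < 0:
                n_opp += 1
            else:
                n_reinf += 1
    if n_opp > n_reinf:
        structure = "cancellation"
    elif n_reinf > n_opp:
        structure = "reinforcement"
    elif n_opp == n_reinf == 0:
        structure = "indeterminate"
    else:
        structure = "mixed"
    return {
        "spans": [m.span for m in components],
        "betas": betas.tolist(),
        "significant": sig.tolist(),
        "n_opposing_pairs": n_opp,
        "n_reinforcing_pairs": n_reinf,
        "structure": structure,
        "predicted_composite_beta": predicted,
        "predicted_composite_se": predicted_se,
    }
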