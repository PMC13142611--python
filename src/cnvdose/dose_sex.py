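"""Dose-response structure across loci and sex-difference analyses.

For each locus with enough carriers of both alleles, the meta-analysed DEL
and DUP effects form one point of a dose-response scatter.  A "mirror" locus
has beta_DUP ~ -c * beta_DEL; an "asymmetric" locus has one active and one
buffered allele.  The decomposition fits a k-component mixture of linear
regressions of beta_DUP on beta_DEL by EM, with each point's known sampling
variance SE_DUP^2 added to the component noise, and selects k by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .meta import MetaResult, fixed_effects_meta, bonferroni
from .cohort_assoc import AssociationResult

MIN_CARRIERS_DOSE = 10


@dataclass
class DoseResponsePoint:
    span: str
    trait: str
    beta_del: float
    se_del: float
    beta_dup: float
    se_dup: float
    n_del: int
    n_dup: int


def build_dose_points(
    meta_del: list[MetaResult],
    meta_dup: list[MetaResult],
    min_carriers: int = MIN_CARRIERS_DOSE,
) -> tuple[list[DoseResponsePoint], float]:
    """Pair DEL/DUP meta effects per span; keep spans with >= min_carriers of
    both alleles.  Returns (points, Pearson r of beta_DEL vs beta_DUP)."""
    dup_by_span = {(m.span, m.trait): m for m in meta_dup}
    points = []
    for md in meta_del:
        mu = dup_by_span.get((md.span, md.trait))
        if mu is None:
            continue
        if md.n_carriers < min_carriers or mu.n_carriers < min_carriers:
            continue
        points.append(
            DoseResponsePoint(
                span=md.span, trait=md.trait,
                beta_del=md.beta, se_del=md.se,
                beta_dup=mu.beta, se_dup=mu.se,
                n_del=md.n_carriers, n_dup=mu.n_carriers,
            )
        )
    if not points:
        raise ValueError("no spans pass the carrier filter for both alleles")
    if len(points) >= 3:
        r = float(stats.pearsonr(
            [p.beta_del for p in points], [p.beta_dup for p in points]
        ).statistic)
    else:
        r = float("nan")
    return points, r


# ---------------------------------------------------------------------------
# mixture of linear regressions (EM, known per-point measurement error)


@dataclass
class ComponentFit:
    k: int
    weights: np.ndarray
    intercepts: np.ndarray
    slopes: np.ndarray
    sigmas: np.ndarray          # residual SD beyond measurement error
    loglik: float
    bic: float
    responsibilities: np.ndarray  # (n, k), rows sum to 1
    assignment: np.ndarray        # hard argmax per point
    converged: bool
    n_iter: int
    n_params: int = field(default=0)


def _component_loglik(y, mu, var):
    return -0.5 * (np.log(2 * np.pi * var) + (y - mu) ** 2 / var)


def _m_step_component(x, y, s2, r, sigma2, inner: int = 2):
    """Weighted line + residual variance for one component given resp. r."""
    a = b = 0.0
    for _ in range(inner):
        var = sigma2 + s2
        w = r / var
        sw = w.sum()
        if sw <= 0:
            break
        xbar = (w * x).sum() / sw
        ybar = (w * y).sum() / sw
        sxx = (w * (x - xbar) ** 2).sum()
        if sxx <= 0:
            b = 0.0
        else:
            b = (w * (x - xbar) * (y - ybar)).sum() / sxx
        a = ybar - b * xbar

        resid2 = (y - a - b * x) ** 2

        # profile sigma^2 by bounded 1-d search on the exact weighted objective
        def obj(log_s2):
            var = np.exp(log_s2) + s2
            return (r * (np.log(var) + resid2 / var)).sum()

        res = _golden_min(obj, -30.0, 5.0)
        sigma2 = float(np.exp(res))
    return a, b, sigma2


def _golden_min(f, lo, hi, tol=1e-7):
    """Golden-section minimization on [lo, hi] (1-d, unimodal profile)."""
    gr = (np.sqrt(5.0) - 1) / 2
    c = hi - gr * (hi - lo)
    d = lo + gr * (hi - lo)
    fc, fd = f(c), f(d)
    while abs(hi - lo) > tol:
        if fc < fd:
            hi, d, fd = d, c, fc
            c = hi - gr * (hi - lo)
            fc = f(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + gr * (hi - lo)
            fd = f(d)
    return 0.5 * (lo + hi)


def _em_once(x, y, s2, k, rng, max_iter, tol, init_resp=None):
    n = len(x)
    # init: random soft responsibilities (or warm start)
    r = rng.dirichlet(np.ones(k), size=n) if init_resp is None else init_resp
    pi = np.full(k, 1.0 / k)
    a = np.zeros(k)
    b = np.zeros(k)
    sigma2 = np.full(k, max(y.var(), 1e-6))
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step
        pi = r.mean(axis=0)
        for j in range(k):
            a[j], b[j], sigma2[j] = _m_step_component(x, y, s2, r[:, j], sigma2[j])
        # E-step
        log_dens = np.empty((n, k))
        for j in range(k):
            var = sigma2[j] + s2
            log_dens[:, j] = np.log(pi[j] + 1e-300) + _component_loglik(
                y, a[j] + b[j] * x, var
            )
        m = log_dens.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
        ll = float(lse.sum())
        r = np.exp(log_dens - lse[:, None])
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return dict(pi=pi, a=a, b=b, sigma2=sigma2, loglik=ll, resp=r,
                converged=converged, n_iter=it)


def fit_components(
    points: list[DoseResponsePoint],
    k: int,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> ComponentFit:
    """Fit a k-component mixture of regressions of beta_DUP on beta_DEL.

    Component noise is sigma_k^2 + SE_DUP_i^2 (measurement error on the
    response is modelled; SE_DEL on the x-axis is ignored by default, a known
    attenuation source).  Multi-start EM with ``n_starts`` seeded restarts;
    returns the best fit by log-likelihood.  k=1 reduces to an iterated
    weighted least squares fit.  BIC = -2 LL + p ln(n), p = 3k + (k-1).
    """
    if len(points) < 2 * k + 2:
        raise ValueError(f"need >= {2 * k + 2} points for k={k}")
    x = np.array([p.beta_del for p in points])
    y = np.array([p.beta_dup for p in points])
    s2 = np.array([p.se_dup**2 for p in points])
    rng = np.random.default_rng(seed)
    # short burn-in for every restart, then polish the best start to
    # convergence (standard multi-start EM economy)
    best = None
    for _ in range(max(1, n_starts if k > 1 else 1)):
        fit = _em_once(x, y, s2, k, rng, max_iter=40, tol=tol)
        if best is None or fit["loglik"] > best["loglik"]:
            best = fit
    polish = _em_once(x, y, s2, k, rng, max_iter=max_iter, tol=tol,
                      init_resp=best["resp"])
    if polish["loglik"] >= best["loglik"]:
        best = polish
    n_params = 3 * k + (k - 1)
    bic = -2.0 * best["loglik"] + n_params * np.log(len(points))
    resp = best["resp"]
    return ComponentFit(
        k=k,
        weights=best["pi"],
        intercepts=best["a"],
        slopes=best["b"],
        sigmas=np.sqrt(best["sigma2"]),
        loglik=best["loglik"],
        bic=float(bic),
        responsibilities=resp,
        assignment=resp.argmax(axis=1),
        converged=best["converged"],
        n_iter=best["n_iter"],
        n_params=n_params,
    )


def select_components(
    points: list[DoseResponsePoint],
    ks=(1, 2),
    criterion: str = "bic",
    **kwargs,
) -> tuple[int, dict[int, ComponentFit]]:
    """Fit each k and pick the best by BIC (default) or AIC."""
    fits = {k: fit_components(points, k, **kwargs) for k in ks}
    if criterion == "bic":
        score = {k: f.bic for k, f in fits.items()}
    elif criterion == "aic":
        score = {k: -2 * f.loglik + 2 * f.n_params for k, f in fits.items()}
    else:
        raise ValueError("criterion must be 'bic' or 'aic'")
    best_k = min(score, key=lambda k: (score[k], k))
    return best_k, fits


# ---------------------------------------------------------------------------
# sex differences


def slope_equality_test(male_betas, female_betas):
    """Regress female effects on male effects across loci and F-test the joint
    hypothesis {intercept = 0, slope = 1} (deviation from the identity line).

    Returns (slope, intercept, F, p).
    """
    male = np.asarray(male_betas, dtype=float)
    female = np.asarray(female_betas, dtype=float)
    if male.size < 3:
        raise ValueError("need >= 3 loci")
    X = sm.add_constant(male)
    fit = sm.OLS(female, X).fit()
    slope, intercept = float(fit.params[1]), float(fit.params[0])
    scale = max(float(np.var(female)), 1e-30)
    if fit.ssr / (male.size * scale) < 1e-24:
        # numerically perfect fit: the F statistic is 0/0; report directly
        on_line = abs(intercept) < 1e-10 and abs(slope - 1.0) < 1e-10
        return slope, intercept, 0.0 if on_line else np.inf, 1.0 if on_line else 0.0
    ftest = fit.f_test((np.eye(2), np.array([0.0, 1.0])))
    return slope, intercept, float(ftest.fvalue), float(ftest.pvalue)


def grouped_sex_difference(
    main_metas: list[MetaResult],
    female_metas: list[MetaResult],
    male_metas: list[MetaResult],
    m_bonferroni: int = 47,
) -> dict[str, MetaResult]:
    """Pooled female-minus-male contrast within effect-sign groups.

    Loci are grouped by the main (sex-combined) meta effect: Bonferroni-
    significant positive, significant negative, or neutral.  Within each
    group, per-locus contrasts d = beta_F - beta_M with SE = sqrt(SE_F^2 +
    SE_M^2) (disjoint samples) are pooled by fixed-effects meta-analysis.
    """
    f_by = {(m.span, m.trait): m for m in female_metas}
    m_by = {(m.span, m.trait): m for m in male_metas}
    flags, _ = bonferroni([m.p for m in main_metas], m=m_bonferroni)
    groups: dict[str, list[AssociationResult]] = {
        "positive": [], "neutral": [], "negative": []
    }
    for mm, sig in zip(main_metas, flags):
        key = (mm.span, mm.trait)
        if key not in f_by or key not in m_by:
            continue
        group = ("positive" if mm.beta > 0 else "negative") if sig else "neutral"
        fm, ml = f_by[key], m_by[key]
        groups[group].append(
            AssociationResult(
                cohort_id=mm.span,
                span=group,
                allele=mm.allele,
                trait=mm.trait,
                beta=fm.beta - ml.beta,
                se=float(np.sqrt(fm.se**2 + ml.se**2)),
                p=1.0,
                n_carriers=fm.n_carriers + ml.n_carriers,
                n_total=fm.n_carriers + ml.n_carriers,
                model="sex_contrast",
            )
        )
    out = {}
    for group, contrasts in groups.items():
        if not contrasts:
            continue
        # pool contrasts irrespective of allele label
        relabeled = [
            AssociationResult(
                cohort_id=c.cohort_id, span=group, allele="ANY", trait=c.trait,
                beta=c.beta, se=c.se, p=c.p, n_carriers=c.n_carriers,
                n_total=c.n_total, model="sex_contrast",
            )
            for c in contrasts
        ]
        out[group] = fixed_effects_meta(relabeled)
    return out
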