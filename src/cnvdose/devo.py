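"""Age-dependent trajectory analysis and age-binned cross-sectional mediation.

Pediatric z-scores from a correctly specified growth reference have mean 0 at
every age in non-carriers, so a carrier's deviation curve is directly
interpretable.  Trajectories are modelled with fixed-df natural cubic spline
bases (not penalized smooths), so nested likelihood-ratio tests have an exact
chi-square reference distribution under the null.  ``basis_df`` counts the
dimensions added beyond a constant carrier offset.

Mediation follows the product-of-coefficients decomposition on raw phenotype
values: mediator model BMI ~ sex + age + CNV, outcome model
HEIGHT ~ BMI + sex + age + CNV; ACME = a*b, ADE = the outcome-model CNV
coefficient, with percentile-bootstrap confidence intervals.  The reverse
direction (CNV -> height -> BMI) swaps mediator and outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats

DEFAULT_BASIS_DF = 5


def _spline_basis(age: np.ndarray, basis_df: int) -> np.ndarray:
    """Natural cubic spline basis of rank basis_df + 1 (spans the constant)."""
    return np.asarray(
        dmatrix("cr(x, df=k) - 1", {"x": age, "k": basis_df + 1})
    )


def _gauss_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


@dataclass
class TrajectoryFit:
    basis_df: int
    loglik_null: float
    loglik_full: float
    lrt: float
    df: int
    p: float
    carrier_offset: float
    smooth_ages: np.ndarray | None = None
    smooth_values: np.ndarray | None = None


def fit_age_smooth(
    z, age, carrier, basis_df: int = DEFAULT_BASIS_DF
) -> TrajectoryFit:
    """Test whether a carrier group's z-deviation varies with age.

    Null model: population intercept + constant carrier offset.  Full model:
    population intercept + a carrier-specific natural-spline function of age
    (which contains the constant offset, adding ``basis_df`` dimensions).
    LRT ~ chi-square(basis_df) under the age-constant null.
    """
    z = np.asarray(z, dtype=float)
    age = np.asarray(age, dtype=float)
    carrier = np.asarray(carrier).astype(bool)
    if len(np.unique(age[carrier])) < 3:
        raise ValueError("carriers must span >= 3 distinct ages")
    n = len(z)
    car = carrier.astype(float)
    X0 = np.column_stack([np.ones(n), car])
    B = _spline_basis(age, basis_df)
    X1 = np.column_stack([np.ones(n), B * car[:, None]])
    rss0, rss1 = _rss(z, X0), _rss(z, X1)
    ll0, ll1 = _gauss_loglik(rss0, n), _gauss_loglik(rss1, n)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lrt, basis_df))
    # fitted carrier deviation on an age grid
    beta1, _, _, _ = np.linalg.lstsq(X1, z, rcond=None)
    grid = np.linspace(age[carrier].min(), age[carrier].max(), 50)
    Bg = _spline_basis(np.concatenate([age, grid]), basis_df)[n:]
    smooth = Bg @ beta1[1:]
    beta0, _, _, _ = np.linalg.lstsq(X0, z, rcond=None)
    return TrajectoryFit(
        basis_df=basis_df,
        loglik_null=ll0,
        loglik_full=ll1,
        lrt=lrt,
        df=basis_df,
        p=p,
        carrier_offset=float(beta0[1]),
        smooth_ages=grid,
        smooth_values=smooth,
    )


def compare_trajectories_by_group(
    z, age, group, basis_df: int = DEFAULT_BASIS_DF
) -> TrajectoryFit:
    """Shared-smooth vs group-specific comparison within carriers.

    ``group`` is a two-level label (e.g. obese/lean split at a BMI
    percentile, sex, or PGS quartile membership).  Shared model: one smooth
    of age for everyone.  Specific model: a separate smooth per group (which
    contains the group offset), so the test detects any difference in the
    height-age relationship, level or shape; LRT df = basis_df + 1.  The
    statistic is symmetric under swapping group labels.
    """
    z = np.asarray(z, dtype=float)
    age = np.asarray(age, dtype=float)
    codes, levels = pd.factorize(np.asarray(group))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {list(levels)}")
    if (codes == 0).sum() == 0 or (codes == 1).sum() == 0:
        raise ValueError("one group is empty")
    n = len(z)
    g = codes.astype(float)
    B = _spline_basis(age, basis_df)  # rank basis_df + 1, spans constant
    X_shared = B
    X_specific = np.column_stack([B * (1 - g)[:, None], B * g[:, None]])
    rss0, rss1 = _rss(z, X_shared), _rss(z, X_specific)
    ll0, ll1 = _gauss_loglik(rss0, n), _gauss_loglik(rss1, n)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    df = basis_df + 1
    p = float(stats.chi2.sf(lrt, df))
    return TrajectoryFit(
        basis_df=basis_df,
        loglik_null=ll0,
        loglik_full=ll1,
        lrt=lrt,
        df=df,
        p=p,
        carrier_offset=float("nan"),
    )


def obesity_split(
    bmi_z: np.ndarray, percentile: float = 90.0
) -> np.ndarray:
    """Obesity flag from a population-norm BMI percentile cutoff (default
    90th; a 30th-percentile preset serves sparse-obesity alleles)."""
    cut = stats.norm.ppf(percentile / 100.0)
    return np.asarray(bmi_z, dtype=float) > cut


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    bin_label: str
    direction: str           # "forward" (CNV->BMI->height) or "reverse"
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    n: int
    n_carriers: int
    n_boot: int
    n_boot_failed: int
    underpowered: bool


def _mediation_point(y_out, mediator, sex, age, cnv):
    n = len(y_out)
    Xm = np.column_stack([np.ones(n), sex, age, cnv])
    bm, _, rank_m, _ = np.linalg.lstsq(Xm, mediator, rcond=None)
    Xo = np.column_stack([np.ones(n), mediator, sex, age, cnv])
    bo, _, rank_o, _ = np.linalg.lstsq(Xo, y_out, rcond=None)
    if rank_m < Xm.shape[1] or rank_o < Xo.shape[1]:
        raise np.linalg.LinAlgError("singular mediation fit")
    a = bm[3]          # CNV -> mediator
    b = bo[1]          # mediator -> outcome
    ade = bo[4]        # direct CNV -> outcome
    return float(a * b), float(ade)


def mediate_by_age(
    data: pd.DataFrame,
    age_bins: list[float],
    n_boot: int = 1000,
    seed: int = 0,
    direction: str = "forward",
    min_carriers: int = 10,
    height_col: str = "height",
    bmi_col: str = "bmi",
) -> list[MediationResult]:
    """Age-binned cross-sectional mediation on raw phenotype values.

    ``age_bins`` are edges; each bin is [lo, hi) (upper bound exclusive).
    Forward direction: mediator = BMI, outcome = height.  Reverse swaps them.
    Bins with fewer than ``min_carriers`` carriers are reported with
    ``underpowered=True``.  Bootstrap reps with singular fits are dropped and
    counted.
    """
    if direction == "forward":
        med_col, out_col = bmi_col, height_col
    elif direction == "reverse":
        med_col, out_col = height_col, bmi_col
    else:
        raise ValueError("direction must be 'forward' or 'reverse'")
    rng = np.random.default_rng(seed)
    sex_codes, _ = pd.factorize(data["sex"])
    df = data.assign(_sex=sex_codes.astype(float))
    results = []
    for lo, hi in zip(age_bins[:-1], age_bins[1:]):
        sub = df[(df["age"] >= lo) & (df["age"] < hi)]
        n = len(sub)
        cnv = sub["carrier"].to_numpy(dtype=float)
        n_car = int(cnv.sum())
        label = f"{lo:g}-{hi:g}"
        y = sub[out_col].to_numpy(dtype=float)
        m = sub[med_col].to_numpy(dtype=float)
        sx = sub["_sex"].to_numpy()
        ag = sub["age"].to_numpy(dtype=float)
        try:
            acme, ade = _mediation_point(y, m, sx, ag, cnv)
        except np.linalg.LinAlgError:
            # e.g. a bin without carriers: report it, don't fail the run
            results.append(MediationResult(
                bin_label=label, direction=direction, acme=float("nan"),
                ade=float("nan"), total=float("nan"),
                prop_mediated=float("nan"),
                acme_ci=(float("nan"), float("nan")),
                ade_ci=(float("nan"), float("nan")),
                n=n, n_carriers=n_car, n_boot=n_boot, n_boot_failed=n_boot,
                underpowered=True,
            ))
            continue
        boots_acme, boots_ade = [], []
        failed = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                ba, bd = _mediation_point(y[idx], m[idx], sx[idx], ag[idx], cnv[idx])
            except np.linalg.LinAlgError:
                failed += 1
                continue
            boots_acme.append(ba)
            boots_ade.append(bd)
        if boots_acme:
            acme_ci = tuple(np.percentile(boots_acme, [2.5, 97.5]))
            ade_ci = tuple(np.percentile(boots_ade, [2.5, 97.5]))
        else:
            acme_ci = ade_ci = (float("nan"), float("nan"))
        total = acme + ade
        prop = acme / total if total != 0 else float("nan")
        results.append(
            MediationResult(
                bin_label=label,
                direction=direction,
                acme=acme,
                ade=ade,
                total=total,
                prop_mediated=prop,
                acme_ci=(float(acme_ci[0]), float(acme_ci[1])),
                ade_ci=(float(ade_ci[0]), float(ade_ci[1])),
                n=n,
                n_carriers=n_car,
                n_boot=n_boot,
                n_boot_failed=failed,
                underpowered=n_car < min_carriers,
            )
        )
    return results


def mediation_to_frame(results: list[MediationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "bin": r.bin_label, "direction": r.direction, "acme": r.acme,
            "ade": r.ade, "total": r.total, "prop_mediated": r.prop_mediated,
            "acme_lo": r.acme_ci[0], "acme_hi": r.acme_ci[1],
            "ade_lo": r.ade_ci[0], "ade_hi": r.ade_ci[1],
            "n": r.n, "n_carriers": r.n_carriers,
            "underpowered": r.underpowered, "n_boot_failed": r.n_boot_failed,
        })
    return pd.DataFrame(rows)
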