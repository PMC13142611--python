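"""Within-cohort model fits.

Every fit here operates on a single cohort's table (one row per sample) and
returns summary statistics only; individual-level data never needs to leave
the cohort to be meta-analysed.  Genotypes are factor-coded with REF (no CNV)
as the reference level, so a coefficient of -0.5 for DEL means carriers sit
half a within-cohort SD below non-carriers of the same sex and age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .locus_model import DEL, DUP, REF, NO_CALL

log = logging.getLogger(__name__)

PC_COLS = [f"PC{i}" for i in range(1, 11)]
MED_CATEGORIES = ("antidepressant", "antipsychotic", "mood_stabilizer")


@dataclass
class AssociationResult:
    cohort_id: str
    span: str
    allele: str
    trait: str
    beta: float
    se: float
    p: float
    n_carriers: int
    n_total: int
    model: str = "main"

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.beta):
            raise ValueError(f"invalid result for {self.span}/{self.allele}")
        if self.n_carriers > self.n_total:
            raise ValueError("n_carriers > n_total")


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def _pc_cols(df: pd.DataFrame, pc_cols) -> list[str]:
    if pc_cols is None:
        return [c for c in PC_COLS if c in df.columns]
    return list(pc_cols)


def fit_main_effect(
    cohort: pd.DataFrame,
    trait: str,
    span: str,
    cohort_id: str = "",
    pc_cols=None,
) -> list[AssociationResult]:
    """CNV main effect: trait ~ factor(genotype, ref=REF) + PC1..PC10.

    ``span`` names the genotype column (values in DEL/DUP/REF/NO_CALL).
    NO_CALL samples are dropped for this span only.  Returns one
    AssociationResult per allele with at least one carrier.
    """
    pcs = _pc_cols(cohort, pc_cols)
    sub = cohort[cohort[span] != NO_CALL]
    sub = sub.dropna(subset=[trait])
    y = sub[trait].to_numpy(dtype=float)
    geno = sub[span].to_numpy()
    del_ind = (geno == DEL).astype(float)
    dup_ind = (geno == DUP).astype(float)
    n_del, n_dup = int(del_ind.sum()), int(dup_ind.sum())
    if n_del == 0 and n_dup == 0:
        raise ValueError(f"span {span}: no DEL or DUP carriers")

    cols, names = [np.ones(len(sub))], ["const"]
    if n_del:
        cols.append(del_ind)
        names.append(DEL)
    if n_dup:
        cols.append(dup_ind)
        names.append(DUP)
    for c in pcs:
        cols.append(sub[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(f"span {span}: rank-deficient design")
    fit = sm.OLS(y, X).fit()
    out = []
    for allele, n_car in ((DEL, n_del), (DUP, n_dup)):
        if n_car == 0:
            continue
        i = names.index(allele)
        out.append(
            AssociationResult(
                cohort_id=cohort_id,
                span=span,
                allele=allele,
                trait=trait,
                beta=float(fit.params[i]),
                se=float(fit.bse[i]),
                p=float(fit.pvalues[i]),
                n_carriers=n_car,
                n_total=len(sub),
                model="main",
            )
        )
    return out


def fit_interaction(
    cohort: pd.DataFrame,
    trait: str,
    span: str,
    moderator: str,
    cohort_id: str = "",
    pc_cols=None,
    min_carriers: int | None = None,
) -> list[AssociationResult]:
    """CNV x moderator interaction: trait ~ genotype * moderator + PCs.

    ``moderator`` is a PGS column (continuous) or a sex column (two-level,
    converted to 0/1).  Returns the allele x moderator coefficient per allele
    present, with z = beta/se recoverable as beta/se.  The >=200-combined-
    carrier filter of the interaction analysis is applied upstream (see
    ``meta.filter_interaction_results``); ``min_carriers`` enforces it here
    when given.
    """
    pcs = _pc_cols(cohort, pc_cols)
    sub = cohort[cohort[span] != NO_CALL].dropna(subset=[trait, moderator])
    mod = sub[moderator]
    if mod.dtype == object or str(mod.dtype) == "category":
        codes, levels = pd.factorize(mod)
        if len(levels) != 2:
            raise ValueError(f"moderator {moderator}: need exactly 2 levels")
        mod = pd.Series(codes.astype(float), index=sub.index)
    mod = mod.to_numpy(dtype=float)
    if np.ptp(mod) == 0:
        raise ValueError(f"moderator {moderator} is constant")

    geno = sub[span].to_numpy()
    y = sub[trait].to_numpy(dtype=float)
    inds = {s: (geno == s).astype(float) for s in (DEL, DUP)}
    present = [s for s in (DEL, DUP) if inds[s].sum() > 0]
    if not present:
        raise ValueError(f"span {span}: no carriers")
    if min_carriers is not None:
        total = int(sum(inds[s].sum() for s in present))
        if total < min_carriers:
            raise ValueError(
                f"span {span}: {total} carriers < required {min_carriers}"
            )
    cols, names = [np.ones(len(sub)), mod], ["const", "mod"]
    for s in present:
        cols.append(inds[s])
        names.append(s)
    for s in present:
        cols.append(inds[s] * mod)
        names.append(f"{s}:mod")
    for c in pcs:
        cols.append(sub[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    fit = sm.OLS(y, X).fit()
    out = []
    for s in present:
        i = names.index(f"{s}:mod")
        out.append(
            AssociationResult(
                cohort_id=cohort_id,
                span=span,
                allele=s,
                trait=trait,
                beta=float(fit.params[i]),
                se=float(fit.bse[i]),
                p=float(fit.pvalues[i]),
                n_carriers=int(inds[s].sum()),
                n_total=len(sub),
                model=f"interaction:{moderator}",
            )
        )
    return out


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("collinear genotype columns dropped from R^2 fit")
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid**2).sum() / tss


def variance_explained(
    cohort: pd.DataFrame,
    trait: str,
    spans: list[str],
    pc_cols=None,
) -> tuple[float, float, float, int]:
    """R^2 of (all spans as factors + PCs) vs (PCs only); Delta R^2 >= 0.

    Samples with NO_CALL at any included span are excluded from both fits so
    the two R^2 values are computed on the same rows.
    """
    pcs = _pc_cols(cohort, pc_cols)
    mask = np.ones(len(cohort), dtype=bool)
    for s in spans:
        mask &= (cohort[s] != NO_CALL).to_numpy()
    sub = cohort[mask].dropna(subset=[trait])
    y = sub[trait].to_numpy(dtype=float)
    cov_cols = [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in pcs]
    X_cov = np.column_stack(cov_cols)
    geno_cols = []
    for s in spans:
        g = sub[s].to_numpy()
        for state in (DEL, DUP):
            ind = (g == state).astype(float)
            if ind.sum() > 0:
                geno_cols.append(ind)
    X_full = np.column_stack(cov_cols + geno_cols) if geno_cols else X_cov
    r2_cov = _r2(y, X_cov)
    r2_full = _r2(y, X_full)
    return r2_full, r2_cov, r2_full - r2_cov, len(sub)


# ---------------------------------------------------------------------------
# medications


def tabulate_medications(
    prescriptions: dict[str, list[str]] | pd.DataFrame,
    dictionary: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample medication-category flags from prescribed-code lists.

    ``dictionary`` maps code -> category in {antidepressant, antipsychotic,
    mood_stabilizer}; ``any`` is the union of the three.  Unknown codes are
    logged and ignored.
    """
    if isinstance(prescriptions, pd.DataFrame):
        prescriptions = (
            prescriptions.groupby("sample_id")["code"].apply(list).to_dict()
        )
    code_to_cat = dict(zip(dictionary["code"].astype(str), dictionary["category"]))
    bad = set(code_to_cat.values()) - set(MED_CATEGORIES)
    if bad:
        raise ValueError(f"unknown medication categories in dictionary: {bad}")
    rows = []
    unknown: set[str] = set()
    for sid, codes in prescriptions.items():
        flags = {c: False for c in MED_CATEGORIES}
        for code in codes:
            cat = code_to_cat.get(str(code))
            if cat is None:
                unknown.add(str(code))
                continue
            flags[cat] = True
        flags["any"] = any(flags.values())
        rows.append({"sample_id": sid, **flags})
    if unknown:
        log.warning("unknown medication codes ignored: %s", sorted(unknown)[:20])
    return pd.DataFrame(rows, columns=["sample_id", *MED_CATEGORIES, "any"])


def medication_enrichment(
    cohort: pd.DataFrame,
    span: str,
    med_col: str,
) -> tuple[float, float, np.ndarray]:
    """Chi-square test (1 df, no continuity correction) of carrier x med use.

    Carriers are samples with DEL or DUP at ``span``; NO_CALL dropped.
    Returns (chi2, p, 2x2 table [[carrier_use, carrier_no], [ref_use, ref_no]]).
    """
    sub = cohort[cohort[span] != NO_CALL]
    carrier = sub[span].isin([DEL, DUP]).to_numpy()
    use = sub[med_col].astype(bool).to_numpy()
    table = np.array(
        [
            [int((carrier & use).sum()), int((carrier & ~use).sum())],
            [int((~carrier & use).sum()), int((~carrier & ~use).sum())],
        ]
    )
    if carrier.sum() == 0:
        raise ValueError(f"span {span}: no carriers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table margins")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), table


# ---------------------------------------------------------------------------
# stratified group means


def stratified_means(
    cohort: pd.DataFrame,
    trait_raw: str,
    span: str,
    pgs_col: str | None = None,
    med_col: str | None = None,
    n_quantiles: int = 4,
    quartiles_on: str = "all",
) -> tuple[pd.DataFrame, float]:
    """Raw-trait group means per genotype x (PGS quantile / medication) cell.

    Quantile boundaries are computed on the full cohort by default
    (``quartiles_on="all"``; carriers are rare so distortion is negligible)
    or on non-carriers (``"noncarriers"``).  Returns the cell table (mean, n,
    se) and the max-min range over non-empty cells.
    """
    sub = cohort[cohort[span] != NO_CALL].copy()
    keys = [span]
    if pgs_col is not None:
        if quartiles_on == "noncarriers":
            base = sub.loc[sub[span] == REF, pgs_col]
        elif quartiles_on == "all":
            base = sub[pgs_col]
        else:
            raise ValueError("quartiles_on must be 'all' or 'noncarriers'")
        edges = np.quantile(base, np.linspace(0, 1, n_quantiles + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        sub["pgs_q"] = pd.cut(sub[pgs_col], edges, labels=range(1, n_quantiles + 1))
        keys.append("pgs_q")
    if med_col is not None:
        keys.append(med_col)
    grouped = sub.groupby(keys, observed=False)[trait_raw]
    table = grouped.agg(mean="mean", n="count", sd="std").reset_index()
    table["se"] = table["sd"] / np.sqrt(table["n"].clip(lower=1))
    nonempty = table[table["n"] > 0]
    rng = float(nonempty["mean"].max() - nonempty["mean"].min()) if len(nonempty) else np.nan
    return table, rng
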