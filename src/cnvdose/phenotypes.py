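"""Harmonized trait scaling.

Adult height/BMI are scaled within each cohort: residualize on sex, age and
age^2, then per sex apply a maximum-likelihood Box-Cox transform (after a
shift to positive support) and standardize to mean 0 / SD 1.  Effects
estimated on the scaled trait are therefore in within-cohort SD units of the
sex- and age-corrected trait, comparable across cohorts regardless of
demographic composition.  Pediatric values are expressed as age/sex z-scores
against an LMS growth reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

MIN_PER_SEX = 30
ADULT_AGE = 18.0


@dataclass
class ScalingParams:
    """Per-sex Box-Cox parameters, stored for audit/reproducibility."""

    trait: str
    lmbda: dict[str, float]
    shift: dict[str, float]
    post_mean: dict[str, float]
    post_sd: dict[str, float]
    pre_sd: dict[str, float] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def residualize_trait(y, sex, age) -> np.ndarray:
    """Residuals of y ~ sex + age + age^2 (least squares).

    ``sex`` may be any two-level coding; it is converted to a 0/1 indicator.
    Raises on rank-deficient designs (constant sex or age).
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    sex_codes, _ = pd.factorize(np.asarray(sex))
    if y.size <= 4:
        raise ValueError("need more than 4 samples to residualize")
    X = np.column_stack([np.ones_like(y), sex_codes.astype(float), age, age**2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design: constant sex or age column"
        )
    fit = sm.OLS(y, X).fit()
    return np.asarray(fit.resid)


def boxcox_per_sex(
    residuals, sex, trait: str = "trait", min_per_sex: int = MIN_PER_SEX
) -> tuple[np.ndarray, ScalingParams]:
    """Per-sex Box-Cox + standardization of residualized trait values.

    Within each sex: shift residuals by (-min + 1) to strictly positive
    support, estimate the Box-Cox lambda by maximum likelihood (searched in
    [-5, 5]), transform, and standardize to mean 0 / SD 1.  The transform is
    strictly increasing within sex, so rank order is preserved.  Because the
    unit pedestal of the shift is not scale-equivariant, outputs for the same
    data in different measurement units agree in rank exactly and in value
    approximately (not to machine precision); see the methods note.
    Returns the recombined scaled vector (input order) and the parameters.
    """
    residuals = np.asarray(residuals, dtype=float)
    sex = np.asarray(sex)
    out = np.empty_like(residuals)
    params = ScalingParams(trait, {}, {}, {}, {}, {})
    for s in pd.unique(sex):
        mask = sex == s
        x = residuals[mask]
        if x.size < min_per_sex:
            raise ValueError(
                f"sex stratum {s!r} has {x.size} samples (< {min_per_sex})"
            )
        pre_sd = float(x.std(ddof=0))
        if pre_sd <= 0:
            raise ValueError(f"sex stratum {s!r}: constant residuals")
        shift = -x.min() + 1.0
        xs = x + shift
        lmbda = float(
            stats.boxcox_normmax(xs, brack=(-5.0, 5.0), method="mle")
        )
        lmbda = float(np.clip(lmbda, -5.0, 5.0))
        t = stats.boxcox(xs, lmbda=lmbda)
        mu, sd = t.mean(), t.std(ddof=0)
        out[mask] = (t - mu) / sd
        key = str(s)
        params.lmbda[key] = lmbda
        params.shift[key] = float(shift)
        params.post_mean[key] = float(mu)
        params.post_sd[key] = float(sd)
        params.pre_sd[key] = float(pre_sd)
    return out, params


def scale_adult_trait(
    df: pd.DataFrame,
    trait: str,
    sex_col: str = "sex",
    age_col: str = "age",
    min_per_sex: int = MIN_PER_SEX,
) -> tuple[pd.Series, ScalingParams]:
    """Full adult scaling chain: residualize -> per-sex Box-Cox -> N(0,1)."""
    resid = residualize_trait(df[trait], df[sex_col], df[age_col])
    scaled, params = boxcox_per_sex(
        resid, df[sex_col].to_numpy(), trait=trait, min_per_sex=min_per_sex
    )
    return pd.Series(scaled, index=df.index, name=f"{trait}_scaled"), params


# ---------------------------------------------------------------------------
# pediatric LMS z-scores


class LmsReference:
    """Growth reference rows (sex, age, L, M, S) with linear age interpolation."""

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age", "L", "M", "S"}
        if not required.issubset(table.columns):
            raise ValueError(f"LMS table needs columns {sorted(required)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("LMS reference requires M > 0 and S > 0")
        for s, sub in table.groupby("sex"):
            ages = sub["age"].to_numpy()
            if not np.all(np.diff(ages) > 0):
                raise ValueError(f"ages not strictly increasing for sex {s!r}")
        self.table = table.sort_values(["sex", "age"]).reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path, trait: str | None = None) -> "LmsReference":
        df = pd.read_csv(path, sep="\t")
        if trait is not None:
            df = df[df["trait"] == trait].drop(columns="trait")
        return cls(df)

    @classmethod
    def packaged(cls, trait: str) -> "LmsReference":
        """Packaged synthetic LMS reference (for tests/demos; not WHO/CDC data)."""
        with resources.as_file(
            resources.files("cnvdose.data").joinpath("lms_reference_synthetic.tsv")
        ) as p:
            return cls.from_tsv(p, trait=trait)

    def lms_at(self, age, sex) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        age = np.atleast_1d(np.asarray(age, dtype=float))
        sex = np.atleast_1d(np.asarray(sex))
        L = np.empty_like(age)
        M = np.empty_like(age)
        S = np.empty_like(age)
        for s in pd.unique(sex):
            sub = self.table[self.table["sex"] == s]
            if sub.empty:
                raise ValueError(f"no reference rows for sex {s!r}")
            a = sub["age"].to_numpy()
            mask = sex == s
            if (age[mask] < a[0]).any() or (age[mask] > a[-1]).any():
                raise ValueError(
                    f"age outside reference range [{a[0]}, {a[-1]}] for sex {s!r}"
                )
            L[mask] = np.interp(age[mask], a, sub["L"].to_numpy())
            M[mask] = np.interp(age[mask], a, sub["M"].to_numpy())
            S[mask] = np.interp(age[mask], a, sub["S"].to_numpy())
        return L, M, S


def pediatric_zscore(value, age, sex, ref: LmsReference) -> np.ndarray:
    """LMS z-score: z = ((value/M)^L - 1) / (L*S), with the log limit at L=0."""
    value = np.atleast_1d(np.asarray(value, dtype=float))
    L, M, S = ref.lms_at(age, sex)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            np.abs(L) < 1e-10,
            np.log(value / M) / S,
            ((value / M) ** L - 1.0) / (L * S),
        )
    return z if z.shape else float(z)


def lms_value_from_z(z, age, sex, ref: LmsReference) -> np.ndarray:
    """Inverse LMS: the measurement whose z-score is ``z`` at (age, sex)."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    L, M, S = ref.lms_at(age, sex)
    return np.where(
        np.abs(L) < 1e-10,
        M * np.exp(S * z),
        M * (1.0 + L * S * z) ** (1.0 / L),
    )
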