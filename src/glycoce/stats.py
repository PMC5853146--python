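"""Cohort statistics for IgG galactosylation traits.

Implements the analysis battery used for hypogalactosylation studies across
RA / axSpA / healthy-control cohorts: nonparametric group comparisons
(Mann-Whitney U, Kruskal-Wallis with Dunn's post hoc), covariate-adjusted
regression (linear primary, logistic variant), disease-activity slope
heterogeneity across serostatus strata, categorical stratification (age, CRP,
disease-duration quartiles), treatment contrasts, transcript fold changes,
and Bonferroni correction for a family of 12 secondary hypotheses.

"Correlation with disease activity" is operationalized as the OLS slope of
the trait on the activity marker with heteroskedasticity-robust (HC3)
standard errors; heterogeneity between strata is the robust Wald test of the
activity x stratum interaction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "KruskalDunnResult",
    "RegressionFit",
    "HeterogeneityResult",
    "TreatmentContrast",
    "FoldChange",
    "SingularityError",
    "mann_whitney",
    "kruskal_dunn",
    "adjusted_comparison",
    "slope_heterogeneity",
    "bonferroni",
    "apply_bonferroni",
    "categorize",
    "treatment_contrast",
    "expression_fold_change",
    "add_seropositive",
    "BONFERRONI_M",
]

# number of secondary hypotheses in the pre-specified testing family
BONFERRONI_M = 12


class SingularityError(ValueError):
    """Raised when a regression design matrix is rank deficient."""


# ------------------------------------------------------------------ results


@dataclass
class GroupComparison:
    groups: tuple[str, ...]
    n: tuple[int, ...]
    medians: tuple[float, ...]
    iqrs: tuple[tuple[float, float], ...]
    test_name: str
    statistic: float
    p_value: float
    p_bonferroni: Optional[float] = None
    bonferroni_m: Optional[int] = None


@dataclass
class KruskalDunnResult:
    groups: tuple[str, ...]
    h_statistic: float
    p_omnibus: float
    pairwise: list[GroupComparison]


@dataclass
class RegressionFit:
    model: str  # "ols" | "logistic"
    outcome: str
    terms: tuple[str, ...]
    params: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    n_used: int
    n_dropped: int


@dataclass
class HeterogeneityResult:
    stratum_variable: str
    activity_marker: str
    strata: tuple[str, ...]
    slopes: dict[str, tuple[float, float, float]]  # level -> (slope, lo, hi)
    interaction_coef: float
    p_value: float
    p_bonferroni: Optional[float] = None
    bonferroni_m: Optional[int] = None


@dataclass
class TreatmentContrast:
    drug: str
    n_treated: int
    n_untreated: int
    unadjusted: dict[str, GroupComparison]  # by outcome
    adjusted: dict[str, RegressionFit]


@dataclass
class FoldChange:
    gene: str
    pop_a: str
    pop_b: str
    value: float  # NaN when undefined
    defined: bool


# ----------------------------------------------------------------- helpers


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    return float(np.median(x)), (float(np.percentile(x, 25)), float(np.percentile(x, 75)))


def _as_sample(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 1:
        raise ValueError(f"sample {name!r} is empty")
    return a


def _encode_sex(s: pd.Series) -> np.ndarray:
    if s.dtype == object or str(s.dtype) == "category":
        return s.map({"F": 0.0, "M": 1.0}).to_numpy(dtype=float)
    return s.to_numpy(dtype=float)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [names[piv[i]] for i in range(len(names)) if i >= (diag > tol).sum()]
        raise SingularityError(f"design matrix is singular; collinear columns: {bad}")


# -------------------------------------------------------------- operations


def mann_whitney(x, y, group_names: tuple[str, str] = ("x", "y")) -> GroupComparison:
    """Two-sided Mann-Whitney U test with per-group medians and IQRs.

    Uses the exact null distribution (equivalent to full permutation
    enumeration) for small untied samples, the tie-corrected normal
    approximation otherwise.
    """
    a = _as_sample(x, group_names[0])
    b = _as_sample(y, group_names[1])
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    ma, ia = _median_iqr(a)
    mb, ib = _median_iqr(b)
    return GroupComparison(
        groups=group_names,
        n=(a.size, b.size),
        medians=(ma, mb),
        iqrs=(ia, ib),
        test_name=f"mann-whitney ({method})",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
    )


def kruskal_dunn(samples: Mapping[str, Sequence[float]]) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test followed by Dunn's pairwise z tests.

    Pairwise p values are multiplied by the number of comparisons
    (Bonferroni-style adjustment, reported in ``p_bonferroni``).
    Requires at least three groups.
    """
    names = list(samples.keys())
    if len(names) < 3:
        raise ValueError(f"kruskal_dunn requires >= 3 groups, got {len(names)}")
    arrays = [_as_sample(samples[g], g) for g in names]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = sps.kruskal(*arrays)

    # Dunn's test on pooled mid-ranks with tie correction
    ranks = sps.rankdata(pooled)
    n_tot = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(float(np.mean(ranks[start : start + a.size])))
        sizes.append(a.size)
        start += a.size
    k = len(names)
    m_comp = k * (k - 1) // 2
    pairwise = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        mi, ii = _median_iqr(arrays[i])
        mj, ij = _median_iqr(arrays[j])
        pairwise.append(
            GroupComparison(
                groups=(names[i], names[j]),
                n=(sizes[i], sizes[j]),
                medians=(mi, mj),
                iqrs=(ii, ij),
                test_name="dunn",
                statistic=float(z),
                p_value=float(min(p, 1.0)),
                p_bonferroni=float(min(1.0, p * m_comp)),
                bonferroni_m=m_comp,
            )
        )
    return KruskalDunnResult(
        groups=tuple(names), h_statistic=float(h), p_omnibus=float(p_omni), pairwise=pairwise
    )


def bonferroni(p: float, m: int = BONFERRONI_M) -> float:
    """Bonferroni-adjusted p value: ``min(1, m * p)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, m * p)


def apply_bonferroni(result, m: int = BONFERRONI_M):
    """Populate ``p_bonferroni`` on a comparison result, guarding against a
    second (compounding) application."""
    if result.p_bonferroni is not None:
        raise ValueError("Bonferroni correction already applied to this result")
    result.p_bonferroni = bonferroni(result.p_value, m)
    result.bonferroni_m = m
    return result


def _complete_cases(df: pd.DataFrame, cols: Sequence[str]) -> tuple[pd.DataFrame, int]:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = df.dropna(subset=list(cols))
    return sub, len(df) - len(sub)


def adjusted_comparison(
    df: pd.DataFrame,
    outcome: str,
    group_var: str,
    covariates: Sequence[str] = ("age", "sex"),
    reference_group: Optional[str] = None,
    model: str = "ols",
) -> RegressionFit:
    """Covariate-adjusted group comparison.

    Primary model (``model='ols'``): linear regression of the trait on group
    indicators plus covariates; group coefficients are adjusted differences
    versus the reference group.  Documented variant (``model='logistic'``):
    logistic regression of membership in the non-reference group (two groups
    only) on the trait plus covariates.

    Rows with missing values in any used column are dropped (complete-case;
    the count is reported in ``n_dropped``).
    """
    cols = [outcome, group_var, *covariates]
    sub, n_dropped = _complete_cases(df, cols)
    levels = sorted(map(str, sub[group_var].astype(str).unique()))
    if len(levels) < 2:
        raise ValueError(f"group variable {group_var!r} has fewer than 2 levels")
    ref_level = str(reference_group) if reference_group is not None else levels[0]
    if ref_level not in levels:
        raise ValueError(f"reference group {ref_level!r} not among levels {levels}")

    cov_cols = []
    cov_names = []
    for c in covariates:
        v = _encode_sex(sub[c]) if c == "sex" else sub[c].to_numpy(dtype=float)
        cov_cols.append(v)
        cov_names.append(c)

    g = sub[group_var].astype(str).to_numpy()
    if model == "ols":
        dummies = [(f"{group_var}[{lv}]", (g == lv).astype(float)) for lv in levels if lv != ref_level]
        names = ["intercept", *[d[0] for d in dummies], *cov_names]
        X = np.column_stack([np.ones(len(sub)), *[d[1] for d in dummies], *cov_cols])
        y = sub[outcome].to_numpy(dtype=float)
        _check_rank(X, names)
        fit = sm.OLS(y, X).fit()
    elif model == "logistic":
        if len(levels) != 2:
            raise ValueError("logistic variant requires exactly 2 groups")
        other = [lv for lv in levels if lv != ref_level][0]
        names = ["intercept", outcome, *cov_names]
        X = np.column_stack([np.ones(len(sub)), sub[outcome].to_numpy(dtype=float), *cov_cols])
        y = (g == other).astype(float)
        _check_rank(X, names)
        fit = sm.Logit(y, X).fit(disp=0)
    else:
        raise ValueError(f"unknown model {model!r}")

    ci = np.asarray(fit.conf_int())
    return RegressionFit(
        model=model,
        outcome=outcome,
        terms=tuple(names),
        params={nm: float(v) for nm, v in zip(names, fit.params)},
        conf_int={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci)},
        pvalues={nm: float(v) for nm, v in zip(names, fit.pvalues)},
        n_used=len(sub),
        n_dropped=n_dropped,
    )


def slope_heterogeneity(
    df: pd.DataFrame,
    outcome: str,
    activity: str,
    stratum: str,
) -> HeterogeneityResult:
    """Test whether the trait-vs-activity slope differs between two strata.

    Fits ``outcome ~ activity * stratum`` by OLS with HC3 robust covariance;
    the heterogeneity p value is the robust Wald test of the interaction term.
    Per-stratum slopes with 95% CIs are derived from the joint fit.
    """
    sub, _ = _complete_cases(df, [outcome, activity, stratum])
    levels = sorted(sub[stratum].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"stratum {stratum!r} must have exactly 2 levels, got {levels}"
        )
    s = (sub[stratum].astype(str) == levels[1]).to_numpy(dtype=float)
    counts = (int((s == 0).sum()), int((s == 1).sum()))
    if min(counts) < 3:
        raise ValueError(f"each stratum needs n >= 3, got {dict(zip(levels, counts))}")
    a = sub[activity].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(a), a, s, a * s])
    _check_rank(X, ["intercept", activity, stratum, f"{activity}:{stratum}"])
    fit = sm.OLS(y, X).fit(cov_type="HC3")

    cov = np.asarray(fit.cov_params())
    tcrit = sps.t.ppf(0.975, df=len(y) - 4)
    slope0 = float(fit.params[1])
    se0 = math.sqrt(cov[1, 1])
    slope1 = float(fit.params[1] + fit.params[3])
    se1 = math.sqrt(cov[1, 1] + cov[3, 3] + 2 * cov[1, 3])
    slopes = {
        levels[0]: (slope0, slope0 - tcrit * se0, slope0 + tcrit * se0),
        levels[1]: (slope1, slope1 - tcrit * se1, slope1 + tcrit * se1),
    }
    return HeterogeneityResult(
        stratum_variable=stratum,
        activity_marker=activity,
        strata=tuple(levels),
        slopes=slopes,
        interaction_coef=float(fit.params[3]),
        p_value=float(fit.pvalues[3]),
    )


# ------------------------------------------------------------ stratification

AGE_BINS = (-np.inf, 25.0, 45.0, 65.0, np.inf)
AGE_LABELS = ("<=25", "25-45", "45-65", ">65")
CRP_BINS = (-np.inf, 5.0, 10.0, 15.0, np.inf)
CRP_LABELS = ("<5", "5-10", "10-15", ">15")


def categorize(df: pd.DataFrame, scheme: str) -> pd.Series:
    """Label subjects by a stratification scheme.

    * ``'age'``: <=25, 25-45, 45-65, >65 years; bins right-closed, so age 45
      falls in "25-45".
    * ``'crp'``: <5, 5-10, 10-15, >15 mg/L; bins left-closed to honour the
      strict "<5" label, so CRP 5.0 falls in "5-10".
    * ``'duration_quartiles'``: quartiles of disease duration at the sample
      25/50/75 percentiles, right-closed.
    """
    if scheme == "age":
        if "age" not in df.columns:
            raise ValueError("missing variable 'age'")
        return pd.cut(df["age"], bins=AGE_BINS, labels=AGE_LABELS, right=True)
    if scheme == "crp":
        if "crp" not in df.columns:
            raise ValueError("missing variable 'crp'")
        return pd.cut(df["crp"], bins=CRP_BINS, labels=CRP_LABELS, right=False)
    if scheme == "duration_quartiles":
        col = "disease_duration"
        if col not in df.columns:
            raise ValueError(f"missing variable {col!r}")
        x = df[col].astype(float)
        q = np.nanpercentile(x, [25, 50, 75])
        bins = np.concatenate([[-np.inf], q, [np.inf]])
        return pd.cut(x, bins=bins, labels=("Q1", "Q2", "Q3", "Q4"), right=True)
    raise ValueError(f"unknown scheme {scheme!r}")


def add_seropositive(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``seropositive`` column: RF-positive and/or ACPA-positive."""
    out = df.copy()
    rf = out["rf"].astype("boolean")
    acpa = out["acpa"].astype("boolean")
    out["seropositive"] = (rf | acpa).astype("boolean")
    return out


def treatment_contrast(df: pd.DataFrame, drug: str = "sulfasalazine") -> TreatmentContrast:
    """Compare treated vs untreated RA subjects on both hypogalactosylation
    outcomes: unadjusted Mann-Whitney plus an age/sex/CRP-adjusted linear
    model."""
    if "cohort" in df.columns:
        df = df[df["cohort"].astype(str) == "RA"]
    if drug not in df.columns:
        raise ValueError(f"missing treatment flag {drug!r}")
    flag = df[drug].astype(float)
    n_treated = int((flag == 1).sum())
    n_untreated = int((flag == 0).sum())
    if n_treated == 0 or n_untreated == 0:
        raise ValueError(
            f"treatment contrast needs both arms: treated={n_treated}, untreated={n_untreated}"
        )
    unadjusted: dict[str, GroupComparison] = {}
    adjusted: dict[str, RegressionFit] = {}
    for outcome in ("g0_g1_ratio", "g0_percent"):
        sub = df.dropna(subset=[outcome, drug])
        f = sub[drug].astype(float)
        unadjusted[outcome] = mann_whitney(
            sub.loc[f == 1, outcome],
            sub.loc[f == 0, outcome],
            group_names=(f"{drug}+", f"{drug}-"),
        )
        adjusted[outcome] = adjusted_comparison(
            df, outcome, drug, covariates=("age", "sex", "crp"), model="ols"
        )
    return TreatmentContrast(
        drug=drug,
        n_treated=n_treated,
        n_untreated=n_untreated,
        unadjusted=unadjusted,
        adjusted=adjusted,
    )


def expression_fold_change(
    expr: pd.DataFrame, gene: str, pop_a: str, pop_b: str
) -> FoldChange:
    """Fold change of mean normalized transcript intensity, ``pop_a / pop_b``.

    ``expr`` is tidy with columns ``gene``, ``population``, ``intensity`` (one
    row per replicate pool).  A zero denominator yields an undefined result
    (NaN, ``defined=False``) rather than an error.
    """
    for col in ("gene", "population", "intensity"):
        if col not in expr.columns:
            raise ValueError(f"expression table missing column {col!r}")
    sub = expr[expr["gene"] == gene]
    a = sub.loc[sub["population"] == pop_a, "intensity"].to_numpy(dtype=float)
    b = sub.loc[sub["population"] == pop_b, "intensity"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"populations {pop_a!r}/{pop_b!r} not found for gene {gene!r}")
    denom = float(np.mean(b))
    if denom == 0.0:
        return FoldChange(gene, pop_a, pop_b, math.nan, False)
    return FoldChange(gene, pop_a, pop_b, float(np.mean(a)) / denom, True)
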