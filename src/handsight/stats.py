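"""Statistical battery for ROI-level brain-behaviour inference.

Implements the analyses run on cohort-level score and ROI-measure vectors:
semi-partial ("part") Pearson correlations with permutation null
distributions, Fisher r-to-z comparison of two correlations, two-predictor
commonality analysis (unique / shared variance with nested-model F tests),
one-way ANCOVA with a subgroup covariate, and the standard group-comparison
tests (t, Mann-Whitney U, Shapiro-Wilk, Kolmogorov-Smirnov, 2x2 ANOVA).

Conventions used throughout:

* degrees of freedom for a correlation are reported as ``n - 2`` (the
  ``r(df)`` convention);
* permutation p-values use the add-one estimator ``(k + 1) / (B + 1)`` so
  that p is never exactly zero and has resolution ``1 / (B + 1)``;
* no multiple-testing correction is applied at the ROI level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PartCorrelationResult",
    "VariancePartition",
    "GroupComparison",
    "part_correlation",
    "permutation_pvalue",
    "fisher_rz_compare",
    "fisher_rz_compare_dependent",
    "commonality_two_predictor",
    "ancova_usage",
    "group_tests",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class PartCorrelationResult:
    """Semi-partial correlation between a score and a covariate-adjusted
    brain measure, optionally with a permutation p-value."""

    r_part: float
    df: int
    n: int
    p_perm: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    tails: str = "two"


@dataclass
class VariancePartition:
    """Commonality decomposition of a two-predictor regression.

    ``unique_x = R2_full - R2_z``, ``unique_z = R2_full - R2_x`` and
    ``shared = R2_x + R2_z - R2_full``; the three components sum to
    ``R2_full`` by construction.
    """

    R2_full: float
    R2_x: float
    R2_z: float
    unique_x: float
    unique_z: float
    shared: float
    F_change_x: float | None = None
    F_change_z: float | None = None
    df_change: tuple[int, int] | None = None
    p_change_x: float | None = None
    p_change_z: float | None = None


@dataclass
class GroupComparison:
    """A single hypothesis test: statistic, dof where applicable, p."""

    kind: str
    statistic: float
    p: float
    dof: float | tuple[float, ...] | None = None
    tails: str = "two"
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_clean_vector(v, name: str) -> np.ndarray:
    out = np.asarray(v, dtype=float).ravel()
    if out.size < 2:
        raise ValueError(f"{name} must have at least 2 elements")
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{name} contains non-finite values")
    return out


def _check_nonconstant(v: np.ndarray, name: str) -> None:
    if np.ptp(v) == 0:
        raise ValueError(f"{name} is constant; correlation undefined")


def residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """OLS residuals of ``y`` on ``z`` with an intercept."""
    y = _as_clean_vector(y, "y")
    z = _as_clean_vector(z, "z")
    if y.size != z.size:
        raise ValueError("y and z must have equal length")
    _check_nonconstant(z, "covariate")
    X = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ---------------------------------------------------------------------------
# part correlation + permutation test
# ---------------------------------------------------------------------------

def part_correlation(x, y, covariate) -> PartCorrelationResult:
    """Semi-partial Pearson correlation of ``x`` with ``y`` adjusted for a
    covariate.

    The covariate is regressed out of the brain measure ``y`` only (not out
    of the score ``x``); the returned value is the plain Pearson correlation
    between ``x`` and those residuals. Reported df follows the ``n - 2``
    convention.
    """
    x = _as_clean_vector(x, "x")
    y = _as_clean_vector(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need n >= 4 for a part correlation")
    _check_nonconstant(x, "x")
    resid = residualize(y, covariate)
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, float(np.abs(y).max()))):
        raise ValueError("covariate explains y exactly; zero residual variance")
    r = float(np.corrcoef(x, resid)[0, 1])
    return PartCorrelationResult(r_part=r, df=x.size - 2, n=x.size)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def permutation_pvalue(
    x,
    y,
    covariate,
    n_permutations: int = 10_000,
    tails: str = "two",
    seed: int | None = None,
) -> PartCorrelationResult:
    """Permutation p-value for the part correlation of ``x`` with adjusted
    ``y``.

    Only the score vector ``x`` is permuted; the covariate-adjusted brain
    measure stays fixed, so each draw re-computes the same semi-partial
    statistic under a random relabelling of subjects.  p is the add-one
    estimator ``(1 + #{|r*| >= |r_obs|}) / (B + 1)`` (two-tailed), or the
    one-sided analogue on the signed statistic.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    base = part_correlation(x, y, covariate)
    x = _as_clean_vector(x, "x")
    resid = residualize(_as_clean_vector(y, "y"), covariate)

    # r(x_perm, e) for all permutations at once: with both vectors
    # standardized, r = <x_perm, e_std> / n
    e = _standardize(resid)
    xs = _standardize(x)
    n = x.size
    rng = np.random.default_rng(seed)
    B = int(n_permutations)
    if B < 1:
        raise ValueError("n_permutations must be >= 1")
    perms = np.argsort(rng.random((B, n)), axis=1)
    r_null = (xs[perms] @ e) / n
    r_obs = float(xs @ e) / n

    if tails == "two":
        k = int(np.sum(np.abs(r_null) >= abs(r_obs) - 1e-15))
    else:
        k = int(np.sum(r_null >= r_obs - 1e-15))
    p = (1 + k) / (B + 1)
    return PartCorrelationResult(
        r_part=base.r_part,
        df=base.df,
        n=base.n,
        p_perm=p,
        n_permutations=B,
        seed=seed,
        tails=tails,
    )


# ---------------------------------------------------------------------------
# Fisher r-to-z comparison of two correlations
# ---------------------------------------------------------------------------

def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int,
                      tails: str = "two") -> GroupComparison:
    """Compare two independent correlations with the Fisher r-to-z test.

    ``Z = (arctanh r1 - arctanh r2) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    normal reference distribution. One-tailed tests assess ``r1 > r2``.
    """
    for r, n, lbl in ((r1, n1, "r1"), (r2, n2, "r2")):
        if abs(r) >= 1:
            raise ValueError(f"|{lbl}| must be < 1")
        if n <= 3:
            raise ValueError("each sample needs n > 3")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = float((np.arctanh(r1) - np.arctanh(r2)) / se)
    if tails == "two":
        p = float(2 * sps.norm.sf(abs(z)))
    else:
        p = float(sps.norm.sf(z))
    return GroupComparison(kind="fisher_rz", statistic=z, p=p, tails=tails)


def fisher_rz_compare_dependent(r1: float, r2: float, r12: float,
                                n: int, tails: str = "two") -> GroupComparison:
    """Steiger-style comparison of two correlations sharing one variable
    measured on the same ``n`` subjects (``r12`` is the correlation between
    the two other variables). Stricter alternative to the independent-samples
    formula when the samples overlap completely."""
    for r, lbl in ((r1, "r1"), (r2, "r2"), (r12, "r12")):
        if abs(r) >= 1:
            raise ValueError(f"|{lbl}| must be < 1")
    if n <= 4:
        raise ValueError("need n > 4")
    rbar = 0.5 * (r1 + r2)
    # Steiger (1980) Z2*, using the backtransformed average correlation
    det = (1 - r1 ** 2 - r2 ** 2 - r12 ** 2) + 2 * r1 * r2 * r12
    psi = r12 * (1 - 2 * rbar ** 2) - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r12 ** 2)
    s = psi / (1 - rbar ** 2) ** 2
    z = float((np.arctanh(r1) - np.arctanh(r2)) *
              np.sqrt((n - 3) / (2 * (1 - s))))
    if tails == "two":
        p = float(2 * sps.norm.sf(abs(z)))
    else:
        p = float(sps.norm.sf(z))
    return GroupComparison(kind="fisher_rz_dependent", statistic=z, p=p,
                           tails=tails, extra={"determinant": det})


# ---------------------------------------------------------------------------
# commonality analysis
# ---------------------------------------------------------------------------

def _r2_single(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(pred, y)[0, 1] ** 2)


def commonality_two_predictor(
    x=None,
    z=None,
    y=None,
    *,
    R2_x: float | None = None,
    R2_z: float | None = None,
    r_xz: float | None = None,
    n: int | None = None,
) -> VariancePartition:
    """Unique and shared explained variance of two predictors of ``y``.

    Two input forms:

    * data vectors ``x, z, y``: R² values come from the actual OLS fits
      (full model ``y ~ x + z`` and the two single-predictor models);
    * summary form ``R2_x, R2_z, r_xz`` (positive-root convention for the
      implied predictor-criterion correlations): the full-model R² is the
      closed form ``(r_xy² + r_zy² - 2 r_xy r_zy r_xz) / (1 - r_xz²)``.

    The partition follows the nested-model identities
    ``unique_x = R2_full - R2_z``, ``unique_z = R2_full - R2_x``,
    ``shared = R2_x + R2_z - R2_full``. When ``n`` is known, ΔR² F tests are
    reported with ``F = ΔR² / ((1 - R2_full) / (n - 3))`` on (1, n-3) df.
    """
    if x is not None:
        x = _as_clean_vector(x, "x")
        z = _as_clean_vector(z, "z")
        y = _as_clean_vector(y, "y")
        if not (x.size == z.size == y.size):
            raise ValueError("x, z, y must have equal length")
        r_xz_val = float(np.corrcoef(x, z)[0, 1])
        if abs(r_xz_val) > 1 - 1e-12:
            raise ValueError("predictors are collinear")
        n = x.size
        R2_x = _r2_single(x, y)
        R2_z = _r2_single(z, y)
        X = np.column_stack([np.ones(n), x, z])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        R2_full = 1.0 - float(np.sum(resid ** 2)) / tss
    else:
        if R2_x is None or R2_z is None or r_xz is None:
            raise ValueError("provide either data vectors or R2_x, R2_z, r_xz")
        if not (0 <= R2_x < 1 and 0 <= R2_z < 1):
            raise ValueError("R2 inputs must lie in [0, 1)")
        if abs(r_xz) >= 1:
            raise ValueError("|r_xz| must be < 1")
        r_xy = np.sqrt(R2_x)
        r_zy = np.sqrt(R2_z)
        R2_full = float(
            (r_xy ** 2 + r_zy ** 2 - 2 * r_xy * r_zy * r_xz) / (1 - r_xz ** 2)
        )

    unique_x = R2_full - R2_z
    unique_z = R2_full - R2_x
    shared = R2_x + R2_z - R2_full

    part = VariancePartition(
        R2_full=float(R2_full), R2_x=float(R2_x), R2_z=float(R2_z),
        unique_x=float(unique_x), unique_z=float(unique_z),
        shared=float(shared),
    )
    if n is not None and n > 3:
        denom = (1.0 - R2_full) / (n - 3)
        part.F_change_x = float(unique_x / denom)
        part.F_change_z = float(unique_z / denom)
        part.df_change = (1, n - 3)
        part.p_change_x = float(sps.f.sf(max(part.F_change_x, 0.0), 1, n - 3))
        part.p_change_z = float(sps.f.sf(max(part.F_change_z, 0.0), 1, n - 3))
    return part


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

def ancova_usage(y, usage, subgroup) -> dict[str, GroupComparison]:
    """One-way ANCOVA: brain measure ~ usage (continuous) + subgroup
    (categorical covariate), partial (Type-III) F per term."""
    y = _as_clean_vector(y, "y")
    usage = _as_clean_vector(usage, "usage")
    sub = np.asarray(subgroup)
    if not (y.size == usage.size == sub.size):
        raise ValueError("inputs must have equal length")
    levels, counts = np.unique(sub, return_counts=True)
    if levels.size < 2:
        raise ValueError("subgroup needs at least 2 levels")
    if np.any(counts < 2):
        raise ValueError("each subgroup level needs at least 2 members")
    _check_nonconstant(usage, "usage")
    df = pd.DataFrame({"y": y, "usage": usage, "subgroup": sub.astype(str)})
    model = smf.ols("y ~ usage + C(subgroup)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    out: dict[str, GroupComparison] = {}
    df_resid = float(model.df_resid)
    for term, key in (("usage", "usage"), ("C(subgroup)", "subgroup")):
        F = float(table.loc[term, "F"])
        p = float(table.loc[term, "PR(>F)"])
        d1 = float(table.loc[term, "df"])
        out[key] = GroupComparison(kind="ancova_F", statistic=F, p=p,
                                   dof=(d1, df_resid))
    out["model"] = GroupComparison(
        kind="ancova_model", statistic=float(model.fvalue),
        p=float(model.f_pvalue),
        dof=(float(model.df_model), df_resid),
        extra={"R2": float(model.rsquared)},
    )
    return out


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def group_tests(a, b=None, kind: str = "t", **kwargs) -> GroupComparison:
    """Standard two-sample (or one-sample, for ``shapiro``) tests.

    kind:
        ``t``            two-tailed independent-samples Student's t
        ``mann_whitney`` Mann-Whitney U (two-tailed)
        ``shapiro``      Shapiro-Wilk normality test on ``a`` alone
        ``ks``           independent-samples two-tailed Kolmogorov-Smirnov
        ``anova2x2``     2x2 between-subjects ANOVA; pass ``values``,
                         ``factor_a``, ``factor_b`` as keyword arrays
    """
    if kind == "anova2x2":
        return _anova_2x2(**kwargs)
    a = _as_clean_vector(a, "a")
    if kind == "shapiro":
        if a.size < 3:
            raise ValueError("shapiro needs n >= 3")
        w, p = sps.shapiro(a)
        return GroupComparison(kind="shapiro", statistic=float(w), p=float(p))
    if b is None:
        raise ValueError(f"kind={kind!r} needs two samples")
    b = _as_clean_vector(b, "b")
    if kind == "t":
        t, p = sps.ttest_ind(a, b)
        return GroupComparison(kind="t", statistic=float(t), p=float(p),
                               dof=a.size + b.size - 2)
    if kind == "mann_whitney":
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(kind="mann_whitney", statistic=float(u),
                               p=float(p))
    if kind == "ks":
        d, p = sps.ks_2samp(a, b)
        # the classical KS Z statistic, as printed alongside D in older
        # statistics packages: Z = D * sqrt(n1*n2/(n1+n2))
        z = float(d * np.sqrt(a.size * b.size / (a.size + b.size)))
        return GroupComparison(kind="ks", statistic=float(d), p=float(p),
                               extra={"Z": z})
    raise ValueError(f"unknown test kind: {kind!r}")


def _anova_2x2(values=None, factor_a=None, factor_b=None) -> GroupComparison:
    if values is None or factor_a is None or factor_b is None:
        raise ValueError("anova2x2 needs values, factor_a, factor_b")
    v = _as_clean_vector(values, "values")
    df = pd.DataFrame({
        "y": v,
        "A": np.asarray(factor_a).astype(str),
        "B": np.asarray(factor_b).astype(str),
    })
    if df["A"].nunique() != 2 or df["B"].nunique() != 2:
        raise ValueError("both factors must have exactly 2 levels")
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    extra = {}
    for term, key in (("C(A)", "A"), ("C(B)", "B"), ("C(A):C(B)", "interaction")):
        extra[key] = {
            "F": float(table.loc[term, "F"]),
            "p": float(table.loc[term, "PR(>F)"]),
            "df": (float(table.loc[term, "df"]), float(model.df_resid)),
        }
    return GroupComparison(
        kind="anova2x2", statistic=extra["A"]["F"], p=extra["A"]["p"],
        dof=extra["A"]["df"], extra=extra,
    )
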