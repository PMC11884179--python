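"""Permutation-based group and age statistics on the ROI metric table.

The inference layer mirrors a ROI-based neuroimaging study design:

* one-way permutation ANCOVA per variable — group as predictor, age and
  sex as covariates — for between-group differences;
* nonparametric (permutation) partial correlations — age as predictor,
  sex as covariate — run separately per group for age associations;
* a quadratic follow-up model with age and age-squared as predictors;
* Benjamini-Hochberg FDR applied separately within each metric x tissue
  family (q < 0.05);
* pooled-variance t and Pearson chi-square tests for demographic tables;
* per-lobe dispersion summaries of R^2 and beta.

All permutation tests use the Freedman-Lane scheme: the reduced
(covariate-only) model is fitted, its residuals are permuted, and the
full-model statistic is recomputed on each permuted response, giving
p = (1 + #{|t*| >= |t|}) / (1 + N).  Permutation streams are seeded per
variable from a master seed, so full-table runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .roi import ROI_LOBES, parse_variable, variable_family

DEFAULT_Q = 0.05


@dataclass(frozen=True)
class PermutationPlan:
    """Number of permutations, master seed, and the permutation scheme."""

    n_permutations: int = 5000
    seed: int = 0
    scheme: str = "freedman_lane"

    def __post_init__(self) -> None:
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        if self.scheme != "freedman_lane":
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")

    def rng_for(self, variable: str, group: str | None = None) -> np.random.Generator:
        """Independent, reproducible stream per (variable, group)."""
        key = [self.seed] + [ord(c) for c in variable]
        if group:
            key += [ord(c) for c in group]
        return np.random.default_rng(np.random.SeedSequence(key))


@dataclass
class StatResult:
    """One variable's test result.

    ``statistic`` is a t statistic (ANCOVA, quadratic term) or the
    partial correlation r; ``beta`` the relevant slope in metric units;
    ``r2`` the goodness of fit of the predictor of interest; ``p_perm``
    the permutation p-value; ``q_flag`` whether the variable survives
    FDR within ``family``.
    """

    variable: str
    statistic: float
    beta: float
    r2: float
    p_perm: float
    n: int
    family: str | None = None
    group: str | None = None
    q_flag: bool | None = None


def _encode(series: pd.Series) -> np.ndarray:
    """Binary-encode a two-level categorical column as 0/1."""
    levels = sorted(series.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 levels, got {levels}")
    return (series == levels[1]).to_numpy(dtype=float)


def _covariate_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in covariates:
        s = df[c]
        cols.append(_encode(s) if s.dtype == object else s.to_numpy(dtype=float))
    return np.column_stack(cols)


def _perm_indices(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    return np.argsort(rng.random((n_perm, n)), axis=1)


def _freedman_lane_t(
    y: np.ndarray,
    Z: np.ndarray,
    X: np.ndarray,
    rng: np.random.Generator,
    n_perm: int,
) -> tuple[float, float, float, float]:
    """Permutation t-test for the last column of X, covariates Z.

    Returns (t_obs, p_perm, beta_obs, partial_R2_obs).  With zero
    permutations p = 1 and t reduces to the parametric statistic.
    """
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} too small for {p} parameters")
    Xp = np.linalg.pinv(X)
    XtX_inv = np.linalg.pinv(X.T @ X)
    c = XtX_inv[-1, -1]
    Zp = np.linalg.pinv(Z)

    def t_of(Y: np.ndarray) -> np.ndarray:
        # Y: (m, n) responses; returns (m,) t statistics for the last coef
        beta = Y @ Xp.T
        resid = Y - beta @ X.T
        sigma2 = np.sum(resid**2, axis=-1) / (n - p)
        return beta[..., -1] / np.sqrt(np.maximum(sigma2 * c, 1e-300))

    yv = y[None, :]
    t_obs = float(t_of(yv)[0])
    beta_full = (yv @ Xp.T)[0]
    beta_obs = float(beta_full[-1])
    # partial R^2 of the tested term: drop in RSS relative to reduced model
    fit_red = (Zp @ y) @ Z.T
    e_red = y - fit_red
    rss_red = float(e_red @ e_red)
    if rss_red <= 1e-12 * max(1.0, float(y @ y)):
        # response fully explained by covariates: nothing left to test
        return 0.0, 1.0, 0.0, 0.0
    resid_full = y - (yv @ Xp.T)[0] @ X.T
    rss_full = float(resid_full @ resid_full)
    r2 = 0.0 if rss_red <= 0 else max(0.0, 1.0 - rss_full / rss_red)

    if n_perm == 0:
        return t_obs, 1.0, beta_obs, r2
    idx = _perm_indices(rng, n_perm, n)
    y_star = fit_red[None, :] + e_red[idx]
    t_star = t_of(y_star)
    p = (1.0 + np.sum(np.abs(t_star) >= np.abs(t_obs) - 1e-12)) / (1.0 + n_perm)
    return t_obs, float(p), beta_obs, r2


def permutation_ancova(
    table: pd.DataFrame,
    variable: str,
    plan: PermutationPlan = PermutationPlan(),
    group_col: str = "group",
    covariates: Sequence[str] = ("age_years", "sex"),
) -> StatResult:
    """Group-difference ANCOVA with Freedman-Lane permutation inference.

    Fits ``variable ~ group + age + sex`` after listwise deletion;
    the reported beta is the group contrast in metric units.
    """
    df = table[[variable, group_col, *covariates]].dropna()
    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    counts = df[group_col].value_counts()
    if counts.min() < 3:
        raise ValueError(f"need n >= 3 per group, got {counts.to_dict()}")
    y = df[variable].to_numpy(dtype=float)
    Z = _covariate_matrix(df, covariates)
    g = _encode(df[group_col])
    X = np.column_stack([Z, g])
    rng = plan.rng_for(variable)
    t, p, beta, r2 = _freedman_lane_t(y, Z, X, rng, plan.n_permutations)
    return StatResult(
        variable=variable, statistic=t, beta=beta, r2=r2, p_perm=p,
        n=len(df), family=_family_or_none(variable),
    )


def permutation_partial_correlation(
    table: pd.DataFrame,
    variable: str,
    plan: PermutationPlan = PermutationPlan(),
    predictor: str = "age_years",
    covariates: Sequence[str] = ("sex",),
    group: str | None = None,
    group_col: str = "group",
) -> StatResult:
    """Permutation partial correlation of ``variable`` with ``predictor``.

    Both response and predictor are residualized on the covariates;
    r is the correlation of the residuals, beta the slope of the
    residual-on-residual regression (metric units per predictor unit),
    R^2 = r^2.  Permutations shuffle the predictor residuals
    (re-residualizing after each shuffle).  If ``group`` is given, the
    analysis is restricted to that group's rows.
    """
    df = table
    if group is not None:
        df = df[df[group_col] == group]
    df = df[[variable, predictor, *covariates]].dropna()
    n = len(df)
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    y = df[variable].to_numpy(dtype=float)
    x = df[predictor].to_numpy(dtype=float)
    Z = _covariate_matrix(df, covariates)
    H = Z @ np.linalg.pinv(Z)
    ry = y - H @ y
    rx = x - H @ x
    sy, sx = np.linalg.norm(ry), np.linalg.norm(rx)
    if sy <= 1e-12 * max(1.0, float(np.linalg.norm(y))) or sx <= 1e-12 * max(
        1.0, float(np.linalg.norm(x))
    ):
        raise ValueError(f"zero residual variance for {variable!r}")
    r_obs = float(ry @ rx / (sy * sx))
    beta = float(ry @ rx / (sx**2))
    r2 = r_obs**2

    n_perm = plan.n_permutations
    if n_perm == 0:
        p = 1.0
    else:
        rng = plan.rng_for(variable, group)
        idx = _perm_indices(rng, n_perm, n)
        rx_p = rx[idx]
        rx_p = rx_p - rx_p @ H.T
        num = rx_p @ ry
        denom = np.linalg.norm(rx_p, axis=1) * sy
        r_star = num / np.maximum(denom, 1e-300)
        p = float(
            (1.0 + np.sum(np.abs(r_star) >= abs(r_obs) - 1e-12)) / (1.0 + n_perm)
        )
    return StatResult(
        variable=variable, statistic=r_obs, beta=beta, r2=r2, p_perm=p,
        n=n, family=_family_or_none(variable), group=group,
    )


def quadratic_age_model(
    table: pd.DataFrame,
    variable: str,
    plan: PermutationPlan = PermutationPlan(),
    age_col: str = "age_years",
    covariates: Sequence[str] = ("sex",),
    group: str | None = None,
    group_col: str = "group",
) -> StatResult:
    """Permutation test of the age-squared term.

    Full model: variable ~ age_c + age_c^2 + sex, with age centered
    before squaring to reduce collinearity; the reduced model drops the
    quadratic term (Freedman-Lane).
    """
    df = table
    if group is not None:
        df = df[df[group_col] == group]
    df = df[[variable, age_col, *covariates]].dropna()
    if len(df) < 5:
        raise ValueError(f"need n >= 5, got {len(df)}")
    age = df[age_col].to_numpy(dtype=float)
    age_c = age - age.mean()
    y = df[variable].to_numpy(dtype=float)
    Z = np.column_stack([_covariate_matrix(df, covariates), age_c])
    X = np.column_stack([Z, age_c**2])
    rng = plan.rng_for(variable, (group or "") + ":quad")
    t, p, beta, r2 = _freedman_lane_t(y, Z, X, rng, plan.n_permutations)
    return StatResult(
        variable=variable, statistic=t, beta=beta, r2=r2, p_perm=p,
        n=len(df), family=_family_or_none(variable), group=group,
    )


def bh_fdr(p_values: Sequence[float], q: float = DEFAULT_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags for one test family."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def apply_family_fdr(results: Iterable[StatResult], q: float = DEFAULT_Q) -> list[StatResult]:
    """Set ``q_flag`` on each result, FDR-correcting within (family, group)."""
    results = list(results)
    keys = {(r.family, r.group) for r in results}
    for key in keys:
        members = [r for r in results if (r.family, r.group) == key]
        flags = bh_fdr([r.p_perm for r in members], q=q)
        for r, flag in zip(members, flags):
            r.q_flag = bool(flag)
    return results


def _family_or_none(variable: str) -> str | None:
    try:
        return variable_family(variable)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Demographic-table tests
# ---------------------------------------------------------------------------

def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample t from summary statistics (pooled variance by default)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_counts(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    arr = np.asarray(table, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Whole-table drivers and summaries
# ---------------------------------------------------------------------------

def run_group_analysis(
    table: pd.DataFrame,
    variables: Sequence[str],
    plan: PermutationPlan = PermutationPlan(),
    q: float = DEFAULT_Q,
) -> list[StatResult]:
    """Permutation ANCOVA over many variables with per-family FDR."""
    results = [permutation_ancova(table, v, plan) for v in variables]
    return apply_family_fdr(results, q=q)


def run_age_analysis(
    table: pd.DataFrame,
    variables: Sequence[str],
    plan: PermutationPlan = PermutationPlan(),
    groups: Sequence[str] = ("NT", "ASD"),
    q: float = DEFAULT_Q,
) -> list[StatResult]:
    """Per-group age partial correlations with per-(family, group) FDR."""
    results = [
        permutation_partial_correlation(table, v, plan, group=g)
        for g in groups
        for v in variables
    ]
    return apply_family_fdr(results, q=q)


def trait_correlation(
    table: pd.DataFrame,
    trait: str,
    variables: Sequence[str],
    plan: PermutationPlan = PermutationPlan(),
    group: str = "ASD",
    q: float = DEFAULT_Q,
) -> list[StatResult]:
    """Partial correlations between a trait score and selected variables.

    Restricted to one group (the trait is only defined there); the FDR
    family is exactly the supplied variable subset.
    """
    sub = table[table["group"] == group]
    if trait not in sub.columns or sub[trait].dropna().empty:
        raise ValueError(f"trait column {trait!r} missing or empty for group {group}")
    results = [
        permutation_partial_correlation(table, v, plan, predictor=trait, group=group)
        for v in variables
    ]
    for r in results:
        r.family = f"trait:{trait}"
    return apply_family_fdr(results, q=q)


def results_frame(results: Iterable[StatResult]) -> pd.DataFrame:
    """Tidy DataFrame of StatResults (one row per variable x group)."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "group": r.group,
                "family": r.family,
                "n": r.n,
                "statistic": r.statistic,
                "beta": r.beta,
                "R2": r.r2,
                "p_perm": r.p_perm,
                "q_flag": r.q_flag,
            }
            for r in results
        ]
    )


def dispersion_summary(
    results: Iterable[StatResult],
    lobes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group, per-lobe mean and SE of R^2 and beta.

    Rows cover every (group, lobe) cell plus an 'all' lobe per group and
    between-group difference rows (group = 'NT-ASD') of the means.
    ROI lobe membership comes from the trailing ROI name of each
    variable.  The sign of r is recorded alongside R^2.
    """
    lobes = dict(ROI_LOBES) if lobes is None else dict(lobes)
    rows = []
    for r in results:
        try:
            _, _, roi_name = parse_variable(r.variable)
        except (ValueError, IndexError):
            roi_name = r.variable
        lobe = lobes.get(roi_name)
        if lobe is None:
            continue
        rows.append(
            {"group": r.group, "lobe": lobe, "R2": r.r2, "beta": r.beta,
             "sign_r": float(np.sign(r.statistic))}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["group", "lobe", "n", "R2_mean", "R2_se", "beta_mean", "beta_se"]
        )

    def _agg(g: pd.DataFrame) -> dict:
        n = len(g)
        return {
            "n": n,
            "R2_mean": g["R2"].mean(),
            "R2_se": g["R2"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "beta_mean": g["beta"].mean(),
            "beta_se": g["beta"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "mean_sign_r": g["sign_r"].mean(),
        }

    out = []
    for group, gdf in df.groupby("group", dropna=False):
        for lobe, ldf in gdf.groupby("lobe"):
            out.append({"group": group, "lobe": lobe, **_agg(ldf)})
        out.append({"group": group, "lobe": "all", **_agg(gdf)})
    summary = pd.DataFrame(out)

    groups = [g for g in summary["group"].unique() if g is not None]
    if len(groups) == 2:
        g1, g2 = sorted(groups)  # e.g. ASD, NT
        for lobe in summary["lobe"].unique():
            a = summary[(summary["group"] == g2) & (summary["lobe"] == lobe)]
            b = summary[(summary["group"] == g1) & (summary["lobe"] == lobe)]
            if len(a) == 1 and len(b) == 1:
                out.append(
                    {
                        "group": f"{g2}-{g1}",
                        "lobe": lobe,
                        "n": int(a["n"].iloc[0]),
                        "R2_mean": float(a["R2_mean"].iloc[0] - b["R2_mean"].iloc[0]),
                        "R2_se": np.nan,
                        "beta_mean": float(
                            a["beta_mean"].iloc[0] - b["beta_mean"].iloc[0]
                        ),
                        "beta_se": np.nan,
                        "mean_sign_r": np.nan,
                    }
                )
        summary = pd.DataFrame(out)
    return summary.reset_index(drop=True)
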