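"""Group comparisons and mixed-effects modeling of per-cell metrics.

Treatment groups are compared metric by metric with two-sided
Kolmogorov–Smirnov tests, Bonferroni-corrected over the family of
comparisons declared in one run. Because cells from the same retina are
not independent, a linear mixed-effects model with a random intercept
per retina (experiment) — optionally with sex and cell-type interaction
terms — checks that condition effects are not artifacts of
retina-to-retina variability.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "GroupComparison",
    "MixedModelResult",
    "ks_two_sided",
    "bonferroni",
    "fit_mixed_effects",
    "summarize_conditions",
]


@dataclass
class GroupComparison:
    metric: str
    group1_label: str
    group2_label: str
    group1_mean: float
    group1_sem: float
    group2_mean: float
    group2_sem: float
    ks_statistic: float
    p_raw: float
    p_bonferroni: float
    n1: int
    n2: int


def ks_two_sided(sample1, sample2) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    Sup-distance between the empirical CDFs; the p-value uses the exact
    distribution when ``n1 * n2 <= 10_000`` and the asymptotic
    approximation otherwise.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("samples must be non-empty")
    method = "exact" if s1.size * s2.size <= 10_000 else "asymp"
    res = sps.ks_2samp(s1, s2, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: each p multiplied by the family size m,
    capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame  # coef, se, stat, p per term
    retina_variance: float  # random-intercept variance component
    residual_variance: float
    df_inference: str  # 'between-within' or 'normal'
    converged: bool
    model: object = None


def _check_design(df: pd.DataFrame, formula: str) -> None:
    import patsy

    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # identify the first collinear columns for the error message
        bad = []
        cols = X.values
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(cols[:, : j + 1]) <= np.linalg.matrix_rank(
                cols[:, :j]
            ):
                bad.append(X.columns[j])
        raise ValueError(f"singular fixed-effects design; collinear terms: {bad}")


def fit_mixed_effects(
    table: pd.DataFrame,
    response: str,
    condition_col: str = "condition",
    group_col: str = "retina_id",
    interactions: tuple[str, ...] = (),
    reml: bool = True,
    df_method: str = "between-within",
) -> MixedModelResult:
    """Linear mixed-effects fit with a random intercept per retina.

    Fixed effects: the treatment condition, plus optional
    condition-by-covariate interaction terms (e.g. sex, cell type).
    Fitting delegates to a restricted-maximum-likelihood solver
    (statsmodels ``MixedLM``).

    Fixed-effect p-values use a t reference with between-cluster degrees
    of freedom (``n_retinas - n_condition_levels``) by default: the
    condition varies between retinas, so the effective sample size is
    the number of retinas, and Monte-Carlo calibration at realistic
    retina counts shows the large-sample normal approximation
    (``df_method='normal'``) inflates the type-I error there.

    Raises
    ------
    ValueError
        If the fixed-effects design is singular (the collinear terms are
        named) or required columns are missing.
    """
    for col in (response, condition_col, group_col, *interactions):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    terms = [f"C({condition_col})"]
    terms += [f"C({condition_col}):C({c})" for c in interactions]
    formula = f"{response} ~ " + " + ".join(terms)
    _check_design(table, formula)

    model = smf.mixedlm(formula, table, groups=table[group_col])
    with warnings.catch_warnings():
        # boundary fits (zero retina variance) are legitimate under the null
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml)

    params = fit.fe_params
    se = fit.bse_fe
    stat = params / se
    n_groups = table[group_col].nunique()
    n_levels = table[condition_col].nunique()
    if df_method == "between-within":
        dof = max(n_groups - n_levels, 1)
        p = 2 * sps.t.sf(np.abs(stat), dof)
    elif df_method == "normal":
        p = 2 * sps.norm.sf(np.abs(stat))
    else:
        raise ValueError("df_method must be 'between-within' or 'normal'")
    fe = pd.DataFrame(
        {"coef": params, "se": se, "stat": stat, "p": p}
    )
    return MixedModelResult(
        fixed_effects=fe,
        retina_variance=float(np.asarray(fit.cov_re)[0, 0]),
        residual_variance=float(fit.scale),
        df_inference=df_method,
        converged=bool(fit.converged),
        model=fit,
    )


def summarize_conditions(
    per_cell_metrics: pd.DataFrame,
    metric: str,
    condition_col: str = "condition",
    comparisons: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-condition mean ± SEM plus pairwise KS tests, Bonferroni-corrected.

    ``comparisons`` defaults to all condition pairs; the Bonferroni
    family is exactly the set of comparisons run here. Returns a
    long-format table with one row per comparison (or per condition when
    only one condition is present).
    """
    if metric not in per_cell_metrics.columns:
        raise ValueError(f"unknown metric {metric!r}")
    df = per_cell_metrics[[condition_col, metric]].dropna()
    groups = {
        lvl: sub[metric].to_numpy() for lvl, sub in df.groupby(condition_col)
    }
    stats_by_group = {
        lvl: (
            float(np.mean(v)),
            float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
            len(v),
        )
        for lvl, v in groups.items()
    }
    if comparisons is None:
        comparisons = list(itertools.combinations(sorted(groups), 2))
    if not comparisons:
        return pd.DataFrame(
            [
                {
                    "metric": metric,
                    "group1": lvl,
                    "group1_mean": m,
                    "group1_sem": s,
                    "n1": n,
                }
                for lvl, (m, s, n) in stats_by_group.items()
            ]
        )
    rows = []
    raw_p = []
    for g1, g2 in comparisons:
        stat, p = ks_two_sided(groups[g1], groups[g2])
        m1, s1, n1 = stats_by_group[g1]
        m2, s2, n2 = stats_by_group[g2]
        rows.append(
            {
                "metric": metric,
                "group1": g1,
                "group1_mean": m1,
                "group1_sem": s1,
                "group2": g2,
                "group2_mean": m2,
                "group2_sem": s2,
                "ks_statistic": stat,
                "p_raw": p,
                "n1": n1,
                "n2": n2,
            }
        )
        raw_p.append(p)
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(raw_p)
    return out
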