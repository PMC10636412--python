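"""Statistical layer: linear trends across actions, Pearson correlations,
group-by-action interaction tests, and action-level grand-average
correlations.

Trends are pooled Pearson correlations between action index and measure over
all (infant, action) observations — the standardized slope of the simple
regression.  No repeated-measures structure is modeled; with four
observations per infant the pooled r understates within-infant dependence,
which is acceptable for the descriptive reporting style targeted here.
Interaction effect sizes are reported on an r scale as the signed square
root of the interaction term's partial R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


class StatsError(ValueError):
    pass


@dataclass
class TrendResult:
    measure: str
    group: str | None
    r: float
    p: float
    n: int
    slope: float


@dataclass
class InteractionResult:
    measure: str
    grouping: str
    r_interaction: float
    p: float
    n: int
    subgroup_analysis: str  # "justified" | "nearly_significant" | "not_justified"


def pearson(x, y) -> tuple[float, float]:
    """Product-moment r with a two-sided t-test p (n - 2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise StatsError(f"need >= 3 paired observations, got {len(x)}")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def trend_across_actions(
    df: pd.DataFrame,
    measure: str,
    group: str | None = None,
    action_col: str = "action",
) -> TrendResult:
    """Pooled Pearson r (and least-squares slope) of ``measure`` against the
    action index over (infant, action) observations; missing cells dropped."""
    sub = df[[action_col, measure]].dropna()
    if sub[action_col].nunique() < 2:
        raise StatsError("need observations from >= 2 actions")
    x = sub[action_col].to_numpy(dtype=float)
    y = sub[measure].to_numpy(dtype=float)
    r, p = pearson(x, y)
    slope = float(np.polyfit(x, y, 1)[0])
    return TrendResult(measure=measure, group=group, r=r, p=p, n=len(sub), slope=slope)


def interaction_test(
    df: pd.DataFrame,
    measure: str,
    group_col: str,
    action_col: str = "action",
    alpha: float = 0.05,
    near_alpha: float = 0.10,
) -> InteractionResult:
    """OLS ``measure ~ group + action + group x action``; the interaction
    effect size is sign(coef) * sqrt(partial R^2) with p from its t statistic.

    ``subgroup_analysis`` records whether per-group follow-up correlations are
    justified (p <= alpha), nearly so (p <= near_alpha), or not.
    """
    sub = df[[measure, group_col, action_col]].dropna()
    g = sub[group_col]
    if g.nunique() != 2:
        raise StatsError(f"{group_col} must be binary, has {g.nunique()} levels")
    codes = (g == sorted(g.unique())[-1]).astype(float).to_numpy()
    action = sub[action_col].to_numpy(dtype=float)
    y = sub[measure].to_numpy(dtype=float)
    X = sm.add_constant(
        np.column_stack([codes, action, codes * action]), has_constant="add"
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError("singular design matrix (empty group or collinear terms)")
    fit = sm.OLS(y, X).fit()
    t = fit.tvalues[3]
    p = float(fit.pvalues[3])
    partial_r2 = t * t / (t * t + fit.df_resid)
    r_int = float(np.sign(fit.params[3]) * np.sqrt(partial_r2))
    status = (
        "justified" if p <= alpha else "nearly_significant" if p <= near_alpha else "not_justified"
    )
    return InteractionResult(
        measure=measure,
        grouping=group_col,
        r_interaction=r_int,
        p=p,
        n=len(sub),
        subgroup_analysis=status,
    )


def grand_average_correlation(
    fas_by_action: dict[int, float], wecs_by_action: dict[int, float]
) -> tuple[float, float]:
    """Descriptive Pearson r over the 4 action-level cohort means.  Invariant
    under subtraction of a common baseline from the FAS means."""
    actions = sorted(fas_by_action)
    if actions != sorted(wecs_by_action) or len(actions) != 4:
        raise StatsError("need exactly 4 paired action-level means")
    f = [fas_by_action[a] for a in actions]
    w = [wecs_by_action[a] for a in actions]
    if any(not np.isfinite(v) for v in f + w):
        raise StatsError("missing action-level mean")
    return pearson(f, w)


def benjamini_hochberg(pvals: list[float]) -> list[float]:
    """Optional FDR adjustment (off by default in the pipeline)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = m - rank_from_end
        running = min(running, p[idx] * m / k)
        adj[idx] = running
    return adj.tolist()
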