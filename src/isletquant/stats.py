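"""Group comparisons and stage summaries.

Two-group comparisons use the classical equal-variance Student t-test
(Welch available as an option); multi-group comparisons use one-way ANOVA
followed by Dunnett's many-to-one test against a control group, with
adjusted p-values computed by seeded Monte-Carlo integration of the joint
multivariate-t distribution of the comparison statistics (exact for
unbalanced designs).  Summaries treat the islet (embryo) as the
statistical unit: per-islet responsive count and mean amplitude first,
then mean ± SEM across islets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["ComparisonResult", "StageSummary", "ttest_unpaired",
           "anova_dunnett", "dunnett_critical_value", "summarize_stage",
           "star_annotation"]


@dataclass
class ComparisonResult:
    groups: tuple[str, str]
    statistic: float
    df: float
    p_value: float
    stars: str
    p_adjusted: Optional[float] = None
    degenerate: bool = False


@dataclass
class StageSummary:
    condition: str
    compartment: str
    n_islets: int
    responsive_mean: float
    responsive_sem: float
    max_dff_pct_mean: float      # % scale (145.6 = 145.6%)
    max_dff_pct_sem: float
    sem_degenerate: bool = False


def star_annotation(p: float) -> str:
    """Significance stars: p<0.001 → ***, <0.01 → **, <0.05 → *, else ns."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p={p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ttest_unpaired(a: Sequence[float], b: Sequence[float],
                   names: tuple[str, str] = ("a", "b"),
                   welch: bool = False) -> ComparisonResult:
    """Unpaired two-tailed Student t-test (equal variance by default)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    df = len(a) + len(b) - 2 if not welch else np.nan
    if not welch and a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # zero pooled variance: identical spread, compare means directly
        if a.mean() == b.mean():
            return ComparisonResult(names, 0.0, df, 1.0, "ns")
        return ComparisonResult(names, np.inf, df, 0.0, "***",
                                degenerate=True)
    res = sstats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = float(res.df)
    return ComparisonResult(names, float(res.statistic), float(df),
                            float(res.pvalue),
                            star_annotation(float(res.pvalue)))


def _dunnett_corr(n_groups: Sequence[int], n_control: int) -> np.ndarray:
    lam = np.sqrt(np.array(n_groups, float)
                  / (np.array(n_groups, float) + n_control))
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    return R


def _max_abs_t_samples(R: np.ndarray, df: int, n_draws: int,
                       seed: int) -> np.ndarray:
    """Monte-Carlo draws of max_j |T_j| for the Dunnett statistic."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
    z = rng.standard_normal((n_draws, len(R))) @ L.T
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    return np.abs(z / s[:, None]).max(axis=1)


def dunnett_critical_value(k: int, df: int, alpha: float = 0.05,
                           n_draws: int = 200_000, seed: int = 1234,
                           balanced_corr: float = 0.5) -> float:
    """Two-sided Dunnett critical value for ``k`` comparisons.

    Balanced designs have pairwise correlation 0.5 between comparison
    statistics; the value is the (1−α) quantile of max|T| under the joint
    multivariate t, estimated by seeded Monte Carlo.
    """
    R = np.full((k, k), balanced_corr)
    np.fill_diagonal(R, 1.0)
    m = _max_abs_t_samples(R, df, n_draws, seed)
    return float(np.quantile(m, 1.0 - alpha))


def anova_dunnett(groups: Sequence[Sequence[float]], control_index: int = 0,
                  names: Optional[Sequence[str]] = None,
                  n_draws: int = 200_000, seed: int = 1234
                  ) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """One-way ANOVA plus Dunnett's many-to-one comparisons.

    Returns the ANOVA F result and one adjusted comparison per treatment
    group versus the control.  Adjusted p-values are
    P(max_j |T_j| ≥ |t_obs|) under the joint multivariate t with the
    design's correlation structure, by seeded Monte-Carlo integration.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if not (0 <= control_index < len(groups)):
        raise ValueError(f"control_index {control_index} out of range")
    arrs = [np.asarray(g, float) for g in groups]
    if any(len(g) < 2 for g in arrs):
        raise ValueError("each group needs n >= 2")
    if names is None:
        names = [f"group{i}" for i in range(len(arrs))]

    F, p_f = sstats.f_oneway(*arrs)
    n_total = sum(len(g) for g in arrs)
    df_err = n_total - len(arrs)
    anova = ComparisonResult(("anova", names[control_index]), float(F),
                             float(df_err), float(p_f),
                             star_annotation(float(p_f)))

    ctrl = arrs[control_index]
    treats = [g for i, g in enumerate(arrs) if i != control_index]
    t_names = [n for i, n in enumerate(names) if i != control_index]
    # pooled error variance across all groups (classical Dunnett)
    ss = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    s2 = ss / df_err
    t_obs = np.array([
        (g.mean() - ctrl.mean())
        / np.sqrt(s2 * (1.0 / len(g) + 1.0 / len(ctrl)))
        for g in treats])

    R = _dunnett_corr([len(g) for g in treats], len(ctrl))
    m = _max_abs_t_samples(R, df_err, n_draws, seed)
    results = []
    for name, t in zip(t_names, t_obs):
        p_raw = 2.0 * sstats.t.sf(abs(t), df_err)
        p_adj = float((m >= abs(t)).mean())
        p_adj = max(p_adj, p_raw)      # adjustment can only increase p
        results.append(ComparisonResult(
            (name, names[control_index]), float(t), float(df_err),
            float(p_raw), star_annotation(p_adj), p_adjusted=p_adj))
    return anova, results


def summarize_stage(calls: pd.DataFrame,
                    group_cols: Sequence[str] = ("condition",),
                    by_compartment: bool = False,
                    pool_cells: bool = False) -> list[StageSummary]:
    """Aggregate per-cell calls to stage summaries.

    ``calls`` is tidy with columns islet_id, responsive, max_dff and the
    grouping columns (plus compartment).  Per islet: responsive count and
    mean Max ΔF/F0 over responsive cells; per group: mean ± SEM over
    islets on the percent scale.  ``pool_cells=True`` instead pools cells
    across islets for the amplitude mean (alternative aggregation).
    """
    req = {"islet_id", "responsive", "max_dff"}
    if not req <= set(calls.columns):
        raise ValueError(f"calls must have columns {sorted(req)}")
    keys = list(group_cols) + (["compartment"] if by_compartment else [])
    summaries = []
    for gkey, g in calls.groupby(keys, sort=True):
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        per_islet = g.groupby("islet_id").apply(
            lambda s: pd.Series({
                "count": float(s.responsive.sum()),
                "amp": s.loc[s.responsive, "max_dff"].mean(),
            }), include_groups=False)
        n = len(per_islet)
        counts = per_islet["count"].to_numpy()
        amps = per_islet["amp"].dropna().to_numpy()   # islets w/ responders
        if pool_cells:
            cell_amp = g.loc[g.responsive, "max_dff"].to_numpy()
            amp_mean = cell_amp.mean() if cell_amp.size else np.nan
            amp_sem = (cell_amp.std(ddof=1) / np.sqrt(len(cell_amp))
                       if len(cell_amp) > 1 else 0.0)
        else:
            amp_mean = amps.mean() if amps.size else np.nan
            amp_sem = (amps.std(ddof=1) / np.sqrt(len(amps))
                       if len(amps) > 1 else 0.0)
        summaries.append(StageSummary(
            condition=str(gkey[0]),
            compartment=str(gkey[-1]) if by_compartment else "all",
            n_islets=n,
            responsive_mean=float(counts.mean()),
            responsive_sem=float(counts.std(ddof=1) / np.sqrt(n))
            if n > 1 else 0.0,
            max_dff_pct_mean=float(100.0 * amp_mean)
            if np.isfinite(amp_mean) else np.nan,
            max_dff_pct_sem=float(100.0 * amp_sem),
            sem_degenerate=n < 2,
        ))
    return summaries
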