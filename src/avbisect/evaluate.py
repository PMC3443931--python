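"""Group-level evaluation of the MLE integration model.

Three questions per age group: how much of the variance in measured
conflict PSEs the forced-fusion model explains; how the threshold-derived
and slope-derived weights compare on average; and whether measured bimodal
thresholds exceed the optimal prediction (one-tailed one-sample t-test,
the direction of non-optimality; stars at p < .05 and p < .01).

The explained-variance statistic is

    R² = 1 − (1/(σ̂² + σ²)) · (1/N) · Σ (S_i − Ŝ_i)²,

with S_i the measured PSEs over all children and conflict levels in the
group, Ŝ_i the model-predicted PSEs, and σ², σ̂² their population
variances (denominator N, so Ŝ = mean(S) gives exactly 0).  R² = 1 means
the model explains all the variance, 0 that it does no better than the
mean, negative that it does worse.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceExplainedResult",
    "ThresholdComparison",
    "r_squared",
    "compare_bimodal_to_prediction",
    "aggregate_by_age",
]


@dataclass(frozen=True)
class VarianceExplainedResult:
    """Explained-variance statistic of measured vs predicted PSEs."""

    age_group: str
    n_points: int
    mean_sq_err: float
    var_predicted: float
    var_measured: float
    r_squared: float


@dataclass(frozen=True)
class ThresholdComparison:
    """One-tailed one-sample t-test of measured − predicted thresholds."""

    age_group: str
    condition_pair: Tuple[str, str]
    t_stat: float
    p_one_tailed: float
    n: int
    mean_difference: float
    significant_05: bool
    significant_01: bool
    degenerate: bool = False


def r_squared(
    measured: Sequence[float],
    predicted: Sequence[float],
    age_group: str = "",
) -> VarianceExplainedResult:
    """Proportion of PSE variance explained by the model (see module doc)."""
    s = np.asarray(measured, dtype=float)
    shat = np.asarray(predicted, dtype=float)
    if s.shape != shat.shape:
        raise ValueError("measured and predicted must have equal length")
    n = s.size
    if n < 2:
        raise ValueError("R^2 requires at least 2 points")
    var_m = float(np.var(s))      # population variance (ddof=0)
    var_p = float(np.var(shat))
    total = var_p + var_m
    if total == 0.0:
        raise ValueError("R^2 undefined: measured and predicted are both constant")
    mse = float(np.mean((s - shat) ** 2))
    return VarianceExplainedResult(
        age_group=age_group,
        n_points=n,
        mean_sq_err=mse,
        var_predicted=var_p,
        var_measured=var_m,
        r_squared=1.0 - mse / total,
    )


def compare_bimodal_to_prediction(
    measured: Sequence[float],
    predicted: Sequence[float],
    age_group: str = "",
    condition_pair: Tuple[str, str] = ("bimodal", "mle_prediction"),
) -> ThresholdComparison:
    """One-tailed one-sample t-test on per-observer (measured − predicted).

    The alternative is measured > predicted: a failure to reach the
    optimal (lower) bimodal bound.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError("measured and predicted must have equal length")
    n = m.size
    if n < 2:
        raise ValueError("t-test requires at least 2 observers")
    d = m - p
    sd = float(np.std(d, ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        # Degenerate: identical differences.  Zero mean gives the null's
        # median p; a nonzero constant difference is decisive.
        t = 0.0 if mean == 0.0 else float(np.inf) * np.sign(mean)
        pval = 0.5 if mean == 0.0 else (0.0 if mean > 0 else 1.0)
        degenerate = True
    else:
        t = mean / (sd / np.sqrt(n))
        pval = float(stats.t.sf(t, df=n - 1))
        degenerate = False
    return ThresholdComparison(
        age_group=age_group,
        condition_pair=condition_pair,
        t_stat=float(t),
        p_one_tailed=float(pval),
        n=n,
        mean_difference=mean,
        significant_05=pval < 0.05,
        significant_01=pval < 0.01,
        degenerate=degenerate,
    )


def _mean_sem(values: np.ndarray) -> Tuple[float, float]:
    values = values[np.isfinite(values)]
    n = values.size
    if n == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, sem


def aggregate_by_age(
    observer_summary: pd.DataFrame,
    conflict_pses: pd.DataFrame,
    bonferroni: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level tables: mean ± SEM per age group, R² and threshold tests.

    Parameters
    ----------
    observer_summary:
        One row per observer with columns ``domain``, ``age_group``,
        ``sigma_v``, ``sigma_a``, ``sigma_bimodal``, ``sigma_va_pred``,
        ``w_a_thresholds``, ``w_a_slope``.
    conflict_pses:
        One row per observer × conflict with columns ``domain``,
        ``age_group``, ``conflict``, ``pse_symmetric``, ``pse_predicted``
        (all children and all Δ enter the group R²).
    bonferroni:
        Correct the t-test stars for the number of age groups per domain
        (off by default: stars are reported per group).

    Returns ``(group_summary, comparisons)`` DataFrames.  SEM is flagged
    NaN for single-observer groups; empty groups are dropped with a
    warning.
    """
    required = {
        "domain", "age_group", "sigma_v", "sigma_a",
        "sigma_bimodal", "sigma_va_pred", "w_a_thresholds", "w_a_slope",
    }
    missing = required - set(observer_summary.columns)
    if missing:
        raise ValueError(f"observer_summary missing columns: {sorted(missing)}")

    rows = []
    comp_rows = []
    for (domain, age_group), g in observer_summary.groupby(
        ["domain", "age_group"], sort=False
    ):
        if len(g) == 0:  # pragma: no cover - groupby never yields empties
            _warnings.warn(f"empty age group {age_group!r} omitted")
            continue
        row: Dict[str, object] = {"domain": domain, "age_group": age_group,
                                  "n_observers": len(g)}
        for col in ("sigma_v", "sigma_a", "sigma_bimodal", "sigma_va_pred",
                    "w_a_thresholds", "w_a_slope"):
            mean, sem = _mean_sem(g[col].to_numpy(dtype=float))
            row[f"{col}_mean"] = mean
            row[f"{col}_sem"] = sem
        pse_g = conflict_pses[
            (conflict_pses["domain"] == domain)
            & (conflict_pses["age_group"] == age_group)
        ]
        finite = np.isfinite(
            pse_g[["pse_symmetric", "pse_predicted"]].to_numpy(dtype=float)
        ).all(axis=1)
        pse_g = pse_g[finite]
        if len(pse_g) >= 2:
            try:
                r2 = r_squared(
                    pse_g["pse_symmetric"].to_numpy(dtype=float),
                    pse_g["pse_predicted"].to_numpy(dtype=float),
                    age_group=age_group,
                )
                row["r_squared"] = r2.r_squared
                row["r_squared_n"] = r2.n_points
            except ValueError:
                row["r_squared"] = float("nan")
                row["r_squared_n"] = len(pse_g)
        else:
            row["r_squared"] = float("nan")
            row["r_squared_n"] = len(pse_g)
        rows.append(row)

        ok = g[["sigma_bimodal", "sigma_va_pred"]].notna().all(axis=1)
        if ok.sum() >= 2:
            comp = compare_bimodal_to_prediction(
                g.loc[ok, "sigma_bimodal"].to_numpy(dtype=float),
                g.loc[ok, "sigma_va_pred"].to_numpy(dtype=float),
                age_group=age_group,
            )
            comp_rows.append({
                "domain": domain,
                "age_group": age_group,
                "n": comp.n,
                "mean_difference": comp.mean_difference,
                "t_stat": comp.t_stat,
                "p_one_tailed": comp.p_one_tailed,
                "significant_05": comp.significant_05,
                "significant_01": comp.significant_01,
                "degenerate": comp.degenerate,
            })
        else:
            _warnings.warn(
                f"group {age_group!r} ({domain}): fewer than 2 complete "
                "observers, threshold comparison skipped"
            )

    comparisons = pd.DataFrame(comp_rows)
    if bonferroni and len(comparisons):
        k = comparisons.groupby("domain")["age_group"].transform("count")
        adj = np.minimum(comparisons["p_one_tailed"] * k, 1.0)
        comparisons["p_adjusted"] = adj
        comparisons["significant_05"] = adj < 0.05
        comparisons["significant_01"] = adj < 0.01
    return pd.DataFrame(rows), comparisons
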