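"""Statistical reporting: group comparisons, vehicle normalization,
summary tables.

Measurements live in a tidy table with columns ``experiment_id``,
``condition``, ``cell_id``, ``metric_name``, ``value``.  Two-group
comparisons use the two-tailed unpaired Student's t-test; three or more
groups use one-way ANOVA with Tukey's HSD post-hoc on all pairs
(Tukey–Kramer for unequal group sizes).  Significance is declared at
P < 0.05.

The unit of analysis is explicit: per-condition dots are typically
per-cell values, but cells within an experiment are not independent, so
the default aggregates to experiment means before testing (per-cell
testing is available as an option) and both sample sizes are always
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05
REQUIRED_COLUMNS = ["experiment_id", "condition", "cell_id", "metric_name", "value"]


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_difference: float
    p_adjusted: float
    significant: bool


@dataclass
class ComparisonResult:
    """Outcome of one group comparison.

    ``pairwise`` is populated only for ANOVA (Tukey post-hoc); for a
    two-group t-test it is empty.
    """

    test_name: str                   # "t-test" or "anova"
    groups: list[str]
    statistic: float                 # t or F
    p_value: float
    n_per_group: dict[str, int] = field(default_factory=dict)
    pairwise: list[PairwiseResult] = field(default_factory=list)


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValueError("table contains non-finite values")
    return table


def _group_values(table: pd.DataFrame, metric_name: str, unit: str
                  ) -> dict[str, np.ndarray]:
    sub = table[table["metric_name"] == metric_name]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric_name!r}")
    if unit == "experiments":
        agg = (sub.groupby(["condition", "experiment_id"], sort=True)["value"]
               .mean().reset_index())
        grouped = {c: g["value"].to_numpy(dtype=float)
                   for c, g in agg.groupby("condition", sort=True)}
    elif unit == "cells":
        grouped = {c: g["value"].to_numpy(dtype=float)
                   for c, g in sub.groupby("condition", sort=True)}
    else:
        raise ValueError("unit must be 'experiments' or 'cells'")
    return grouped


def compare_groups(table: pd.DataFrame, metric_name: str,
                   unit: str = "experiments",
                   alpha: float = ALPHA) -> ComparisonResult:
    """Compare conditions for one metric.

    Two conditions → two-tailed unpaired Student's t-test (pooled
    variance).  More than two → one-way ANOVA, with Tukey HSD adjusted
    p-values for every pair.  Raises for a single condition or any group
    with fewer than two observations.
    """
    validate_table(table)
    grouped = _group_values(table, metric_name, unit)
    names = sorted(grouped)
    if len(names) < 2:
        raise ValueError("need at least two conditions to compare")
    for name in names:
        if len(grouped[name]) < 2:
            raise ValueError(f"condition {name!r} has fewer than 2 observations")
    n_per_group = {name: len(grouped[name]) for name in names}

    if len(names) == 2:
        t_stat, p = stats.ttest_ind(grouped[names[0]], grouped[names[1]],
                                    equal_var=True)
        return ComparisonResult("t-test", names, float(t_stat), float(p),
                                n_per_group)

    f_stat, p = stats.f_oneway(*(grouped[name] for name in names))
    values = np.concatenate([grouped[name] for name in names])
    labels = np.concatenate([[name] * len(grouped[name]) for name in names])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = list(combinations([str(g) for g in tukey.groupsunique], 2))
    pairwise = [PairwiseResult(pair=pair, mean_difference=float(diff),
                               p_adjusted=float(p_adj), significant=bool(rej))
                for pair, diff, p_adj, rej in zip(
                    pairs, tukey.meandiffs, tukey.pvalues, tukey.reject)]
    return ComparisonResult("anova", names, float(f_stat), float(p),
                            n_per_group, pairwise)


def normalize_to_vehicle(table: pd.DataFrame,
                         vehicle_condition: str = "vehicle") -> pd.DataFrame:
    """Divide every value by its experiment's vehicle mean, per metric.

    After normalization the vehicle condition has mean exactly 1 within
    each experiment.  A missing vehicle group in any experiment is an
    error naming that experiment.
    """
    validate_table(table)
    out = table.copy()
    for (exp, metric), idx in out.groupby(
            ["experiment_id", "metric_name"], sort=False).groups.items():
        sub = out.loc[idx]
        vehicle = sub.loc[sub["condition"] == vehicle_condition, "value"]
        if vehicle.empty:
            raise ValueError(
                f"experiment {exp!r} has no {vehicle_condition!r} rows "
                f"for metric {metric!r}")
        mean = float(vehicle.mean())
        if mean == 0:
            raise ValueError(f"experiment {exp!r}: vehicle mean is 0")
        out.loc[idx, "value"] = sub["value"] / mean
    return out


def summarize(table: pd.DataFrame, unit: str = "experiments") -> pd.DataFrame:
    """Per-condition mean ± s.e.m. with both sample sizes.

    ``unit`` selects the dispersion unit: across experiment means
    (default) or across cells.  The s.e.m. of a single observation is
    undefined and reported as missing.  Both ``n_experiments`` and
    ``n_cells`` are always reported.
    """
    validate_table(table)
    rows = []
    for (metric, condition), sub in table.groupby(
            ["metric_name", "condition"], sort=True):
        per_exp = sub.groupby("experiment_id")["value"].mean()
        samples = per_exp.to_numpy() if unit == "experiments" \
            else sub["value"].to_numpy(dtype=float)
        if unit not in ("experiments", "cells"):
            raise ValueError("unit must be 'experiments' or 'cells'")
        n = len(samples)
        sem = float(np.std(samples, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"metric_name": metric, "condition": condition,
                     "mean": float(np.mean(samples)), "sem": sem,
                     "n_experiments": int(sub["experiment_id"].nunique()),
                     "n_cells": int(len(sub)), "unit": unit})
    return pd.DataFrame(rows)
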