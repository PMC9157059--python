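"""Phenotype-level statistics: strain means, strain-effect ANOVA, correlations.

Replicate glucose measurements (µg/fly, pooled-fly samples) are averaged
per strain to form the response vector of the association model; the
strain effect itself is assessed by one-way fixed-effect ANOVA on all
individual measurements, and reproducibility across conditions by
Pearson correlation of strain means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "validate_phenotype_table",
    "strain_means",
    "anova_strain_effect",
    "pearson_between_conditions",
    "protein_control",
    "AnovaResult",
]


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effect ANOVA summary (F = MS_between / MS_within)."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def validate_phenotype_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype-table contract; returns the table unchanged.

    Requires columns strain/replicate/condition/glucose, non-negative
    glucose, and unique (strain, condition, replicate) keys.
    """
    if len(table) == 0:
        raise ValueError("phenotype table is empty")
    required = {"strain", "replicate", "condition", "glucose"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    if (table["glucose"].dropna() < 0).any():
        raise ValueError("glucose concentrations must be non-negative")
    if table.duplicated(["strain", "condition", "replicate"]).any():
        raise ValueError("(strain, condition, replicate) keys must be unique")
    return table


def strain_means(table: pd.DataFrame, condition: str) -> pd.Series:
    """Arithmetic mean glucose per strain in one condition.

    Returns a Series indexed by strain ID in first-appearance order —
    the ``y`` vector of the mixed model.  Strains with no record in the
    condition are simply absent (callers can diff against the full strain
    list to report omissions).
    """
    validate_phenotype_table(table)
    sub = table[table["condition"] == condition]
    if len(sub) == 0:
        raise ValueError(f"condition {condition!r} not present in table")
    order = sub["strain"].drop_duplicates().tolist()
    means = sub.groupby("strain", sort=False)["glucose"].mean()
    return means.reindex(order)


def _anova_groups(groups: list[np.ndarray]) -> AnovaResult:
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    df_b, df_w = k - 1, n_total - k
    if df_w < 1:
        raise ValueError("ANOVA needs >= 1 residual degree of freedom")
    grand = np.concatenate(groups).mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_w == 0.0 and ss_b == 0.0:
        raise ValueError("all measurements identical: F statistic undefined")
    if ss_w == 0.0:
        # zero within-group variance: degenerate limit F -> +inf, p -> 0
        return AnovaResult(np.inf, 0.0, df_b, df_w)
    f = (ss_b / df_b) / (ss_w / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w)


def anova_strain_effect(table: pd.DataFrame, condition: str,
                        value: str = "glucose") -> AnovaResult:
    """One-way ANOVA of strain on all individual measurements in a condition."""
    validate_phenotype_table(table)
    sub = table[table["condition"] == condition]
    if len(sub) == 0:
        raise ValueError(f"condition {condition!r} not present in table")
    sub = sub.dropna(subset=[value])
    groups = [g[value].to_numpy() for _, g in sub.groupby("strain", sort=False)]
    return _anova_groups(groups)


def pearson_between_conditions(means_a: pd.Series, means_b: pd.Series) -> tuple[float, float, int]:
    """Pearson r of strain means on the strain intersection.

    Two-sided p from the t transform with ``n_common - 2`` degrees of
    freedom.  Requires >= 3 common strains and non-zero variance in both.
    """
    common = means_a.index.intersection(means_b.index)
    n = len(common)
    if n < 3:
        raise ValueError(f"need >= 3 common strains, got {n}")
    x = means_a.loc[common].to_numpy(dtype=float)
    y = means_b.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance in strain means: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def protein_control(table: pd.DataFrame,
                    condition: str | None = None) -> tuple[AnovaResult, tuple[float, float, int]]:
    """Body-size control: strain ANOVA on protein and per-sample glucose~protein r.

    Protein should neither vary across strains nor correlate with glucose
    in individual samples if glucose variation reflects glycemia rather
    than body size.  Missing protein values are dropped pairwise.
    """
    validate_phenotype_table(table)
    if "protein" not in table.columns:
        raise ValueError("phenotype table has no protein column")
    sub = table if condition is None else table[table["condition"] == condition]
    if len(sub) == 0:
        raise ValueError(f"condition {condition!r} not present in table")
    prot = sub.dropna(subset=["protein"])
    if len(prot) == 0:
        raise ValueError("no protein measurements present")
    groups = [g["protein"].to_numpy(dtype=float) for _, g in prot.groupby("strain", sort=False)]
    anova = _anova_groups(groups)
    paired = prot.dropna(subset=["glucose"])
    x = paired["glucose"].to_numpy(dtype=float)
    y = paired["protein"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 paired samples for correlation")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return anova, (float(r), float(p), len(x))
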