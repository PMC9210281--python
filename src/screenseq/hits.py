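"""Outlier-based hit calling on per-gene AI distributions.

Each readout gene is analysed independently: all conditions (treated and
control wells, all concentrations and time points) are pooled, observations
with fewer than 30 informative counts are dropped, quartiles and the
interquartile range are computed, and observations beyond k x IQR outside
the quartiles (default k = 3, "far out" fences) are flagged as primary hits.
A gene with stable allele-specific expression yields a tight AI distribution
and no outliers; a perturbation that shifts AI in one well falls outside
the fences.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneFences",
    "tukey_hinges",
    "quartiles",
    "gene_fences",
    "call_hits",
    "UnevaluableGene",
    "LOW",
    "HIGH",
    "NONE",
]

LOW = "LOW"
HIGH = "HIGH"
NONE = "NONE"


class UnevaluableGene(ValueError):
    """Raised when a gene retains too few observations to place fences."""


@dataclass(frozen=True)
class GeneFences:
    gene: str
    median_ai: float
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    k: float
    n_obs_used: int


def tukey_hinges(values) -> tuple[float, float, float]:
    """(lower hinge, median, upper hinge) by median-of-halves.

    With an odd number of observations the median belongs to both halves.
    Transparent and exactly reproducible by hand at screen-sized n.
    """
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 0:
        raise ValueError("no values")
    half = (n + 1) // 2
    return (statistics.median(v[:half]),
            statistics.median(v),
            statistics.median(v[n - half:]))


def quartiles(values, method: str = "hinges") -> tuple[float, float, float]:
    """(q1, median, q3) by Tukey hinges (default) or linear interpolation."""
    if method == "hinges":
        return tukey_hinges(values)
    if method == "linear":
        q1, med, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
        return float(q1), float(med), float(q3)
    raise ValueError(f"unknown quartile method {method!r}")


def gene_fences(ai_values, k: float = 3.0, gene: str = "",
                quartile_method: str = "hinges",
                fence_mode: str = "q3") -> GeneFences:
    """Quartile fences for one gene's pooled AI observations.

    fence_mode "q3" places fences at Q1 - k*IQR and Q3 + k*IQR (Tukey's
    rule); "q1" places the upper fence at Q1 + k*IQR instead. Fences are not
    clipped to [0, 1]: a fence beyond the unit interval simply means no AI
    can be an outlier on that side.
    """
    v = [float(x) for x in ai_values]
    if len(v) < 4:
        raise UnevaluableGene(
            f"gene {gene or '?'}: {len(v)} observations after filtering (< 4)")
    q1, med, q3 = quartiles(v, quartile_method)
    iqr = q3 - q1
    upper_base = q3 if fence_mode == "q3" else q1
    if fence_mode not in ("q3", "q1"):
        raise ValueError(f"unknown fence_mode {fence_mode!r}")
    return GeneFences(
        gene=gene, median_ai=med, q1=q1, q3=q3, iqr=iqr,
        lower_fence=q1 - k * iqr,
        upper_fence=upper_base + k * iqr,
        k=k, n_obs_used=len(v),
    )


def call_hits(
    ai_df: pd.DataFrame,
    min_total: int = 30,
    k: float = 3.0,
    quartile_method: str = "hinges",
    fence_mode: str = "q3",
    gene_col: str = "gene",
    ai_col: str = "ai",
    n_col: str = "n_total",
) -> pd.DataFrame:
    """Flag outlier AI observations per gene.

    Input: one row per observation (one gene in one well) with its AI and
    informative-count total. Per gene: drop observations with fewer than
    ``min_total`` counts, compute fences on the retained pool, and flag
    observations outside the fences. Returns every input row annotated with
    passed_count_filter, evaluable, q1/q3/iqr, lower_fence/upper_fence,
    is_hit, and direction (LOW/HIGH/NONE).
    """
    out = ai_df.copy()
    out["passed_count_filter"] = out[n_col].to_numpy() >= min_total
    out["evaluable"] = False
    for col in ("q1", "q3", "iqr", "lower_fence", "upper_fence"):
        out[col] = np.nan
    out["is_hit"] = False
    out["direction"] = NONE

    for gene, grp in out.groupby(gene_col, sort=True):
        kept = grp[grp["passed_count_filter"]]
        try:
            f = gene_fences(kept[ai_col], k=k, gene=str(gene),
                            quartile_method=quartile_method,
                            fence_mode=fence_mode)
        except UnevaluableGene:
            continue
        idx = kept.index
        out.loc[grp.index, "evaluable"] = True
        out.loc[grp.index, ["q1", "q3", "iqr"]] = f.q1, f.q3, f.iqr
        out.loc[grp.index, "lower_fence"] = f.lower_fence
        out.loc[grp.index, "upper_fence"] = f.upper_fence
        ai = kept[ai_col].to_numpy(dtype=float)
        low = ai < f.lower_fence
        high = ai > f.upper_fence
        out.loc[idx[low], ["is_hit", "direction"]] = True, LOW
        out.loc[idx[high], ["is_hit", "direction"]] = True, HIGH
    return out


def primary_hits(hits_df: pd.DataFrame) -> pd.DataFrame:
    """Flagged rows only (the screen's primary-hit list)."""
    return hits_df[hits_df["is_hit"]].reset_index(drop=True)
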