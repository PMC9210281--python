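"""Allelic-imbalance estimation and validation analyses.

AI is oriented maternal-over-total throughout: AI = n_129 / (n_129 + n_Cast).
Confidence intervals are exact (Clopper-Pearson) binomial intervals, chosen
for correct behaviour at the AI ~ 0/1 boundaries where monoallelically
expressed genes live. Ambiguous counts never enter AI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AIEstimate",
    "Trajectory",
    "compute_ai",
    "ai_table",
    "expected_mixture_ai",
    "concordance",
    "ConcordanceResult",
    "summarize_timecourse",
]


@dataclass(frozen=True)
class AIEstimate:
    ai: float
    n_maternal: int
    n_paternal: int
    n_total: int
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class Trajectory:
    gene: str
    dose: float
    days: tuple[float, ...]
    ai: tuple[float, ...]
    stable_from: float | None


def _ratio(a: int, b: int) -> float:
    return a / (a + b)


def compute_ai(count_maternal: int, count_paternal: int,
               conf_level: float = 0.95) -> AIEstimate | None:
    """Point AI = maternal/(maternal+paternal) with an exact binomial CI.

    Returns None (no data) when both counts are zero — a well with no
    informative molecules has no AI, not AI = 0.
    """
    if count_maternal < 0 or count_paternal < 0:
        raise ValueError("counts must be non-negative")
    n = count_maternal + count_paternal
    if n == 0:
        return None
    lo, hi = proportion_confint(count_maternal, n, alpha=1.0 - conf_level,
                                method="beta")
    return AIEstimate(
        ai=_ratio(count_maternal, count_paternal),
        n_maternal=count_maternal,
        n_paternal=count_paternal,
        n_total=n,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def ai_table(counts: pd.DataFrame, conf_level: float = 0.95) -> pd.DataFrame:
    """Per-row AI estimates for a counts table (count_129 / count_cast columns).

    Rows with zero informative counts are dropped (no-data), mirroring the
    downstream exclusion rule.
    """
    keep = []
    for r in counts.itertuples(index=False):
        est = compute_ai(int(r.count_129), int(r.count_cast), conf_level)
        if est is None:
            continue
        row = r._asdict()
        row.update(ai=est.ai, n_total=est.n_total,
                   ci_low=est.ci_low, ci_high=est.ci_high)
        keep.append(row)
    return pd.DataFrame(keep)


def expected_mixture_ai(frac_maternal_material: float) -> float:
    """Expected AI of a titration mix of pure 129 and pure Cast material.

    Mixing is linear: material that is 30% 129 by template abundance yields
    an expected maternal fraction of 0.30.
    """
    f = float(frac_maternal_material)
    if not 0.0 <= f <= 1.0:
        raise ValueError("mixture fraction must be in [0, 1]")
    return f


@dataclass(frozen=True)
class ConcordanceResult:
    pearson_r: float
    max_abs_deviation: float
    slope: float
    intercept: float


def concordance(expected, observed) -> ConcordanceResult:
    """Agreement between expected and measured AI vectors.

    Used for the genomic-DNA titration check and for the UMI vs non-UMI
    assay comparison.
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1-D vectors with >= 3 points")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("no-data entries must be removed before concordance")
    fit = stats.linregress(x, y)
    if np.all(y - x == (y - x)[0]):
        # exact translations: report r = 1 without floating-point fuzz
        r = 1.0
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return ConcordanceResult(
        pearson_r=r,
        max_abs_deviation=float(np.max(np.abs(y - x))),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def _stable_from(days: np.ndarray, ai: np.ndarray, tol: float) -> float | None:
    """Earliest day from which every consecutive AI change is <= tol."""
    diffs = np.abs(np.diff(ai))
    ok_from = None
    for i in range(len(diffs) - 1, -1, -1):
        if diffs[i] <= tol:
            ok_from = i
        else:
            break
    return None if ok_from is None else float(days[ok_from])


def summarize_timecourse(ai_df: pd.DataFrame, stability_tol: float = 0.05,
                         gene_col: str = "gene", dose_col: str = "conc_uM",
                         day_col: str = "day", ai_col: str = "ai") -> list[Trajectory]:
    """Per (gene, dose) exposure/recovery trajectories with plateau detection.

    ``stable_from`` is the earliest collection day after which AI changes by
    at most ``stability_tol`` between every pair of consecutive time points —
    the operational reading of "AI reached levels that remained stable".
    """
    out: list[Trajectory] = []
    for (gene, dose), grp in ai_df.groupby([gene_col, dose_col], sort=True):
        if len(grp) < 2:
            raise ValueError(f"trajectory ({gene}, {dose}) needs >= 2 time points")
        grp = grp.sort_values(day_col)
        days = grp[day_col].to_numpy(dtype=float)
        if len(np.unique(days)) != len(days):
            raise ValueError(f"duplicate days in trajectory ({gene}, {dose})")
        ai = grp[ai_col].to_numpy(dtype=float)
        out.append(Trajectory(
            gene=gene, dose=float(dose),
            days=tuple(days), ai=tuple(ai),
            stable_from=_stable_from(days, ai, stability_tol),
        ))
    return out


def trajectories_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    rows = [
        {"gene": t.gene, "conc_uM": t.dose,
         "days": ",".join(str(d) for d in t.days),
         "ai": ",".join(f"{a:.6g}" for a in t.ai),
         "stable_from": "" if t.stable_from is None else t.stable_from}
        for t in trajs
    ]
    return pd.DataFrame(rows, columns=["gene", "conc_uM", "days", "ai", "stable_from"])
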