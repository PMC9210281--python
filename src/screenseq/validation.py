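"""Built-in validation experiments.

Each function runs a self-contained simulate -> count -> estimate experiment
mirroring the assay's wet-lab validations: exact ground-truth recovery on a
small screen, parameter recovery at screen scale, genomic-DNA titration
concordance, and null/sensitivity characterisation of the hit caller.
They are used by the test suite and by the reproduction script.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .aistats import compute_ai, concordance, ConcordanceResult
from .demux import count_screen
from .hits import call_hits
from .panel import plate_layout
from .simulate import SimParams, simulate_screen, synthetic_barcodes, synthetic_panel

__all__ = [
    "mini_screen_exactness",
    "parameter_recovery",
    "titration_concordance",
    "null_hit_simulations",
    "shift_sensitivity",
]


def _run_pipeline(panel, design, barcodes, params, workdir=None):
    with tempfile.TemporaryDirectory(dir=workdir) as d:
        r1, r2 = Path(d) / "r1.fastq.gz", Path(d) / "r2.fastq.gz"
        truth = simulate_screen(panel, design, params, r1, r2)
        counts, summary = count_screen(r1, r2, panel, barcodes, design)
    return truth, counts, summary


def mini_screen_exactness(seed: int = 0, n_assays: int = 4, n_wells: int = 24,
                          molecules: int = 500) -> dict:
    """Error-free, duplication-1 mini-screen: pipeline counts and AI must
    reproduce the simulator's ground truth exactly."""
    panel = synthetic_panel(n_assays, n_assays, seed=seed + 1)
    barcodes = synthetic_barcodes(seed=seed + 2)
    design = plate_layout([], [], n_wells // 2, n_wells - n_wells // 2)
    design = design.attach_barcodes(barcodes)
    rng = np.random.default_rng(seed)
    truth_map = {(a.gene, w.well): float(rng.uniform(0.05, 0.95))
                 for a in panel for w in design.wells}
    params = SimParams(true_ai=truth_map, molecules_per_assay_well=molecules,
                       mean_pcr_duplication=1.0, substitution_error_rate=0.0,
                       seed=seed)
    truth, counts, summary = _run_pipeline(panel, design, barcodes, params)
    m = truth.merge(counts, on=["gene", "assay_id", "well"], how="left")
    count_mismatch = int(((m.count_129 != m.n_molecules_maternal)
                          | (m.count_cast != m.n_molecules_paternal)
                          | (m.count_ambiguous != 0)).sum())
    ai_mismatch = 0
    for r in m.itertuples():
        est = compute_ai(int(r.count_129), int(r.count_cast))
        emp = (r.n_molecules_maternal
               / (r.n_molecules_maternal + r.n_molecules_paternal))
        ai_mismatch += est is None or est.ai != emp
    return {
        "n_points": len(m),
        "count_mismatches": count_mismatch,
        "ai_mismatches": int(ai_mismatch),
        "unassigned_reads": summary["unassigned"],
    }


def parameter_recovery(seed: int = 0, n_assays: int = 27, molecules: int = 1000,
                       mean_dup: float = 3.0, error_rate: float = 1e-3) -> dict:
    """Screen-scale recovery: 27 assays x 96 wells at realistic error and
    PCR duplication; fraction of points whose AI estimate is within three
    binomial standard errors of the generating truth."""
    panel = synthetic_panel(n_assays, 23, seed=seed + 1)
    barcodes = synthetic_barcodes(seed=seed + 2)
    design = plate_layout([f"drug{i + 1:02d}" for i in range(24)],
                          [1.0, 10.0, 20.0], 12, 12)
    design = design.attach_barcodes(barcodes)
    rng = np.random.default_rng(seed)
    genes = sorted({a.gene for a in panel})
    truth_map = {(g, w.well): float(rng.uniform(0.05, 0.95))
                 for g in genes for w in design.wells}
    params = SimParams(true_ai=truth_map, molecules_per_assay_well=molecules,
                       mean_pcr_duplication=mean_dup,
                       substitution_error_rate=error_rate, seed=seed)
    truth, counts, summary = _run_pipeline(panel, design, barcodes, params)
    m = truth.merge(counts, on=["gene", "assay_id", "well"], how="left")
    within = 0
    n_points = 0
    for r in m.itertuples():
        if pd.isna(r.count_129):
            n_points += 1
            continue
        est = compute_ai(int(r.count_129), int(r.count_cast))
        if est is None:
            n_points += 1
            continue
        se = np.sqrt(r.true_ai * (1.0 - r.true_ai) / molecules)
        within += abs(est.ai - r.true_ai) <= 3 * se
        n_points += 1
    return {
        "n_points": n_points,
        "fraction_within_3se": within / n_points,
        "assigned_reads": summary["assigned"],
        "total_reads": summary["total_pairs"],
    }


def titration_concordance(seed: int = 0, fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
                          molecules: int = 10_000,
                          n_assays: int = 4) -> tuple[ConcordanceResult, int]:
    """Simulated genomic-DNA titration: known mixes of pure maternal and pure
    paternal material; expected AI is the mix fraction. Returns the
    concordance summary over all (assay, mix) points and the point count."""
    panel = synthetic_panel(n_assays, n_assays, seed=seed + 1)
    barcodes = synthetic_barcodes(seed=seed + 2)
    design = plate_layout([], [], len(fractions), 0).attach_barcodes(barcodes)
    truth_map = {(a.gene, w.well): f
                 for a in panel
                 for w, f in zip(design.wells, fractions)}
    params = SimParams(true_ai=truth_map, molecules_per_assay_well=molecules,
                       substitution_error_rate=1e-3, seed=seed)
    _, counts, _ = _run_pipeline(panel, design, barcodes, params)
    counts = counts.set_index(["assay_id", "well"])
    expected, observed = [], []
    for a in panel:
        for w, f in zip(design.wells, fractions):
            r = counts.loc[(a.assay_id, w.well)]
            est = compute_ai(int(r.count_129), int(r.count_cast))
            expected.append(f)
            observed.append(est.ai)
    return concordance(expected, observed), len(expected)


def null_hit_simulations(seed: int = 0, n_sims: int = 200, n_obs: int = 96,
                         n_reads: int = 1000, p: float = 0.5, k: float = 3.0,
                         n_controls: int = 12) -> dict:
    """Null screens: per gene-simulation, 96 well AIs drawn from
    Binomial(n_reads, p)/n_reads — no real perturbation anywhere. Counts
    gene-simulations with any false hit, and false hits landing on the
    designated untreated-control observations."""
    rng = np.random.default_rng(seed)
    sims_with_hit = 0
    control_hits = 0
    total_hits = 0
    for _ in range(n_sims):
        ai = rng.binomial(n_reads, p, size=n_obs) / n_reads
        df = pd.DataFrame({
            "gene": "null", "ai": ai, "n_total": n_reads,
            "is_control": [i < n_controls for i in range(n_obs)],
        })
        res = call_hits(df, k=k)
        n_hits = int(res.is_hit.sum())
        total_hits += n_hits
        sims_with_hit += n_hits > 0
        control_hits += int(res[res.is_control].is_hit.sum())
    return {
        "n_sims": n_sims,
        "sims_with_false_hit": sims_with_hit,
        "false_sim_rate": sims_with_hit / n_sims,
        "total_false_hits": total_hits,
        "control_false_hits": control_hits,
    }


def shift_sensitivity(seed: int = 0, n_sims: int = 200, n_obs: int = 96,
                      n_reads: int = 1000, baseline: float = 0.1,
                      shifted: float = 0.8, k: float = 3.0) -> dict:
    """Sensitivity: one condition shifted from a paternal-biased baseline
    (AI ~ 0.1) to maternal bias (AI ~ 0.8), the magnitude of the screen's
    strongest validated hit; fraction of simulations where it is flagged."""
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_sims):
        ai = rng.binomial(n_reads, baseline, size=n_obs) / n_reads
        ai[-1] = rng.binomial(n_reads, shifted) / n_reads
        df = pd.DataFrame({"gene": "g", "ai": ai, "n_total": n_reads})
        res = call_hits(df, k=k)
        detected += bool(res.is_hit.iloc[-1])
    return {"n_sims": n_sims, "detected": detected,
            "detection_rate": detected / n_sims}
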