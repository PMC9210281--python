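"""Droplet digital PCR allelic quantification.

Each droplet is scored positive or negative on two fluorescence channels:
HEX labels the maternal (129) allele probe, FAM the paternal (Cast) allele
probe (mapping configurable; it is probe-design-specific). AI is the
fractional abundance of maternal-only droplets among single-positive
droplets; double-positive droplets (both templates in one droplet) are
excluded. Absolute template concentrations use the standard Poisson
occupancy correction lambda = -ln(1 - p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DropletCounts",
    "classify_droplets",
    "ddpcr_ai",
    "poisson_concentration",
    "poisson_ai",
    "auto_threshold",
    "simulate_droplets",
    "simulate_droplets_from_counts",
    "DROPLET_VOLUME_UL",
]

#: nominal droplet volume, µL (0.85 nL, instrument convention)
DROPLET_VOLUME_UL = 0.00085


@dataclass(frozen=True)
class DropletCounts:
    n_empty: int
    n_fam_only: int  # paternal (Cast)
    n_hex_only: int  # maternal (129)
    n_double: int

    @property
    def n_total(self) -> int:
        return self.n_empty + self.n_fam_only + self.n_hex_only + self.n_double


def classify_droplets(fam_amplitudes, hex_amplitudes,
                      fam_threshold: float, hex_threshold: float) -> DropletCounts:
    """Four-way partition of droplets by per-channel amplitude thresholds."""
    fam = np.asarray(fam_amplitudes, dtype=float)
    hex_ = np.asarray(hex_amplitudes, dtype=float)
    if fam.size == 0 or fam.shape != hex_.shape:
        raise ValueError("need equal-length, non-empty amplitude vectors")
    if not (np.isfinite(fam).all() and np.isfinite(hex_).all()):
        raise ValueError("amplitudes must be finite")
    if fam_threshold <= 0 or hex_threshold <= 0:
        raise ValueError("thresholds must be positive")
    fam_pos = fam > fam_threshold
    hex_pos = hex_ > hex_threshold
    return DropletCounts(
        n_empty=int((~fam_pos & ~hex_pos).sum()),
        n_fam_only=int((fam_pos & ~hex_pos).sum()),
        n_hex_only=int((~fam_pos & hex_pos).sum()),
        n_double=int((fam_pos & hex_pos).sum()),
    )


def ddpcr_ai(counts: DropletCounts) -> float | None:
    """AI = maternal-only / (maternal-only + paternal-only) droplets.

    Double-positive droplets are excluded. Returns None when there are no
    informative (single-positive) droplets.
    """
    informative = counts.n_hex_only + counts.n_fam_only
    if informative == 0:
        return None
    return counts.n_hex_only / informative


def poisson_concentration(n_positive: int, n_total: int,
                          droplet_volume_ul: float = DROPLET_VOLUME_UL) -> float:
    """Template concentration (copies/µL) from the positive-droplet fraction.

    lambda = -ln(1 - p) copies per droplet; concentration = lambda / volume.
    """
    if not 0 <= n_positive <= n_total or n_total == 0:
        raise ValueError("need 0 <= n_positive <= n_total, n_total > 0")
    if n_positive == n_total:
        raise ValueError("all droplets positive: concentration unbounded "
                         "(saturated reaction)")
    lam = -np.log1p(-n_positive / n_total)
    return float(lam / droplet_volume_ul)


def poisson_ai(counts: DropletCounts,
               droplet_volume_ul: float = DROPLET_VOLUME_UL) -> float | None:
    """AI from per-channel Poisson concentrations (uses double-positives).

    Comparison mode: channel-positive totals include double-positive
    droplets, each channel is Poisson-corrected, and AI is the maternal
    concentration fraction.
    """
    n = counts.n_total
    hex_pos = counts.n_hex_only + counts.n_double
    fam_pos = counts.n_fam_only + counts.n_double
    if hex_pos + fam_pos == 0 or hex_pos == n or fam_pos == n:
        return None
    c_mat = poisson_concentration(hex_pos, n, droplet_volume_ul)
    c_pat = poisson_concentration(fam_pos, n, droplet_volume_ul)
    if c_mat + c_pat == 0:
        return None
    return c_mat / (c_mat + c_pat)


def auto_threshold(amplitudes, rng_seed: int = 0) -> float:
    """Midpoint between negative- and positive-cluster mean amplitudes.

    One-dimensional 2-means on the channel's amplitudes; a fallback when no
    homozygous-control gates are provided. Manual thresholds remain the
    default.
    """
    x = np.sort(np.asarray(amplitudes, dtype=float))
    if x.size < 2 or x[0] == x[-1]:
        raise ValueError("cannot separate clusters in a constant signal")
    centers = np.array([x[0], x[-1]])
    for _ in range(100):
        mid = centers.mean()
        lo, hi = x[x <= mid], x[x > mid]
        if lo.size == 0 or hi.size == 0:
            break
        new = np.array([lo.mean(), hi.mean()])
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    return float(centers.mean())


# ---------------------------------------------------------------------------
# droplet simulation


_AMP = dict(neg_mean=1000.0, neg_sd=100.0, pos_mean=6000.0, pos_sd=300.0)


def _amplitudes(positive: np.ndarray, rng: np.random.Generator,
                neg_mean, neg_sd, pos_mean, pos_sd) -> np.ndarray:
    amp = rng.normal(neg_mean, neg_sd, size=positive.size)
    amp[positive] = rng.normal(pos_mean, pos_sd, size=int(positive.sum()))
    return amp


def simulate_droplets(true_ai: float, n_droplets: int,
                      mean_copies_per_droplet: float = 0.15,
                      seed: int = 0, **amp_params):
    """Poisson-occupancy droplet simulation at a known allelic imbalance.

    Maternal and paternal template copies per droplet are independent
    Poisson draws with rates split by ``true_ai``. Returns
    (fam_amplitudes, hex_amplitudes, true DropletCounts).
    """
    if not 0.0 <= true_ai <= 1.0:
        raise ValueError("true_ai must be in [0, 1]")
    p = {**_AMP, **amp_params}
    rng = np.random.default_rng(seed)
    lam = mean_copies_per_droplet
    mat = rng.poisson(lam * true_ai, size=n_droplets) > 0
    pat = rng.poisson(lam * (1.0 - true_ai), size=n_droplets) > 0
    counts = DropletCounts(
        n_empty=int((~mat & ~pat).sum()),
        n_fam_only=int((pat & ~mat).sum()),
        n_hex_only=int((mat & ~pat).sum()),
        n_double=int((mat & pat).sum()),
    )
    hex_amp = _amplitudes(mat, rng, **p)
    fam_amp = _amplitudes(pat, rng, **p)
    return fam_amp, hex_amp, counts


def simulate_droplets_from_counts(counts: DropletCounts, seed: int = 0,
                                  **amp_params):
    """Amplitudes for exactly the requested category counts (no sampling of
    occupancy), shuffled into a random droplet order."""
    p = {**_AMP, **amp_params}
    rng = np.random.default_rng(seed)
    mat = np.zeros(counts.n_total, dtype=bool)
    pat = np.zeros(counts.n_total, dtype=bool)
    i = counts.n_empty
    pat[i : i + counts.n_fam_only] = True
    i += counts.n_fam_only
    mat[i : i + counts.n_hex_only] = True
    i += counts.n_hex_only
    mat[i:] = True
    pat[i:] = True
    order = rng.permutation(counts.n_total)
    mat, pat = mat[order], pat[order]
    hex_amp = _amplitudes(mat, rng, **p)
    fam_amp = _amplitudes(pat, rng, **p)
    return fam_amp, hex_amp


def read_droplets(path) -> tuple[np.ndarray, np.ndarray]:
    """droplets.csv with columns fam_amplitude, hex_amplitude."""
    df = pd.read_csv(path)
    for col in ("fam_amplitude", "hex_amplitude"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return df["fam_amplitude"].to_numpy(float), df["hex_amplitude"].to_numpy(float)


def write_droplets(fam_amplitudes, hex_amplitudes, path) -> None:
    pd.DataFrame({"fam_amplitude": fam_amplitudes,
                  "hex_amplitude": hex_amplitudes}).to_csv(path, index=False)
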