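"""Synthetic paired-FASTQ generation with known ground-truth allele fractions.

Emulates the targeted screening library: for every (assay, well) a binomial
number of maternal cDNA molecules is drawn at the well's true allelic
imbalance; UMI assays tag each molecule with a random UMI and emit a
1 + Poisson(mean-1) number of PCR-duplicate read pairs, non-UMI assays emit
one read pair per molecule. Read 1 carries BC1 + spacer (+ UMI); read 2
carries BC2 + spacer + the amplicon prefix with the SNP base set to the
molecule's allele. Substitution errors are applied i.i.d. per base after
read assembly. Output is deterministic and byte-identical for a fixed seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    AssayDef,
    AssayType,
    BarcodePair,
    ReadStructure,
    ScreenDesign,
    WellCondition,
    hamming,
    plate_wells,
)

__all__ = [
    "SimParams",
    "simulate_screen",
    "synthetic_panel",
    "synthetic_barcodes",
    "uniform_truth",
    "write_truth",
    "read_truth",
    "DEFAULT_SPACER",
]

DEFAULT_SPACER = "TTTTTTT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PAD = ord("A")


@dataclass
class SimParams:
    """Simulation settings.

    true_ai maps (gene, well) -> fraction of maternal (129) molecules.
    Qualities are constant ``base_qual`` except at simulated error positions,
    which get ``error_qual``.
    """

    true_ai: dict[tuple[str, str], float]
    molecules_per_assay_well: int = 1000
    mean_pcr_duplication: float = 1.0
    substitution_error_rate: float = 0.0
    seed: int = 0
    read_structure: ReadStructure = field(default_factory=ReadStructure)
    spacer: str = DEFAULT_SPACER
    base_qual: int = 37
    error_qual: int = 14

    def __post_init__(self) -> None:
        for (gene, well), ai in self.true_ai.items():
            if not 0.0 <= ai <= 1.0:
                raise ValueError(f"true_ai[{gene},{well}]={ai} outside [0,1]")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must be in [0,1)")
        if self.mean_pcr_duplication < 1.0:
            raise ValueError("mean_pcr_duplication must be >= 1")
        if len(self.spacer) != self.read_structure.spacer_len:
            raise ValueError("spacer length inconsistent with read structure")


def _seq_to_codes(seq: str) -> np.ndarray:
    """ACGT string -> 0..3 code array."""
    lut = np.full(128, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("non-ACGT base in sequence")
    return codes


def _apply_errors(codes: np.ndarray, rate: float, rng: np.random.Generator):
    """Mutate ``codes`` (n_reads x L) in place; return error position mask."""
    if rate <= 0.0:
        return None
    mask = rng.random(codes.shape) < rate
    idx = np.nonzero(mask)
    if idx[0].size:
        shift = rng.integers(1, 4, size=idx[0].size, dtype=np.uint8)
        codes[idx] = (codes[idx] + shift) % 4
    return mask


class _FastqWriter:
    """Buffered gzip FASTQ writer with fixed mtime for reproducible bytes."""

    def __init__(self, path):
        raw = open(path, "wb")
        # empty filename + fixed mtime keep the gzip header byte-stable
        self._gz = gzip.GzipFile(filename="", fileobj=raw, mode="wb",
                                 compresslevel=2, mtime=0)
        self._raw = raw
        self._buf: list[bytes] = []
        self._nbytes = 0

    def write(self, name: bytes, seq: bytes, qual: bytes) -> None:
        rec = b"@%s\n%s\n+\n%s\n" % (name, seq, qual)
        self._buf.append(rec)
        self._nbytes += len(rec)
        if self._nbytes > 4 << 20:
            self.flush()

    def flush(self) -> None:
        if self._buf:
            self._gz.write(b"".join(self._buf))
            self._buf = []
            self._nbytes = 0

    def close(self) -> None:
        self.flush()
        self._gz.close()
        self._raw.close()


def simulate_screen(
    panel: list[AssayDef],
    design: ScreenDesign,
    params: SimParams,
    r1_path,
    r2_path,
) -> pd.DataFrame:
    """Write a paired FASTQ library and return the ground-truth table.

    Returns a DataFrame with one row per (assay, well): gene, assay_id, well,
    true_ai, n_molecules_maternal, n_molecules_paternal.
    """
    if not panel:
        raise ValueError("panel is empty")
    rs = params.read_structure
    for a in panel:
        if rs.insert_start + a.snp_offset >= rs.read2_len:
            raise ValueError(
                f"assay {a.assay_id}: SNP at offset {a.snp_offset} is not "
                f"covered by read 2 ({rs.read2_len} nt after "
                f"{rs.insert_start} nt of barcode+spacer)"
            )
    if not design.barcode_map:
        raise ValueError("design has no barcode map; call attach_barcodes first")
    for w in design.wells:
        for a in panel:
            if (a.gene, w.well) not in params.true_ai:
                raise ValueError(f"true_ai missing entry for ({a.gene}, {w.well})")

    rng = np.random.default_rng(params.seed)
    spacer_codes = _seq_to_codes(params.spacer)
    qual_b = bytes([params.base_qual + 33])
    qual_e = params.error_qual + 33

    # per-assay templates in 0..3 code space
    templates = []
    for a in panel:
        ins = _seq_to_codes(a.amplicon_seq[: rs.insert_len])
        r2 = np.concatenate([_seq_to_codes("A" * rs.bc_len), spacer_codes, ins])
        r1 = np.zeros(rs.read1_len, dtype=np.uint8)  # code 0 = 'A' padding
        r1[rs.bc_len : rs.insert_start] = spacer_codes
        templates.append((r1, r2))

    w1 = _FastqWriter(r1_path)
    w2 = _FastqWriter(r2_path)
    truth_rows = []
    serial = 0
    try:
        for wc in design.wells:
            pair = design.barcode_map[wc.well]
            bc1_codes = _seq_to_codes(pair.bc1)
            bc2_codes = _seq_to_codes(pair.bc2)
            for a, (t1, t2) in zip(panel, templates):
                ai = params.true_ai[(a.gene, wc.well)]
                n_mol = params.molecules_per_assay_well
                n_mat = int(rng.binomial(n_mol, ai))
                truth_rows.append(
                    {"gene": a.gene, "assay_id": a.assay_id, "well": wc.well,
                     "true_ai": ai, "n_molecules_maternal": n_mat,
                     "n_molecules_paternal": n_mol - n_mat}
                )
                serial = _emit_block(
                    a, n_mol, n_mat, t1, t2, bc1_codes, bc2_codes, params, rng,
                    w1, w2, qual_b, qual_e, serial,
                )
    finally:
        w1.close()
        w2.close()
    return pd.DataFrame(
        truth_rows,
        columns=["gene", "assay_id", "well", "true_ai",
                 "n_molecules_maternal", "n_molecules_paternal"],
    )


def _distinct_umis(n_mol: int, umi_len: int, rng: np.random.Generator) -> np.ndarray:
    """Random UMIs for one (assay, well), pairwise Hamming distance >= 2.

    Molecules within a group get mutually distinguishable tags, so UMI
    deduplication is lossless and the pipeline can be held to exact
    ground-truth recovery. Real libraries have a small tag-collision rate
    that this generator deliberately excludes (see docs).
    """
    if 4**umi_len < 20 * n_mol:
        raise ValueError("UMI space too small for collision-free tagging")
    chosen = np.empty((n_mol, umi_len), dtype=np.uint8)
    taken: set[bytes] = set()  # chosen UMIs plus their 1-neighbourhoods
    k = 0
    while k < n_mol:
        batch = rng.integers(0, 4, size=(max(32, n_mol - k), umi_len), dtype=np.uint8)
        for row in batch:
            key = row.tobytes()
            if key in taken:
                continue
            chosen[k] = row
            taken.add(key)
            b = bytearray(key)
            for i in range(umi_len):
                orig = b[i]
                for c in range(4):
                    if c != orig:
                        b[i] = c
                        taken.add(bytes(b))
                b[i] = orig
            k += 1
            if k == n_mol:
                break
    return chosen


def _emit_block(a, n_mol, n_mat, t1, t2, bc1_codes, bc2_codes, params, rng,
                w1, w2, qual_b, qual_e, serial):
    """Emit all read pairs for one (assay, well); returns updated serial."""
    if n_mol == 0:
        return serial
    rs = params.read_structure
    alleles = np.empty(n_mol, dtype=np.uint8)
    mat_code = _seq_to_codes(a.allele_maternal)[0]
    pat_code = _seq_to_codes(a.allele_paternal)[0]
    alleles[:n_mat] = mat_code
    alleles[n_mat:] = pat_code

    umi_assay = a.assay_type is AssayType.UMI
    if umi_assay:
        umis = _distinct_umis(n_mol, rs.umi_len, rng)
        if params.mean_pcr_duplication > 1.0:
            dups = 1 + rng.poisson(params.mean_pcr_duplication - 1.0, size=n_mol)
        else:
            dups = np.ones(n_mol, dtype=np.int64)
    else:
        dups = np.ones(n_mol, dtype=np.int64)
    mol_idx = np.repeat(np.arange(n_mol), dups)
    n_reads = mol_idx.size

    r1 = np.tile(t1, (n_reads, 1))
    r1[:, :rs.bc_len] = bc1_codes
    if umi_assay:
        r1[:, rs.insert_start : rs.insert_start + rs.umi_len] = umis[mol_idx]
    r2 = np.tile(t2, (n_reads, 1))
    r2[:, :rs.bc_len] = bc2_codes
    r2[:, rs.insert_start + a.snp_offset] = alleles[mol_idx]

    e = params.substitution_error_rate
    m1 = _apply_errors(r1, e, rng)
    m2 = _apply_errors(r2, e, rng)

    def _err_positions(mask):
        pos: dict[int, list[int]] = {}
        if mask is not None:
            rows, cols = np.nonzero(mask)
            for r, c in zip(rows.tolist(), cols.tolist()):
                pos.setdefault(r, []).append(c)
        return pos

    err1, err2 = _err_positions(m1), _err_positions(m2)

    s1 = _BASES[r1].tobytes()
    s2 = _BASES[r2].tobytes()
    L1, L2 = rs.read1_len, rs.read2_len
    q1_const = qual_b * L1
    q2_const = qual_b * L2

    def _qual(errs, row, const):
        cols = errs.get(row)
        if cols is None:
            return const
        q = bytearray(const)
        for j in cols:
            q[j] = qual_e
        return bytes(q)

    for i in range(n_reads):
        name = b"sim_%09d" % (serial + i)
        w1.write(name, s1[i * L1 : (i + 1) * L1], _qual(err1, i, q1_const))
        w2.write(name, s2[i * L2 : (i + 1) * L2], _qual(err2, i, q2_const))
    return serial + n_reads


# ---------------------------------------------------------------------------
# synthetic panel / barcodes / truth helpers


def synthetic_panel(
    n_assays: int = 27,
    n_genes: int = 23,
    seed: int = 7,
    amplicon_len_range: tuple[int, int] = (250, 450),
    snp_offset_range: tuple[int, int] = (20, 110),
    read_structure: ReadStructure | None = None,
) -> list[AssayDef]:
    """Random but valid assay panel.

    Genes beyond ``n_genes`` get a second assay of the other readout type,
    mirroring a panel where a subset of genes is measured both with and
    without UMIs. SNP offsets stay within the read-2 window.
    """
    if n_assays < n_genes:
        n_genes = n_assays
    rs = read_structure or ReadStructure()
    rng = np.random.default_rng(seed)
    assays: list[AssayDef] = []
    genes = [f"Gene{i + 1:02d}" for i in range(n_genes)]
    gene_of = genes + [genes[i % n_genes] for i in range(n_assays - n_genes)]
    for i in range(n_assays):
        n = int(rng.integers(*amplicon_len_range, endpoint=True))
        off_hi = min(snp_offset_range[1], rs.insert_len - 1, n - 1)
        off = int(rng.integers(snp_offset_range[0], off_hi, endpoint=True))
        codes = rng.integers(0, 4, size=n, dtype=np.uint8)
        seq = _BASES[codes].tobytes().decode()
        ref = seq[off]
        alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        mat, pat = (ref, alt) if rng.random() < 0.5 else (alt, ref)
        seq = seq[:off] + mat + seq[off + 1 :]
        atype = AssayType.UMI if i % 2 == 0 else AssayType.NON_UMI
        assays.append(
            AssayDef(
                assay_id=f"{gene_of[i]}_a{i + 1}",
                gene=gene_of[i],
                amplicon_seq=seq,
                snp_offset=off,
                allele_maternal=mat,
                allele_paternal=pat,
                assay_type=atype,
            )
        )
    return assays


def _random_whitelist(n: int, length: int, min_dist: int,
                      rng: np.random.Generator) -> list[str]:
    wl: list[str] = []
    attempts = 0
    while len(wl) < n:
        cand = _BASES[rng.integers(0, 4, size=length, dtype=np.uint8)].tobytes().decode()
        if all(hamming(cand, w) >= min_dist for w in wl):
            wl.append(cand)
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not build barcode whitelist")
    return wl


def synthetic_barcodes(
    wells: list[str] | None = None,
    seed: int = 11,
    plate_id: str = "plate1",
    min_distance: int = 2,
) -> list[BarcodePair]:
    """Combinatorial barcode grid: 8 row BC1s x 12 column BC2s -> 96 wells."""
    wells = wells if wells is not None else plate_wells()
    rng = np.random.default_rng(seed)
    bc1s = _random_whitelist(8, 6, min_distance, rng)
    bc2s = _random_whitelist(12, 6, min_distance, rng)
    grid = {f"{r}{c:02d}": (bc1s[i], bc2s[j])
            for i, r in enumerate("ABCDEFGH")
            for j, c in enumerate(range(1, 13))}
    pairs = []
    for w in wells:
        if w not in grid:
            raise ValueError(f"well {w!r} is not a 96-well coordinate")
        b1, b2 = grid[w]
        pairs.append(BarcodePair(bc1=b1, bc2=b2, well=w, plate_id=plate_id))
    return pairs


def uniform_truth(
    panel: list[AssayDef],
    design: ScreenDesign,
    ai: float = 0.5,
    overrides: dict[tuple[str, str], float] | None = None,
) -> dict[tuple[str, str], float]:
    """(gene, well) -> true AI map, constant with optional per-entry overrides."""
    truth = {(a.gene, w.well): ai for a in panel for w in design.wells}
    if overrides:
        for key, v in overrides.items():
            if key not in truth:
                raise KeyError(f"override {key} not in panel x design")
            truth[key] = v
    return truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
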