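"""Demultiplexing and allele-specific, UMI-corrected counting.

The computational core of the screen: paired reads are resolved to a well by
their combinatorial barcode pair (both barcodes must agree), to an assay by
closed-panel matching of the read-2 insert against the known amplicons, and
to an allele by the base observed at the SNP position. For UMI assays,
PCR duplicates are collapsed with directional UMI clustering; for non-UMI
assays raw reads are counted.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
import pysam

from .panel import (
    AssayDef,
    AssayType,
    BarcodePair,
    ReadStructure,
    ScreenDesign,
    hamming,
)

__all__ = [
    "MATERNAL",
    "PATERNAL",
    "AMBIGUOUS",
    "ParsedRead",
    "AllelicCount",
    "match_barcode",
    "assign_assay",
    "call_allele",
    "collapse_umis",
    "count_screen",
]

# allele call codes (indices into per-UMI tally vectors)
MATERNAL = 0
PATERNAL = 1
AMBIGUOUS = 2

_ASSAY_KEY_LEN = 12  # exact-match prefix index for the fast assay lookup path


@dataclass(frozen=True)
class ParsedRead:
    bc1_obs: str
    bc2_obs: str
    umi_obs: str
    insert: str
    insert_quals: str


@dataclass(frozen=True)
class AllelicCount:
    gene: str
    assay_id: str
    well: str
    count_maternal: int
    count_paternal: int
    count_ambiguous: int
    n_raw_reads: int

    def __post_init__(self) -> None:
        called = self.count_maternal + self.count_paternal + self.count_ambiguous
        if min(self.count_maternal, self.count_paternal,
               self.count_ambiguous, self.n_raw_reads) < 0 or called > self.n_raw_reads:
            raise ValueError("inconsistent allelic counts")


def parse_read_pair(r1_seq: str, r2_seq: str, r2_quals: str,
                    rs: ReadStructure) -> ParsedRead:
    """Split a read pair into barcodes, UMI window, and insert.

    The UMI window on read 1 is always extracted; it is only meaningful for
    UMI assays (for non-UMI assays it contains padding).
    """
    s = rs.insert_start
    return ParsedRead(
        bc1_obs=r1_seq[: rs.bc_len],
        bc2_obs=r2_seq[: rs.bc_len],
        umi_obs=r1_seq[s : s + rs.umi_len],
        insert=r2_seq[s:],
        insert_quals=r2_quals[s:],
    )


# ---------------------------------------------------------------------------
# barcode matching


def match_barcode(observed: str, whitelist: Iterable[str],
                  max_mismatch: int = 1) -> str | None:
    """Resolve an observed barcode to the unique whitelist entry within
    ``max_mismatch`` substitutions; None if no match or a tie."""
    best: str | None = None
    best_d = max_mismatch + 1
    tied = False
    for bc in whitelist:
        if len(bc) != len(observed):
            continue
        d = hamming(observed, bc)
        if d < best_d:
            best, best_d, tied = bc, d, False
        elif d == best_d:
            tied = True
    if best is None or tied:
        return None
    return best


def _correction_table(whitelist: list[str], max_mismatch: int) -> dict[str, str]:
    """Observed barcode -> corrected barcode, for all sequences within
    max_mismatch of exactly one whitelist entry. O(1) lookup per read."""
    table: dict[str, str | None] = {bc: bc for bc in whitelist}
    if max_mismatch >= 1:
        for bc in whitelist:
            for i, alt in itertools.product(range(len(bc)), "ACGT"):
                if alt == bc[i]:
                    continue
                neigh = bc[:i] + alt + bc[i + 1 :]
                if neigh in table and table[neigh] != bc:
                    table[neigh] = None  # ambiguous between two entries
                elif neigh not in table:
                    table[neigh] = bc
    if max_mismatch >= 2:
        raise NotImplementedError("barcode correction supports <= 1 mismatch")
    return {k: v for k, v in table.items() if v is not None}


# ---------------------------------------------------------------------------
# assay assignment


def _mismatch_frac(insert: str, expected: str, snp_offset: int) -> float:
    """Mismatch fraction over the overlap, SNP position excluded."""
    n = min(len(insert), len(expected))
    if n == 0:
        return 1.0
    mm = sum(a != b for a, b in zip(insert[:n], expected[:n]))
    denom = n
    if snp_offset < n:
        denom -= 1
        if insert[snp_offset] != expected[snp_offset]:
            mm -= 1
    if denom == 0:
        return 1.0
    return mm / denom


def assign_assay(insert: str, panel: list[AssayDef],
                 max_mismatch_frac: float = 0.1) -> str | None:
    """Closed-panel matching: compare the insert to each amplicon over the
    overlap, excluding the SNP base so allele state cannot bias assignment.
    Returns the unique qualifying assay_id, or None."""
    if not insert:
        return None
    hits = [a.assay_id for a in panel
            if _mismatch_frac(insert, a.amplicon_seq, a.snp_offset)
            <= max_mismatch_frac]
    if len(hits) == 1:
        return hits[0]
    return None


# ---------------------------------------------------------------------------
# allele calling


def call_allele(insert: str, quals: str, assay: AssayDef,
                min_phred: int = 20) -> int:
    """Base at the SNP -> MATERNAL/PATERNAL; third allele, low quality, or a
    truncated insert -> AMBIGUOUS."""
    off = assay.snp_offset
    if off >= len(insert):
        return AMBIGUOUS
    if quals and ord(quals[off]) - 33 < min_phred:
        return AMBIGUOUS
    base = insert[off]
    if base == assay.allele_maternal:
        return MATERNAL
    if base == assay.allele_paternal:
        return PATERNAL
    return AMBIGUOUS


# ---------------------------------------------------------------------------
# UMI collapse


def _neighbors1(umi: str) -> Iterable[str]:
    for i in range(len(umi)):
        for alt in "ACGT":
            if alt != umi[i]:
                yield umi[:i] + alt + umi[i + 1 :]


def directional_clusters(counts: dict[str, int]) -> list[list[str]]:
    """Directional UMI clustering.

    UMI b is merged into UMI a when Hamming(a, b) <= 1 and
    reads(a) >= 2*reads(b) - 1; clusters grow transitively from the most
    abundant unassigned UMI downward. Ties are broken lexicographically so
    the partition is deterministic.
    """
    order = sorted(counts, key=lambda u: (-counts[u], u))
    assigned: set[str] = set()
    clusters: list[list[str]] = []
    for root in order:
        if root in assigned:
            continue
        cluster = [root]
        assigned.add(root)
        frontier = [root]
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                cu = counts[u]
                for v in _neighbors1(u):
                    if v in counts and v not in assigned and cu >= 2 * counts[v] - 1:
                        assigned.add(v)
                        cluster.append(v)
                        nxt.append(v)
            frontier = nxt
        clusters.append(cluster)
    return clusters


def collapse_umis(records: list[tuple[str, int]],
                  method: str = "directional") -> tuple[int, int, int]:
    """UMI-corrected molecule counts for one gene x well.

    ``records`` is a list of (umi, allele_call) read-level tuples. Each UMI
    cluster yields one molecule whose allele is the majority call among the
    cluster's reads (ties -> ambiguous). ``method`` is "directional" or
    "identity" (every distinct UMI = one molecule).
    """
    if not records:
        return (0, 0, 0)
    tallies: dict[str, list[int]] = defaultdict(lambda: [0, 0, 0])
    for umi, call in records:
        tallies[umi][call] += 1
    return _collapse_tallies(dict(tallies), method)


def _collapse_tallies(tallies: dict[str, list[int]], method: str) -> tuple[int, int, int]:
    if method == "identity":
        clusters = [[u] for u in tallies]
    elif method == "directional":
        counts = {u: sum(t) for u, t in tallies.items()}
        clusters = directional_clusters(counts)
    else:
        raise ValueError(f"unknown UMI collapse method {method!r}")
    out = [0, 0, 0]
    for cluster in clusters:
        m = sum(tallies[u][MATERNAL] for u in cluster)
        p = sum(tallies[u][PATERNAL] for u in cluster)
        a = sum(tallies[u][AMBIGUOUS] for u in cluster)
        top = max(m, p, a)
        if (m == top) + (p == top) + (a == top) > 1:
            out[AMBIGUOUS] += 1
        elif m == top:
            out[MATERNAL] += 1
        elif p == top:
            out[PATERNAL] += 1
        else:
            out[AMBIGUOUS] += 1
    return tuple(out)


# ---------------------------------------------------------------------------
# full streaming pipeline


def _assay_key_index(panel: list[AssayDef], rs: ReadStructure) -> dict[str, AssayDef]:
    """Exact-match index on the first bases of the insert.

    Keys include both allele variants when the SNP falls inside the key
    window. Prefixes shared by two assays are dropped (those reads take the
    slow path)."""
    k = min(_ASSAY_KEY_LEN, rs.insert_len)
    index: dict[str, AssayDef | None] = {}
    for a in panel:
        variants = {a.with_allele(a.allele_maternal)[:k],
                    a.with_allele(a.allele_paternal)[:k]}
        for key in variants:
            if index.get(key, a) is not a:
                index[key] = None
            else:
                index[key] = a
    return {key: a for key, a in index.items() if a is not None}


def count_screen(
    r1_path,
    r2_path,
    panel: list[AssayDef],
    barcodes: list[BarcodePair],
    design: ScreenDesign,
    read_structure: ReadStructure | None = None,
    *,
    max_bc_mismatch: int = 1,
    min_phred: int = 20,
    max_mismatch_frac: float = 0.1,
    umi_collapse: str = "directional",
) -> tuple[pd.DataFrame, dict]:
    """Stream a paired FASTQ library into per-(assay, well) allelic counts.

    Returns (counts table, run summary). The counts table has one row per
    (assay, well) with at least one assigned read, annotated with the well's
    condition; the summary tallies assigned and unassigned read pairs
    (assigned + unassigned = total, always).
    """
    rs = read_structure or ReadStructure()
    bc1_table = _correction_table(sorted({p.bc1 for p in barcodes}), max_bc_mismatch)
    bc2_table = _correction_table(sorted({p.bc2 for p in barcodes}), max_bc_mismatch)
    pair_to_well = {(p.bc1, p.bc2): p.well for p in barcodes}
    design_wells = set(design.well_names)
    key_index = _assay_key_index(panel, rs)
    klen = min(_ASSAY_KEY_LEN, rs.insert_len)
    by_id = {a.assay_id: a for a in panel}
    # precomputed full-length allele variants for the fast verification path
    variants = {a.assay_id: (a.with_allele(a.allele_maternal)[: rs.insert_len],
                             a.with_allele(a.allele_paternal)[: rs.insert_len])
                for a in panel}

    s = rs.insert_start
    umi_end = s + rs.umi_len
    summary = {
        "total_pairs": 0,
        "assigned": 0,
        "unassigned_barcode": 0,
        "unassigned_well": 0,
        "unassigned_assay": 0,
        "allele_maternal_reads": 0,
        "allele_paternal_reads": 0,
        "allele_ambiguous_reads": 0,
    }
    # (assay_id, well) -> {umi: [m, p, a]} for UMI assays, [m, p, a] otherwise
    umi_groups: dict[tuple[str, str], dict[str, list[int]]] = defaultdict(dict)
    raw_groups: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0, 0])
    raw_reads: dict[tuple[str, str], int] = defaultdict(int)

    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for i, (rec1, rec2) in enumerate(zip(f1, f2)):
            summary["total_pairs"] += 1
            if rec1.name != rec2.name:
                raise ValueError(f"read-pair name mismatch at record {i}: "
                                 f"{rec1.name} vs {rec2.name}")
            seq1, seq2 = rec1.sequence, rec2.sequence
            bc1 = bc1_table.get(seq1[: rs.bc_len])
            bc2 = bc2_table.get(seq2[: rs.bc_len])
            if bc1 is None or bc2 is None:
                summary["unassigned_barcode"] += 1
                continue
            well = pair_to_well.get((bc1, bc2))
            if well is None or well not in design_wells:
                summary["unassigned_well"] += 1
                continue
            insert = seq2[s:]
            assay = key_index.get(insert[:klen])
            if assay is not None:
                vm, vp = variants[assay.assay_id]
                if insert != vm and insert != vp:
                    if _mismatch_frac(insert, assay.amplicon_seq,
                                      assay.snp_offset) > max_mismatch_frac:
                        assay = None
            if assay is None:
                aid = assign_assay(insert, panel, max_mismatch_frac)
                assay = by_id.get(aid) if aid else None
            if assay is None:
                summary["unassigned_assay"] += 1
                continue
            summary["assigned"] += 1
            call = call_allele(insert, rec2.quality[s:], assay, min_phred)
            if call == MATERNAL:
                summary["allele_maternal_reads"] += 1
            elif call == PATERNAL:
                summary["allele_paternal_reads"] += 1
            else:
                summary["allele_ambiguous_reads"] += 1
            key = (assay.assay_id, well)
            raw_reads[key] += 1
            if assay.assay_type is AssayType.UMI:
                umi = seq1[s:umi_end]
                tally = umi_groups[key].get(umi)
                if tally is None:
                    umi_groups[key][umi] = tally = [0, 0, 0]
                tally[call] += 1
            else:
                raw_groups[key][call] += 1

    rows = []
    for key in sorted(set(umi_groups) | set(raw_groups)):
        aid, well = key
        assay = by_id[aid]
        if key in umi_groups:
            m, p, amb = _collapse_tallies(umi_groups[key], umi_collapse)
        else:
            m, p, amb = raw_groups[key]
        cond = design.condition(well)
        pair = design.barcode_map.get(well) if design.barcode_map else None
        rows.append({
            "plate_id": pair.plate_id if pair else "plate1",
            "well": well,
            "drug": cond.drug if cond.drug is not None else "NONE",
            "conc_uM": cond.concentration,
            "day": cond.timepoint,
            "control_kind": cond.control_kind.value,
            "gene": assay.gene,
            "assay_id": aid,
            "n_raw_reads": raw_reads[key],
            "count_129": m,
            "count_cast": p,
            "count_ambiguous": amb,
        })
    cols = ["plate_id", "well", "drug", "conc_uM", "day", "control_kind",
            "gene", "assay_id", "n_raw_reads", "count_129", "count_cast",
            "count_ambiguous"]
    counts = pd.DataFrame(rows, columns=cols)
    unassigned = (summary["unassigned_barcode"] + summary["unassigned_well"]
                  + summary["unassigned_assay"])
    summary["unassigned"] = unassigned
    assert summary["assigned"] + unassigned == summary["total_pairs"]
    return counts, summary


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
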