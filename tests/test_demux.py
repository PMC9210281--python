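"""Demultiplexing, allele calling, UMI collapse (vs brute-force oracle),
and the end-to-end counting pipeline."""

import dataclasses
import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenseq.demux import (
    AMBIGUOUS,
    MATERNAL,
    PATERNAL,
    AllelicCount,
    assign_assay,
    call_allele,
    collapse_umis,
    count_screen,
    directional_clusters,
    match_barcode,
    parse_read_pair,
)
from screenseq.panel import AssayDef, AssayType, ReadStructure, hamming, plate_layout
from screenseq.simulate import (
    SimParams,
    simulate_screen,
    synthetic_barcodes,
    synthetic_panel,
    uniform_truth,
)

WHITELIST = ["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT", "AACCGG"]


class TestMatchBarcode:
    def test_exact(self):
        assert match_barcode("CCCCCC", WHITELIST) == "CCCCCC"

    def test_one_mismatch_unique(self):
        assert match_barcode("CACCCC", WHITELIST) == "CCCCCC"

    def test_distance_two_unassigned(self):
        assert match_barcode("CACACC", WHITELIST) is None

    def test_tie_unassigned(self):
        # equidistant (1) from two whitelist entries
        assert match_barcode("AACCGA", ["AACCGG", "AACCAA"]) is None

    def test_length_mismatch_unassigned(self):
        assert match_barcode("AAAAA", WHITELIST) is None

    @given(st.text(alphabet="ACGT", min_size=6, max_size=6))
    def test_matches_exhaustive_rule(self, observed):
        got = match_barcode(observed, WHITELIST, max_mismatch=1)
        within = [bc for bc in WHITELIST if hamming(observed, bc) <= 1]
        assert got == (within[0] if len(within) == 1 else None)


def _toy_assay(seq="ACGTACGTACGTACGTACGT" * 5, off=10, atype=AssayType.NON_UMI,
               aid="t1", gene="G1"):
    mat = seq[off]
    pat = "ACGT"[("ACGT".index(mat) + 1) % 4]
    return AssayDef(aid, gene, seq, off, mat, pat, atype)


@pytest.fixture(scope="module")
def panel():
    return synthetic_panel(6, 6, seed=13)


class TestAssignAssay:

    def test_exact_prefix_either_allele(self, panel):
        for a in panel[:3]:
            for allele in (a.allele_maternal, a.allele_paternal):
                insert = a.with_allele(allele)[:122]
                assert assign_assay(insert, panel) == a.assay_id

    def test_five_percent_errors_still_assigned(self, panel, rng):
        a = panel[0]
        insert = list(a.amplicon_seq[:100])
        for i in rng.choice(100, size=5, replace=False):
            if i != a.snp_offset:
                insert[i] = "ACGT"[("ACGT".index(insert[i]) + 1) % 4]
        assert assign_assay("".join(insert), panel) == a.assay_id

    def test_random_insert_unassigned(self, panel, rng):
        junk = "".join(rng.choice(list("ACGT"), size=122))
        assert assign_assay(junk, panel) is None

    def test_empty_insert_unassigned(self, panel):
        assert assign_assay("", panel) is None

    def test_snp_position_excluded_from_mismatches(self):
        # insert matching except a third (non-allele) base at the SNP
        a = _toy_assay()
        third = next(b for b in "ACGT"
                     if b not in (a.allele_maternal, a.allele_paternal))
        insert = a.amplicon_seq[:a.snp_offset] + third + \
            a.amplicon_seq[a.snp_offset + 1:30]
        assert assign_assay(insert, [a], max_mismatch_frac=0.0) == a.assay_id


class TestCallAllele:
    def test_allele_calls(self):
        a = _toy_assay()
        q37 = "F" * len(a.amplicon_seq)
        assert call_allele(a.with_allele(a.allele_maternal), q37, a) == MATERNAL
        assert call_allele(a.with_allele(a.allele_paternal), q37, a) == PATERNAL
        third = next(b for b in "ACGT"
                     if b not in (a.allele_maternal, a.allele_paternal))
        assert call_allele(a.with_allele(third), q37, a) == AMBIGUOUS

    def test_low_quality_ambiguous(self):
        a = _toy_assay()
        quals = list("F" * len(a.amplicon_seq))
        quals[a.snp_offset] = chr(10 + 33)  # Q10 < threshold 20
        assert call_allele(a.with_allele(a.allele_maternal), "".join(quals),
                           a) == AMBIGUOUS

    def test_truncated_insert_ambiguous(self):
        a = _toy_assay(off=50)
        assert call_allele(a.amplicon_seq[:40], "F" * 40, a) == AMBIGUOUS


# ---------------------------------------------------------------------------
# UMI collapse vs brute-force oracle


def brute_force_clusters(counts):
    """Independent oracle: repeatedly take the most abundant unassigned UMI
    (lexicographic tie-break) and grow its cluster to a fixed point by set
    expansion over the directional merge condition."""
    unassigned = set(counts)
    clusters = []
    while unassigned:
        root = sorted(unassigned, key=lambda u: (-counts[u], u))[0]
        cluster = {root}
        unassigned.discard(root)
        changed = True
        while changed:
            changed = False
            for a in sorted(cluster):
                for b in sorted(unassigned):
                    if (len(a) == len(b)
                            and sum(x != y for x, y in zip(a, b)) <= 1
                            and counts[a] >= 2 * counts[b] - 1):
                        cluster.add(b)
                        unassigned.discard(b)
                        changed = True
        clusters.append(sorted(cluster))
    return sorted(sorted(c) for c in clusters)


class TestCollapseUmis:
    def test_single_molecule(self):
        assert collapse_umis([("AAAAAAAAAA", MATERNAL)] * 5) == (1, 0, 0)

    def test_satellite_merged(self):
        recs = [("AAAAAAAAAA", PATERNAL)] * 9 + [("AAAAAAAAAT", PATERNAL)]
        assert collapse_umis(recs) == (0, 1, 0)  # 9 >= 2*1-1 merges the pair

    def test_two_distant_clusters(self):
        recs = [("AAAAAAAAAA", MATERNAL)] * 2 + [("TTTTTTTTTT", PATERNAL)] * 2
        assert collapse_umis(recs) == (1, 1, 0)

    def test_equal_counts_merge_both_ways(self):
        # 1 >= 2*1-1: singletons at Hamming 1 collapse to one molecule
        recs = [("AAAAAAAAAA", MATERNAL), ("AAAAAAAAAT", MATERNAL)]
        assert collapse_umis(recs) == (1, 0, 0)

    def test_no_merge_when_count_rule_fails(self):
        # 2 < 2*2-1 = 3: neither absorbs the other
        recs = [("AAAAAAAAAA", MATERNAL)] * 2 + [("AAAAAAAAAT", PATERNAL)] * 2
        assert collapse_umis(recs) == (1, 1, 0)

    def test_allele_tie_is_ambiguous(self):
        recs = [("AAAAAAAAAA", MATERNAL), ("AAAAAAAAAA", PATERNAL)]
        assert collapse_umis(recs) == (0, 0, 1)

    def test_identity_method(self):
        recs = [("AAAAAAAAAA", MATERNAL), ("AAAAAAAAAT", MATERNAL)]
        assert collapse_umis(recs, method="identity") == (2, 0, 0)

    def test_empty(self):
        assert collapse_umis([]) == (0, 0, 0)

    def test_molecules_never_exceed_reads(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            recs = [("".join(rng.choice(list("ACGT"), size=4)),
                     int(rng.integers(0, 3))) for _ in range(n)]
            m, p, a = collapse_umis(recs)
            assert 0 < m + p + a <= n

    def test_oracle_equivalence_1000_random_cases(self):
        """Directional clustering matches the brute-force fixed-point oracle
        on >= 1000 random inputs of up to 12 distinct UMIs."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            k = int(rng.integers(1, 13))
            # short UMIs so Hamming-1 adjacency is common
            distinct = {"".join(rng.choice(list("ACGT"), size=3))
                        for _ in range(k)}
            umis = {u: int(c) for u, c in
                    zip(sorted(distinct), rng.integers(1, 20, size=len(distinct)))}
            got = sorted(sorted(c) for c in directional_clusters(umis))
            assert got == brute_force_clusters(umis)

    @given(st.dictionaries(st.text(alphabet="ACGT", min_size=3, max_size=3),
                           st.integers(1, 30), min_size=1, max_size=10))
    def test_oracle_equivalence_property(self, umis):
        got = sorted(sorted(c) for c in directional_clusters(umis))
        assert got == brute_force_clusters(umis)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _run(tmp_path, panel, design, barcodes, **sim_kw):
    params = SimParams(**sim_kw)
    r1, r2 = tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz"
    gt = simulate_screen(panel, design, params, r1, r2)
    counts, summary = count_screen(r1, r2, panel, barcodes, design)
    return gt, counts, summary


class TestCountScreen:
    def test_exact_ground_truth_recovery(self, tmp_path, mini_panel,
                                         control_design, barcodes):
        truth = uniform_truth(mini_panel, control_design, 0.37)
        gt, counts, summary = _run(tmp_path, mini_panel, control_design,
                                   barcodes, true_ai=truth,
                                   molecules_per_assay_well=500, seed=11)
        m = gt.merge(counts, on=["gene", "assay_id", "well"])
        assert len(m) == len(gt)
        assert (m.count_129 == m.n_molecules_maternal).all()
        assert (m.count_cast == m.n_molecules_paternal).all()
        assert (m.count_ambiguous == 0).all()
        assert summary["unassigned"] == 0

    def test_read_conservation_with_errors(self, tmp_path, mini_panel,
                                           control_design, barcodes):
        truth = uniform_truth(mini_panel, control_design, 0.5)
        _, counts, summary = _run(tmp_path, mini_panel, control_design,
                                  barcodes, true_ai=truth,
                                  molecules_per_assay_well=200, seed=12,
                                  substitution_error_rate=0.01,
                                  mean_pcr_duplication=2.0)
        assert summary["assigned"] + summary["unassigned"] == summary["total_pairs"]
        assert (counts.n_raw_reads >= counts.count_129 + counts.count_cast
                + counts.count_ambiguous).all()

    def test_umi_collapse_reduces_duplicates(self, tmp_path, mini_panel,
                                             control_design, barcodes):
        truth = uniform_truth(mini_panel, control_design, 0.5)
        gt, counts, _ = _run(tmp_path, mini_panel, control_design, barcodes,
                             true_ai=truth, molecules_per_assay_well=300,
                             seed=13, mean_pcr_duplication=4.0)
        umi_ids = {a.assay_id for a in mini_panel if a.assay_type is AssayType.UMI}
        sub = counts[counts.assay_id.isin(umi_ids)]
        assert (sub.n_raw_reads > sub.count_129 + sub.count_cast).all()
        m = gt.merge(sub, on=["gene", "assay_id", "well"])
        assert (m.count_129 == m.n_molecules_maternal).all()
        assert (m.count_cast == m.n_molecules_paternal).all()

    def test_allele_swap_symmetry(self, tmp_path, mini_panel, control_design,
                                  barcodes):
        truth = uniform_truth(mini_panel, control_design, 0.25)
        params = SimParams(true_ai=truth, molecules_per_assay_well=150, seed=14)
        r1, r2 = tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz"
        simulate_screen(mini_panel, control_design, params, r1, r2)
        counts, _ = count_screen(r1, r2, mini_panel, barcodes, control_design)
        swapped_panel = [
            dataclasses.replace(a, allele_maternal=a.allele_paternal,
                                allele_paternal=a.allele_maternal)
            for a in mini_panel
        ]
        swapped, _ = count_screen(r1, r2, swapped_panel, barcodes, control_design)
        m = counts.merge(swapped, on=["assay_id", "well"], suffixes=("", "_sw"))
        assert (m.count_129 == m.count_cast_sw).all()
        assert (m.count_cast == m.count_129_sw).all()

    def test_empty_fastq(self, tmp_path, mini_panel, control_design, barcodes):
        r1, r2 = tmp_path / "e1.fq.gz", tmp_path / "e2.fq.gz"
        for p in (r1, r2):
            with gzip.open(p, "wt"):
                pass
        counts, summary = count_screen(r1, r2, mini_panel, barcodes,
                                       control_design)
        assert counts.empty and summary["total_pairs"] == 0

    def test_row_bound(self, tmp_path, mini_panel, control_design, barcodes):
        truth = uniform_truth(mini_panel, control_design, 0.5)
        _, counts, _ = _run(tmp_path, mini_panel, control_design, barcodes,
                            true_ai=truth, molecules_per_assay_well=30, seed=15)
        assert len(counts) <= len(mini_panel) * len(control_design.wells)

    def test_foreign_barcode_unassigned(self, tmp_path, mini_panel,
                                        control_design, barcodes):
        truth = uniform_truth(mini_panel, control_design, 0.5)
        params = SimParams(true_ai=truth, molecules_per_assay_well=50, seed=16)
        r1, r2 = tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz"
        simulate_screen(mini_panel, control_design, params, r1, r2)
        # drop half the wells from the demux design: their reads must land
        # in unassigned_well, never in another well's counts
        kept_wells = control_design.well_names[:12]
        design2 = plate_layout([], [], 6, 6).attach_barcodes(
            [p for p in barcodes if p.well in kept_wells])
        kept_bcs = [p for p in barcodes if p.well in kept_wells]
        counts, summary = count_screen(r1, r2, mini_panel, kept_bcs, design2)
        assert set(counts.well) <= set(kept_wells)
        assert summary["unassigned"] > 0
        assert summary["assigned"] + summary["unassigned"] == summary["total_pairs"]


class TestAllelicCount:
    def test_inconsistent_rejected(self):
        with pytest.raises(ValueError):
            AllelicCount("g", "a", "A01", 5, 5, 5, 10)

    def test_parse_read_pair_windows(self):
        rs = ReadStructure()
        r1 = "A" * 6 + "T" * 7 + "G" * 10 + "C" * 42
        pr = parse_read_pair(r1, "C" * 6 + "T" * 7 + "A" * 122, "F" * 135, rs)
        assert pr.bc1_obs == "A" * 6
        assert pr.bc2_obs == "C" * 6
        assert pr.umi_obs == "G" * 10
        assert pr.insert == "A" * 122
        assert len(pr.insert_quals) == 122
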