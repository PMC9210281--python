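"""Assay panel, barcode sheets, and screen design: data model, TSV I/O, validation.

The screen measures allelic imbalance (AI) for a panel of SNP-bearing
amplicons in an F1 hybrid (maternal 129S1/SvImJ x paternal Cast/EiJ).
Each readout amplicon carries one strain-distinguishing SNP; each well of a
96-well plate is encoded by a combinatorial pair of 6-nt barcodes (BC1 on
read 1, BC2 on read 2), each followed by a 7-nt spacer.
"""

from __future__ import annotations

import enum
import itertools
import re
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "AssayType",
    "ControlKind",
    "AssayDef",
    "BarcodePair",
    "WellCondition",
    "ScreenDesign",
    "ReadStructure",
    "ValidationReport",
    "validate_assay",
    "validate_barcodes",
    "hamming",
    "experimental_points",
    "read_budget",
    "plate_layout",
    "plate_wells",
    "read_panel",
    "write_panel",
    "read_barcodes",
    "write_barcodes",
    "read_design",
    "write_design",
]

_DNA = re.compile(r"^[ACGT]+$")

PLATE_CAPACITY = 96


class AssayType(str, enum.Enum):
    """UMI assays tag each cDNA molecule (3'-SNPs, oligo-dT priming);
    non-UMI assays count raw reads (internal SNPs, two gene-specific primers)."""

    UMI = "UMI"
    NON_UMI = "NON_UMI"


class ControlKind(str, enum.Enum):
    UNTREATED = "UNTREATED"
    VEHICLE = "VEHICLE"
    NA = "NA"


def _check_dna(seq: str, what: str) -> None:
    if not isinstance(seq, str) or not _DNA.match(seq):
        raise ValueError(f"{what} must be a non-empty A/C/G/T string, got {seq!r}")


@dataclass(frozen=True)
class AssayDef:
    """One readout amplicon with its strain-distinguishing SNP.

    ``snp_offset`` is a 0-based index into ``amplicon_seq``;
    ``allele_maternal`` is the 129 allele, ``allele_paternal`` the Cast allele.
    """

    assay_id: str
    gene: str
    amplicon_seq: str
    snp_offset: int
    allele_maternal: str
    allele_paternal: str
    assay_type: AssayType

    def __post_init__(self) -> None:
        _check_dna(self.amplicon_seq, "amplicon_seq")
        _check_dna(self.allele_maternal, "allele_maternal")
        _check_dna(self.allele_paternal, "allele_paternal")
        if len(self.allele_maternal) != 1 or len(self.allele_paternal) != 1:
            raise ValueError("alleles must be single bases")
        if self.allele_maternal == self.allele_paternal:
            raise ValueError("maternal and paternal alleles must differ")
        if not 0 <= self.snp_offset < len(self.amplicon_seq):
            raise ValueError(
                f"snp_offset {self.snp_offset} outside amplicon of length "
                f"{len(self.amplicon_seq)}"
            )
        if self.amplicon_seq[self.snp_offset] not in (
            self.allele_maternal,
            self.allele_paternal,
        ):
            raise ValueError(
                "amplicon base at snp_offset must equal one of the two alleles"
            )
        object.__setattr__(self, "assay_type", AssayType(self.assay_type))

    def with_allele(self, allele: str) -> str:
        """Amplicon sequence with the SNP base set to ``allele``."""
        s = self.amplicon_seq
        return s[: self.snp_offset] + allele + s[self.snp_offset + 1 :]


@dataclass(frozen=True)
class BarcodePair:
    """Combinatorial well encoding: 6-nt BC1 (read 1) + 6-nt BC2 (read 2)."""

    bc1: str
    bc2: str
    well: str
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        _check_dna(self.bc1, "bc1")
        _check_dna(self.bc2, "bc2")
        if len(self.bc1) != 6 or len(self.bc2) != 6:
            raise ValueError("barcodes must be 6 nt")


@dataclass(frozen=True)
class WellCondition:
    well: str
    drug: str | None = None
    concentration: float = 0.0  # µM
    timepoint: float = 7.0  # days of exposure
    is_control: bool = False
    control_kind: ControlKind = ControlKind.NA

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_kind", ControlKind(self.control_kind))
        if self.is_control and self.drug is not None:
            raise ValueError("control wells must not carry a drug")
        if self.is_control and self.control_kind is ControlKind.NA:
            raise ValueError("control wells need control_kind UNTREATED or VEHICLE")


@dataclass
class ScreenDesign:
    """Plate map: one condition per well, plus the well -> barcode-pair map."""

    wells: list[WellCondition]
    barcode_map: dict[str, BarcodePair] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [w.well for w in self.wells]
        if len(names) != len(set(names)):
            raise ValueError("duplicate well in design")
        for w in self.barcode_map:
            if w not in set(names):
                raise ValueError(f"barcode map references unknown well {w!r}")

    @property
    def well_names(self) -> list[str]:
        return [w.well for w in self.wells]

    def condition(self, well: str) -> WellCondition:
        for w in self.wells:
            if w.well == well:
                return w
        raise KeyError(well)

    def attach_barcodes(self, pairs: list[BarcodePair]) -> "ScreenDesign":
        by_well = {p.well: p for p in pairs}
        missing = [w.well for w in self.wells if w.well not in by_well]
        if missing:
            raise ValueError(f"no barcode pair for wells: {missing[:5]}")
        return replace(self, barcode_map={w.well: by_well[w.well] for w in self.wells})


@dataclass(frozen=True)
class ReadStructure:
    """Layout of the paired reads.

    Read 1 (from the P7 end, 65 nt): BC1 + spacer + UMI (UMI assays) + padding.
    Read 2 (from the P5 end, 135 nt): BC2 + spacer + amplicon prefix with the SNP.
    """

    bc_len: int = 6
    spacer_len: int = 7
    umi_len: int = 10
    read1_len: int = 65
    read2_len: int = 135

    def __post_init__(self) -> None:
        if self.bc_len + self.spacer_len + self.umi_len > self.read1_len:
            raise ValueError("read 1 too short for barcode + spacer + UMI")
        if self.bc_len + self.spacer_len >= self.read2_len:
            raise ValueError("read 2 too short for barcode + spacer + insert")

    @property
    def insert_start(self) -> int:
        return self.bc_len + self.spacer_len

    @property
    def insert_len(self) -> int:
        return self.read2_len - self.insert_start


# ---------------------------------------------------------------------------
# validation

#: rule identifiers emitted by validate_assay
LENGTH_RANGE = "LENGTH_RANGE"
SNP_TOO_INTERNAL = "SNP_TOO_INTERNAL"

ValidationReport = list


def validate_assay(
    assay: AssayDef,
    min_len: int = 250,
    max_len: int = 500,
    max_snp_end_dist: int = 135,
) -> ValidationReport:
    """Check the panel's geometric primer-design constraints.

    The amplicon (fragment) length must fall within [min_len, max_len] and the
    SNP must sit within ``max_snp_end_dist`` bases of the nearer amplicon end,
    so that a 135-nt read reaches it. Returns a list of violated rule names;
    an empty list means the assay passes.
    """
    report: ValidationReport = []
    n = len(assay.amplicon_seq)
    if not min_len <= n <= max_len:
        report.append(LENGTH_RANGE)
    end_dist = min(assay.snp_offset, n - 1 - assay.snp_offset)
    if end_dist > max_snp_end_dist:
        report.append(SNP_TOO_INTERNAL)
    return report


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def validate_barcodes(pairs: list[BarcodePair], min_distance: int = 2) -> None:
    """Enforce whitelist design rules.

    Each (bc1, bc2) combination must be unique per plate, and within each of
    the two whitelists all barcodes must be at pairwise Hamming distance
    >= ``min_distance`` so that single-mismatch correction is unambiguous.
    """
    seen: set[tuple[str, str, str]] = set()
    for p in pairs:
        key = (p.plate_id, p.bc1, p.bc2)
        if key in seen:
            raise ValueError(f"duplicate barcode pair {p.bc1}/{p.bc2} on {p.plate_id}")
        seen.add(key)
    for attr in ("bc1", "bc2"):
        wl = sorted({getattr(p, attr) for p in pairs})
        for a, b in itertools.combinations(wl, 2):
            if hamming(a, b) < min_distance:
                raise ValueError(
                    f"{attr} whitelist barcodes {a}/{b} closer than "
                    f"Hamming {min_distance}"
                )


# ---------------------------------------------------------------------------
# screen-size arithmetic


def experimental_points(n_snps: int, n_wells: int, n_timepoints: int) -> int:
    """Number of allele-specific measurements: SNPs x wells x collection times."""
    for v in (n_snps, n_wells, n_timepoints):
        if not isinstance(v, int) or v < 1:
            raise ValueError("all factors must be positive integers")
    return n_snps * n_wells * n_timepoints


def read_budget(points: int, depth_per_point: int) -> int:
    """Sequenced fragments needed at a given coverage depth per point."""
    if points < 1 or depth_per_point < 1:
        raise ValueError("points and depth must be >= 1")
    return points * depth_per_point


def plate_wells(n: int = PLATE_CAPACITY) -> list[str]:
    """Row-major 96-well coordinates A01..H12 (first ``n``)."""
    coords = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]
    if n > len(coords):
        raise ValueError("a plate has at most 96 wells")
    return coords[:n]


def plate_layout(
    drugs: list[str],
    concentrations: list[float],
    n_untreated: int,
    n_vehicle: int,
    timepoint: float = 7.0,
) -> ScreenDesign:
    """Lay out one plate: one well per (drug, concentration), then controls.

    Mirrors the screen's plate: e.g. 24 drugs x 3 concentrations = 72 treated
    wells plus 12 untreated and 12 vehicle (solvent-only) control wells.
    """
    n_treated = len(drugs) * len(concentrations)
    n_total = n_treated + n_untreated + n_vehicle
    if n_total > PLATE_CAPACITY:
        raise ValueError(f"{n_total} wells exceed plate capacity {PLATE_CAPACITY}")
    wells = plate_wells(n_total)
    conds: list[WellCondition] = []
    it = iter(wells)
    for drug in drugs:
        for conc in concentrations:
            conds.append(
                WellCondition(next(it), drug=drug, concentration=conc,
                              timepoint=timepoint)
            )
    for kind, count in ((ControlKind.UNTREATED, n_untreated),
                        (ControlKind.VEHICLE, n_vehicle)):
        for _ in range(count):
            conds.append(
                WellCondition(next(it), drug=None, concentration=0.0,
                              timepoint=timepoint, is_control=True,
                              control_kind=kind)
            )
    return ScreenDesign(wells=conds)


# ---------------------------------------------------------------------------
# TSV I/O  (tab-separated, header row, '#' comment lines)

_PANEL_COLS = ["assay_id", "gene", "assay_type", "amplicon_seq", "snp_offset",
               "allele_129", "allele_cast"]
_BARCODE_COLS = ["plate_id", "well", "bc1", "bc2"]
_DESIGN_COLS = ["well", "drug", "conc_uM", "day", "control_kind"]


def _read_tsv(path, cols) -> pd.DataFrame:
    # keep_default_na=False: "NA" is a valid control_kind token, not missing data
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_panel(path) -> list[AssayDef]:
    df = _read_tsv(path, _PANEL_COLS)
    assays = [
        AssayDef(
            assay_id=r.assay_id,
            gene=r.gene,
            amplicon_seq=r.amplicon_seq,
            snp_offset=int(r.snp_offset),
            allele_maternal=r.allele_129,
            allele_paternal=r.allele_cast,
            assay_type=AssayType(r.assay_type),
        )
        for r in df.itertuples()
    ]
    ids = [a.assay_id for a in assays]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate assay_id in panel")
    return assays


def write_panel(assays: list[AssayDef], path) -> None:
    pd.DataFrame(
        [
            {
                "assay_id": a.assay_id,
                "gene": a.gene,
                "assay_type": a.assay_type.value,
                "amplicon_seq": a.amplicon_seq,
                "snp_offset": a.snp_offset,
                "allele_129": a.allele_maternal,
                "allele_cast": a.allele_paternal,
            }
            for a in assays
        ],
        columns=_PANEL_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_barcodes(path) -> list[BarcodePair]:
    df = _read_tsv(path, _BARCODE_COLS)
    return [
        BarcodePair(bc1=r.bc1, bc2=r.bc2, well=r.well, plate_id=r.plate_id)
        for r in df.itertuples()
    ]


def write_barcodes(pairs: list[BarcodePair], path) -> None:
    pd.DataFrame(
        [{"plate_id": p.plate_id, "well": p.well, "bc1": p.bc1, "bc2": p.bc2}
         for p in pairs],
        columns=_BARCODE_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_design(path) -> ScreenDesign:
    df = _read_tsv(path, _DESIGN_COLS)
    wells = []
    for r in df.itertuples():
        drug = None if (pd.isna(r.drug) or r.drug in ("", "NONE")) else r.drug
        kind = ControlKind(r.control_kind)
        wells.append(
            WellCondition(
                well=r.well,
                drug=drug,
                concentration=float(r.conc_uM),
                timepoint=float(r.day),
                is_control=kind is not ControlKind.NA,
                control_kind=kind,
            )
        )
    return ScreenDesign(wells=wells)


def write_design(design: ScreenDesign, path) -> None:
    pd.DataFrame(
        [
            {
                "well": w.well,
                "drug": "NONE" if w.drug is None else w.drug,
                "conc_uM": w.concentration,
                "day": w.timepoint,
                "control_kind": w.control_kind.value,
            }
            for w in design.wells
        ],
        columns=_DESIGN_COLS,
    ).to_csv(path, sep="\t", index=False)
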