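# Methods

## Assay model

The screen measures allelic imbalance (AI) for a closed panel of readout
amplicons in F1 hybrid (maternal 129S1/SvImJ × paternal Cast/EiJ) cells. Each
assay is one amplicon carrying one strain-distinguishing SNP. Two readout
chemistries coexist on the same plate:

- **UMI assays** — SNPs near the 3' end, primed with a UMI-tagged oligo-dT;
  each cDNA molecule carries a unique molecular identifier, and counting is
  per molecule after duplicate collapse.
- **non-UMI assays** — internal SNPs amplified with two gene-specific
  primers; counting is per read.

Wells are encoded combinatorially: a 6-nt BC1 and 7-nt spacer open read 1, a
6-nt BC2 and 7-nt spacer open read 2; the remainder of read 2 (122 nt with
the default 65/135-nt read lengths) covers the amplicon prefix containing the
SNP. Read 1 additionally carries the 10-nt UMI after the spacer for UMI
assays. AI is always oriented maternal-over-total:
AI = n_129 / (n_129 + n_Cast).

Panel geometry is validated against the assay's design rules: amplicon
length in [250, 500] bp and SNP within 135 bp of the nearer amplicon end
(so a 135-nt read reaches it). Rules that would need genome annotation
(repeat masking, exon boundaries) are out of scope for a closed panel.

## Synthetic libraries

The generator draws, for each (assay, well), the maternal molecule count
from Binomial(N, AI_true) with N = `molecules_per_assay_well` (default
1000, matching the screen's ~1000× coverage target per experimental point).
For UMI assays each molecule emits `1 + Poisson(d − 1)` read pairs
(d = `mean_pcr_duplication`): support ≥ 1, mean exactly d, and d = 1
degenerates to exactly one read per molecule, which keeps the error-free
pipeline-vs-truth comparison exact. Non-UMI assays emit one read pair per
molecule. Substitution errors are applied i.i.d. per base after read
assembly (rate default 0; screen-scale validation uses 10⁻³); error
positions get a configurable lower base quality (default Q14 vs the Q37
baseline). Output is byte-identical for a fixed seed.

Two deliberate idealisations:

- **UMIs are collision-free within a group.** UMIs are sampled with pairwise
  Hamming distance ≥ 2 inside each (assay, well). Uniformly random 10-nt
  UMIs would produce a few Hamming ≤ 1 pairs per thousand molecules, which
  the directional collapse rule (correctly) merges; the generator excludes
  them so that exact ground-truth recovery is a meaningful invariant. Real
  libraries therefore have a small (≲0.5%) molecule-undercount the
  simulator does not reproduce.
- **No allele-specific amplification bias, RT inefficiency, primer
  cross-talk, index hopping, or indels.** Passing tests bound demultiplexing
  and counting errors, not these upstream distortions.

The bundled `synthetic_panel` (27 assays over 23 genes, mixed UMI/non-UMI)
and `synthetic_barcodes` (8 × 12 combinatorial grid, pairwise Hamming ≥ 2
within each whitelist) provide study-shaped defaults; the plate layout
default is 24 drugs × 3 concentrations (1, 10, 20 µM) plus 12 untreated and
12 vehicle control wells.

## Demultiplexing and counting

Reads are resolved in three steps, streaming:

1. **Well** — each barcode is corrected to the unique whitelist entry within
   one substitution (precomputed neighbourhood table; ties unassigned). The
   whitelists' pairwise Hamming distance ≥ 2 makes 1-mismatch correction
   unambiguous; the validator enforces this. Both barcodes must resolve and
   the (BC1, BC2) pair must map to a designed well — no single-barcode
   rescue.
2. **Assay** — closed-panel matching of the read-2 insert against each
   amplicon over their overlap, excluding the SNP position from mismatch
   counting so allele state cannot bias assignment; the unique assay with
   mismatch fraction ≤ 0.1 wins, otherwise unassigned. (A genome aligner
   adds nothing here: the 27 amplicons are known and mutually distinguishable.
   A 12-nt exact-prefix index plus full verification makes the common path
   O(1) per read.)
3. **Allele** — the insert base at the SNP offset: maternal base → 129,
   paternal base → Cast; any third base, a base below Q20, or a truncated
   insert → ambiguous. Ambiguous calls are reported for QC and never enter
   AI.

For UMI assays, reads within a (assay, well) group are collapsed with
**directional UMI clustering**: UMI b merges into a when Hamming(a, b) ≤ 1
and reads(a) ≥ 2·reads(b) − 1, growing clusters from the most abundant UMI
downward (deterministic lexicographic tie-break); one molecule per cluster,
its allele the majority call among the cluster's reads, ties → ambiguous.
An `identity` mode (distinct UMI = molecule) is available for sensitivity
analysis. The implementation is checked against an exhaustive fixed-point
oracle on all inputs of ≤ 12 UMIs.

Run summaries preserve read conservation: assigned + unassigned = total,
with unassigned split by failure stage.

## AI estimation

Point estimate AI = n_129/(n_129 + n_Cast); wells with zero informative
counts are no-data, not AI = 0. Intervals are Clopper–Pearson exact binomial
(default 95%), chosen over Wald because MAE genes sit at the AI ≈ 0/1
boundary where Wald degenerates. Titration and UMI-vs-non-UMI agreement are
summarised by Pearson r, maximum absolute deviation, and the least-squares
line; genomic-DNA mixes of pure parental material are assumed to mix
linearly (expected AI = maternal mass fraction). Exposure/recovery time
courses report `stable_from`: the earliest collection day after which every
consecutive AI change is ≤ 0.05 (the plateau tolerance; the underlying
claim is qualitative, so the tolerance is a package choice).

## Hit calling

Per gene, independently: drop observations (one gene in one well) with
n_129 + n_Cast < 30; pool every retained condition — treated and control
wells, all concentrations and collection days — and compute quartiles;
flag observations outside [Q1 − k·IQR, Q3 + k·IQR] with k = 3 ("far out"
fences, stringent against false positives). Controls are pooled and
themselves eligible to be flagged; in a well-behaved screen they never are.
Design choices where the procedure is underdetermined:

- **Quartiles** default to Tukey hinges (median-of-halves) — transparent and
  exactly reproducible by hand at n = 72–96; `linear` interpolation is a
  flag. At these sample sizes the difference is small but not zero.
- **Fences** default to Q1 − k·IQR / Q3 + k·IQR. A legacy mode
  (`fence_mode="q1"`) bases the upper fence on Q1 as well.
- **Order**: the count filter runs before quartile computation, so a
  low-count extreme value cannot widen its own gene's fences.
- Fences are not clipped to [0, 1]; a fence outside the unit interval means
  no observation can be an outlier on that side (e.g. IQR ≥ ~0.14 at k = 3
  makes hits impossible — intentional: noisy genes should not yield hits).
- A gene with fewer than 4 retained observations is unevaluable and yields
  no hits.

Null behaviour: with 96 observations per gene at Binomial(1000, 0.5)/1000,
the IQR is ≈ 0.021, the fences sit ≈ 4.3 binomial SD from the median, and
the expected per-gene false-hit probability is ≈ 0.2%; simulation (200
seeded screens) confirms ≤ 1% of gene-simulations produce any false hit and
a 0.1 → 0.8 shift is detected always.

## ddPCR quantification

Droplets are classified by per-channel amplitude thresholds (HEX = maternal
probe, FAM = paternal; mapping configurable). AI is the fractional abundance
n_HEX-only / (n_HEX-only + n_FAM-only); double-positive droplets (both
templates co-encapsulated) are excluded. Template concentration uses the
Poisson occupancy correction λ = −ln(1 − p) copies/droplet at 0.85 nL per
droplet. A comparison mode (`poisson_ai`) computes AI from per-channel
Poisson concentrations instead, which uses double-positives; at typical
loading (λ ≲ 0.2) the two agree closely, and the single-positive ratio's
occupancy bias is < 0.01 for λ ≤ 0.15. Thresholds are required
configuration (gates are set from homozygous controls in practice); a 1-D
2-means midpoint estimator is provided but off by default. The droplet
simulator draws per-droplet template counts from independent Poissons split
by the true AI and Gaussian amplitudes per cluster; a label-exact variant
generates requested category counts directly.

## Problem sizes and tolerances

The validation experiments run at the screen's stated scale: 27 assays × 96
wells × 1000 molecules (≈5 × 10⁶ read pairs with duplication 3) for
parameter recovery, ≥ 99% of points within 3 binomial SE; 4 × 24 wells at
500 molecules for the exact-recovery check; 10,000 molecules per titration
mix, r > 0.99; 200 simulations each for hit-caller specificity and
sensitivity; 20,000 droplets for ddPCR checks. All randomness flows from
explicit seeds; FASTQ output is byte-stable (fixed gzip header fields).
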