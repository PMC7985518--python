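# Methods

This note documents the models, parameter defaults, numerical choices and
limitations of `tfcascade`. It is the package's own account of its science;
every empirical number it mentions is computed by the test suite or by
`scripts/acceptance.py`.

## Coordinate conventions

All in-memory intervals are 0-based half-open. BED input/output keeps that
convention; GTF is 1-based inclusive and converted on read. A gene's TSS is
`start` on the `+` strand and `end − 1` on the `−` strand. Overlap requires
≥ 1 bp of intersection under half-open semantics, so an interval starting
exactly at a window's `end` does not overlap it. The TSS window is
`[max(0, tss − w), tss + w)` with `w = 25,000` bp by default, clamped at the
chromosome origin. Full peak intervals (not summits) are used for window
assignment; this is the most permissive reading and is symmetric in peak
width.

## TRAP affinity model

A motif's count matrix is regularized with a pseudocount of 1, floored at a
probability of 0.001 and renormalized. The mismatch-energy matrix is

E(b, i) = ln(p_max,i / p_b,i) / λ,

so the consensus base of every column has energy 0. The occupancy of a
window with total energy E is p = R₀e⁻ᴱ/(1 + R₀e⁻ᴱ), and a sequence's
affinity is the sum of p over both strands and all offsets. Windows
containing non-ACGT characters (assembly gaps) contribute 0 and are skipped
silently — genomes contain N runs and erroring on them would make the
scanner unusable.

Constants: λ = 0.7 and ln R₀ = 0.584·m − 5.66 (m = motif width) are the
published TRAP defaults; both are exposed in the pipeline configuration.
The vectorized scanner is checked against a naive per-window loop to 1e−9
and is invariant under reverse complementation of the input.

When a TF has several motif variants (merged motif collections), per-gene
scores are aggregated across variants with `max` by default (`sum` and
`mean` are available). `max` is conservative: a gene scores as well as its
best-supported variant, and adding a redundant variant cannot inflate it.

## Affinity threshold calibration

Channel iii only counts motif evidence whose raw region affinity meets a
threshold calibrated from random sequences. The background set is built by
dinucleotide-preserving shuffles (Altschul–Erikson) of the input
open-chromatin sequences themselves (default n = 1,000, seeded), so the
null preserves length and dinucleotide composition exactly. The threshold
is the empirical (1 − p) quantile of the background affinities with the
ceiling order-statistic definition (`numpy` method `higher`); the default
p = 0.05. Under this definition p = 1/n returns the background maximum, and
the threshold is monotone non-increasing in p.

Two consequences are worth stating plainly:

* by construction, a fraction ≈ p of background regions exceeds the
  threshold, so channel iii has an irreducible ~5% false-positive rate per
  scanned region. On the default synthetic landscape only up-regulated
  secondary genes expose one treated-condition region each, so the expected
  primary/secondary specificity is ≈ 0.97–0.98, comfortably above the 0.95
  benchmark but not 1.0;
* thresholding is applied to raw region affinities *before* decay
  weighting (configurable). Applying it after decay would make evidence
  depend on distance twice.

## TF–gene scores

score(g, tf) = Σ over regions r overlapping the TSS window of
affinity(r, tf) · exp(−d/d₀), with d the distance from the region midpoint
to the TSS and d₀ = 5,000 bp (the TEPIC-lineage default; configurable).
The midpoint is used because it is symmetric and does not depend on region
width; a region centred on the TSS receives weight exactly 1 and a region
at d = d₀ weight e⁻¹. Genes with no qualifying region score 0 for every TF.

## Classification

A gene is an early responder if significant (adjusted p < 0.05, strict) at
any early time point (2.5 h, 4 h), and a late responder if significant only
at the late time point (24 h). Genes significant both early and late count
as early; there is no transient category (the generator never produces
early-only responses, matching the observed response structure). A DEG is
primary when at least `k` of the three channels support it; `k = 1` by
default with `k = 2` exposed as the stringent variant. Raising `k` can only
shrink the primary set (asserted as a property test).

Upset summaries report exclusive channel-combination counts split by
timing. Percentages are always recomputed from the counts at one decimal
with round-half-even; they are never stored independently, so a published
ratio that disagrees with its own printed counts cannot be reproduced —
only the counts-derived value is.

## DYNAMITE regression

Features are per-gene log2 ratios of treated vs control TF–gene scores with
ε = 1e−3 added to both sides (a plain difference is available); labels are
the sign of the late-time-point fold change, zero fold changes excluded.
The model is an elastic-net logistic regression (mixing parameter
l1_ratio = 0.1, penalty grid logarithmic over six decades, C ∈ 10⁻³…10²)
fitted with nested stratified cross-validation: 6 inner folds select the
penalty by accuracy (ties go to the stronger penalty), 6 outer folds each
fit one model on standardized training features, and coefficients are
averaged over the outer folds. Fold assignment, the saga solver and the
scaler are all seeded, so results are bit-identical for a fixed seed. When
the labeled set is too small for 6×6 CV the fold counts are reduced to the
minority-class count with a warning; with fewer than two minority-class
samples the fit is refused. By default the regression runs on the late
secondary DEGs only (the subset the classification could not explain), as
that is the question the ranking answers; the filter can be disabled.

Normalization divides absolute coefficients by the maximum absolute
coefficient (all-zero coefficients stay zero); ranks break ties
alphabetically so output ordering is deterministic.

## TF network

The root TF points at every primary-target TF (`root_primary` edges). An
early TF e gains a `predicted_binding` edge to TF t ≠ e when the decayed
treated-condition score of e's motif at t's gene locus exceeds the edge
threshold. Only early TFs emit binding edges (a late responder cannot have
acted yet within the time course); parallel root and binding evidence yields
two distinct typed edges. Decayed gene scores, not raw region affinities,
are thresholded — the edge claims binding *at the gene locus*, so distance
to the TSS must matter.

The edge threshold accepts either the per-TF calibrated thresholds or an
absolute score. The pipeline default is an absolute expected occupancy of
0.1 bound sites: the calibrated p = 0.05 quantile is designed to admit 5%
of background regions, which is appropriate for screening a gene's whole
window but too permissive for asserting a specific TF→TF edge; at 0.1 a
planted consensus site near the TSS scores ≈ 0.6–0.9 while background
regions stay below ≈ 0.07 even when they contain a one-mismatch site, so
edge calls are essentially noise-free. The calibrated option remains for
users who prefer the screening behaviour.

## Synthetic data generator

The generator emulates the structure of the motivating study — a root
receptor activated by a ligand, a 2.5 h/4 h/24 h expression time course,
root ChIP-seq peaks, condition-specific open chromatin, REM→gene links and
motif collections — with full ground truth. Defaults, which are the
conditions of every recovery benchmark:

* 2 chromosomes × 9 Mb of i.i.d. sequence at GC 0.41 (the human average),
  optionally with N blocks to exercise gap handling;
* 300 genes on ≥ 60 kb territories (the ±25 kb window plus a flank for
  window-external REM evidence), both strands, TSS near the territory
  centre — neighbouring windows can therefore never share planted evidence;
* 6 TFs: the root, 2 early responders, 3 late responders, each with a
  synthetic 12-bp motif; consensus sequences are rejection-sampled to
  pairwise Hamming distance ≥ 4 so motifs cannot cross-react;
* 50% of genes responsive; 60% of responders primary; 25% of primaries
  early — proportions in the range reported for ligand-response time
  courses, chosen once and fixed;
* noise-free peaks and labels (`peak_noise_rate = 0`,
  `label_noise_rate = 0`); both rates are configurable.

Primary genes draw an evidence-channel combination from a configurable
7-cell distribution. Channel separability is enforced by construction:
REM-channel evidence (REM plus overlapping root peak) is placed 26–34 kb
from the TSS, *outside* the window, so the REM channel cannot imply the
window channel; motif-channel regions carry an embedded root consensus in
open chromatin inside the window. TF-coding genes draw from the
window/REM cells only, keeping their loci clear of incidental open
chromatin so network-edge recovery is statistically clean. Secondary genes
carry a single early-driver consensus in open chromatin that is present
only in the treated condition (up-regulation) or only in the control
condition (down-regulation); the score contrast of the driver column
therefore determines the label. Planted TF→TF edges embed an early TF's
consensus within 2.5 kb of a target TF gene's TSS in both conditions.

`simulate_driver_dataset` is a compact benchmark for the regression stage
alone: score matrices in which one driver column carries a ±2 log2-unit
contrast aligned with the labels (flipped at the configured noise rate)
and the other columns carry lognormal jitter.

### What the benchmarks do and do not show

Passing the recovery benchmarks shows the pipeline is *internally
consistent*: each planted evidence type is recovered by its flag operation,
the regression finds a driver whose signal is actually in the features, and
the network recovers exactly the planted binding sites. The generator does
not model read-level noise, peak-calling uncertainty, motif-model
imperfection, co-factor binding without a canonical motif, enhancer–gene
skipping, or correlated expression noise — so recovery rates here are upper
bounds, not estimates of performance on real data. In real data the window
channel in particular is known to fire for many genes without a motif
match, and specificity is bounded by the calibration p-value as described
above.

## Determinism

Every source of randomness (genome generation, shuffling, fold assignment,
solver) flows from explicit seeds; two runs with the same configuration and
seed produce byte-identical output tables, which the test suite asserts by
file comparison. Problem sizes used by the benchmarks — a 300-gene
landscape, 60-gene regression replicates, 20 seeded repetitions — keep a
full verification run in the tens of seconds on one CPU while leaving every
statistical margin (e.g. ≥ 18/20 driver recoveries) wide.

## Known limitations

* The REM channel consumes region→gene links as given; it does not model
  the correlation analysis that produced them.
* Differential expression is consumed as summary tables; no count-level
  modelling or batch correction.
* The regression models main effects only (no TF–TF interactions) and one
  contrast at a time.
* Edge direction in the network encodes the early→late time logic, not
  causal proof; parallel regulation and feedback beyond one step are out of
  scope.
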