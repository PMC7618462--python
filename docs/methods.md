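# Methods

This note records the models implemented, the assumptions behind them, the
defaults and why they were chosen, and what the synthetic data does and
does not establish about behaviour on real data.

## Synthetic data generator

The generator emulates the statistical design of a timecourse multiome
perturbation experiment: cells sampled at five timepoints (labelled D3,
D3.5, D4, D4.5, D5, i.e. 12-hour intervals), two conditions (WT and KD,
default 50% KD per timepoint), and a fixed set of discrete cell types.

**Counts.** For cell *c* of type *t*, feature *g*:
`count ~ NB(mean = depth_c · π[g, t], size = θ)` with a shared dispersion
`θ = 2` (variance `μ + μ²/θ`). The negative binomial is the standard count
family for droplet data; a shared dispersion keeps the model minimal.
Per-cell depths are lognormal (median 10⁴ RNA reads, 1.5 × 10⁴ ATAC
fragments — typical droplet-multiome scales). `θ = 0` switches sampling off
(counts are rounded means), which produces archetype references for
degenerate tests.

**Cell-type structure.** Type profiles `π[:, t]` are built from lognormal
baseline means with disjoint marker-gene blocks per type (default 25 genes
at 8-fold elevation, i.e. log2FC 3). This marker strength is what makes
cluster separation in PCA space exceed ~5 within-cluster standard
deviations, the regime in which kNN label transfer should be nearly exact.
Composition per timepoint is Dirichlet-distributed (concentration 8, so no
type is vanishingly rare).

**Depletion.** Lineage depletion operates on sampling probabilities, not
counts: in the KD condition a depleted type's composition probability is
multiplied by its factor `f ∈ (0, 1]` and the removed mass is
redistributed proportionally over the other types. The KD:WT composition
ratio of the depleted type therefore converges to `f` exactly, matching a
compositional (per-cell abundance) readout.

**Regulatory links.** Each TF is highly expressed in ~¼ of the cell types.
A linked peak's mean accessibility in type *t* is multiplied by
`exp(effect · a_tf(t))` where `a_tf` is the TF's expression profile scaled
to max 1; the default effect 1.5 (natural-log scale) is a strong but not
saturating regulatory coupling. Planted links receive motif scores from
the upper half of the score range; an equal number of decoy motif matches
(motif present, no coupling) provides true negatives, and per-(peak, type)
lognormal jitter (σ = 0.3) keeps decoy correlations noisy rather than
exactly zero.

**QC metadata.** The simulated gene panel is desk-scale (hundreds to ~10³
genes), so detected-gene counts derived from the realized matrix could
never reach the published thresholds (which assume a full transcriptome).
The generator therefore writes full-experiment-scale QC metrics into the
cell metadata — total reads, detected genes, mito/ribo percentages,
doublet score, TSS enrichment, fragment count, blacklist fraction — with
ranks consistent with the realized depths, and the pipeline filters on
those columns with the published thresholds unchanged. A planted 5%
low-quality subpopulation (low depth, few genes, high mito, low TSS, high
blacklist) and 2% doublets (score ~ N(2.0, 0.3)) give the filters
something to remove; the good-cell metric distributions were chosen so
that expected leakage through each threshold is well below 1% per metric
(~3% combined).

**Reproducibility.** All randomness derives from `SimConfig.seed` through
independent named streams (model, cells, rna, atac, qcmeta, atlas), so
changing the gene panel does not perturb cell-type assignment. Identical
(config, seed) gives bit-identical datasets and pipeline output files.

**What the generator does not emulate:** batch effects between samples,
ambient RNA, fragment-length structure, doublet expression profiles (only
scores), continuous differentiation trajectories (types are discrete), and
peak co-accessibility beyond the planted TF couplings. Tests passing on
this generator therefore demonstrate correctness of the computations and
their behaviour under the modelled noise, not robustness to artefacts the
generator omits.

## QC

Every printed threshold uses a strict inequality, so boundary values are
excluded: log10 reads in (3, 5), detected genes in (2500, 12000), mito% <
25, ribo% < 30, doublet score flagged when > 1.25, TSS enrichment in
(9, 35); fragment count is an inclusive minimum (≥ 3500) and blacklist
fraction an inclusive maximum (≤ 0.05). A `chimera` profile carries the
stricter variant ((3.5, 5), (1500, 10000), < 5, < 35, > 0.5). Filters are
idempotent and monotone in their thresholds.

Gene exclusion matches name prefixes and suffixes (`Rik`, `Mt`, `Rps`,
`Rpl`, `Gm`) case-sensitively as printed. Whether `Mt` denotes nuclear
`Mt*` genes (metallothioneins) or mitochondrial symbols is ambiguous in
mouse nomenclature, where mitochondrial genes are written `mt-*`; both are
excluded by default since removing mitochondrial genes is the evident
intent, and the pattern lists are configurable. Mito/ribo gene sets for
the percentage metrics default to `mt-` and `Rps`/`Rpl` prefix matches and
are injectable.

## Label transfer

Size factors are library sizes scaled to mean one (a deliberate
simplification of pooling-based deconvolution factors; with no batch
structure in the data the two differ only by small per-cell corrections),
and normalized values are `ln(count/sf + 1)`. HVGs are ranked by variance
of the log-normalized expression — across reference cell-type means by
default (selection targets genes separating types), across cells
optionally. The joint embedding is a single PCA fitted on the concatenated
reference and query restricted to the HVGs; per-dataset log-normalization
equalizes depth between the two. Mutual-nearest-neighbour batch
correction is intentionally absent: the synthetic data is batch-free and
the transfer rule itself is unchanged by it.

Assignment takes the modal label of the k = 25 nearest reference cells
(Euclidean); a tie between equally frequent labels goes to the label of
the closest reference cell among the tied labels' members, and neighbour
distance ties are broken by lowest reference index (deterministic). With
k = 1 and the reference as its own query the assignment is exactly the
reference labelling.

## In-silico ChIP

Pseudobulk profiles sum counts over cluster members and normalize as
`ln(sum/total × 1e6 + 1)`. For each TF, the Pearson correlation across
clusters is computed against every motif-containing peak's accessibility
profile; zero-variance vectors give correlation 0 by convention so flat
peaks never abort a run.

The binding score multiplies this correlation by the min-max normalized
product of the peak's motif score and its maximum normalized accessibility
across clusters. Two readings of "maximum normalized accessibility" are
implemented: the default takes the peak's maximum pseudobulk accessibility
over clusters divided by the global maximum over all peaks (any global
constant cancels in the subsequent min-max step); the alternative
`per_peak` mode scales each peak's profile by its own maximum, making the
accessibility term identically 1 so only the motif score enters. The
min-max runs over each TF's motif-containing peaks by default (scores must
be comparable across peaks within a TF; a global axis is switchable). A TF
with a single motif peak has an undefined min-max and receives a scaled
product of 1. Consequences: |score| ≤ |correlation| always, and rescaling
the entire accessibility matrix leaves scores unchanged; rescaling a
single peak's profile changes its rank among the TF's peaks in the default
mode (and is a no-op in `per_peak` mode).

Peaks with score > 0.2 are bound; TFs with fewer than 40 bound peaks carry
a `retained = False` flag for downstream TF-activity work. Marker
detection substitutes a one-vs-rest Wilcoxon rank-sum test (with BH-FDR
and log2 fold change of group means, pseudocount 1) for specialised
bias-matched ATAC testing machinery, keeping the published decision rule
(FDR ≤ 0.1, log2FC ≥ 0.5) intact. Motif enrichment is an upper-tail
hypergeometric draw of the marker set from the background. Interval
overlap reports pairs on the same chromosome overlapping by ≥ 100 bases
(0-based, half-open).

## Differential abundance

For each retained cell, the k = 100 nearest retained neighbours (self
excluded — including the cell itself would bias the observed fraction
toward its own condition) give the observed KD count x. The expected
fraction is `ê = Σ_t n_t r_t / k` with `r_t` the global KD ratio at
timepoint t. WT cells of the earliest timepoint are excluded by default,
both as tested cells and as neighbour candidates, anchoring the earliest
timepoint's expected ratio at 1 — before the perturbation acts, only KD
cells are informative there.

The two-sided p-value is the exact convention summing all outcome
probabilities not exceeding the observed outcome's probability (with a
10⁻⁹ relative guard against floating-point ties); it reduces to tail
doubling in the symmetric case and matches exhaustive rational enumeration
to < 10⁻¹² for k ≤ 25. Degenerate expectations keep the exact mass: under
ê = 0 an observation of 0 has p = 1, a discordant observation gets the
smallest positive float. BH-FDR runs across all tested cells; the DA
level is o/ê (defined as 1 when both are 0). The per-cell tests share
neighbours and are therefore positively correlated; the calibration check
is on the marginal rate of q < 0.05 calls under the null, which the exact
binomial holds conservatively below nominal.

## Pseudobulk differential expression

Each cell type × condition group yields 5 replicates, each the sum over a
random 40% subsample without replacement (replicates may overlap; group
size must be ≥ ⌈1/0.4⌉). Features are filtered at CPM ≥ 1 in at least
half the replicates and detection in ≥ 5% of the group's cells (these two
thresholds are configuration, chosen as conventional defaults), plus the
name-based exclusions. Testing is a Welch two-sample test on replicate
log2(CPM+1) values in place of a negative-binomial GLM — the replicate
construction, filtering and the |log2FC| > 0.5 & FDR < 0.05 decision rule
are the preserved substance; the test statistic is pluggable machinery.

A structural caveat, shared by any subsampled-pseudobulk design:
overlapping replicates of one cell pool do not capture pool-level sampling
noise, so replicate-based p-values overstate certainty. The |log2FC| gate
is what keeps the realized false-call rate of the full decision rule below
nominal under the null, and that rule (not the raw p-values) is what the
package's calibration checks certify.

The cell-type-specific comparison takes a features × cell-types logFC
matrix (missing entries as 0), subtracts each feature's across-type mean,
and z-tests the deviation against the across-type standard deviation
(ddof 1; zero spread gives p = 1). Deviations sum to zero across types by
construction.

## Problem sizes and numerical choices

Validation runs use desk-scale designs chosen to exercise the asymptotic
claims while keeping the full suite in minutes: 5,000 cells for DA
calibration (20 replicates) and power; 20 cell types × 50 TFs × 5,000
peaks for in-silico ChIP recovery; 1,000 query cells against a 400-cell
atlas for transfer accuracy; 1,200-cell end-to-end runs. PCA uses the
randomized solver with a fixed random state (deterministic for fixed
input); kNN searches are exact; all tie-breaks are by lowest index. The
pipeline writes only plain-text formats, and two runs from the same config
and seed produce byte-identical files.
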