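# Methods

`scsplice` re-implements, as a tested pipeline, a single-cell analysis of
cassette-exon splicing and its DNA-methylation determinants: PSI
quantification with coverage floors, binomial cell/gene dispersion models,
methylation-aware sequence featurization, locus-level methylation–splicing
association, ridge prediction of splicing rates and categories, and
category-switch analysis between two cell states.  A synthetic-data
generator with planted ground truth makes every stage verifiable without
external downloads.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Splicing quantification

PSI for one cassette exon in one cell is the raw read ratio
`inclusion / (inclusion + exclusion)`, with no isoform-length correction and
no informative prior: an entry is quantified only when the total read count
is at least `min_reads` (default 5), and an exon is retained only when
quantified in at least `min_cells` cells (default 10).  The cell-count floor
is evaluated *after* the read floor (observation = a quantifiable PSI
value); the alternative reading — counting cells with any coverage — was
rejected because a cell that cannot yield a PSI value contributes nothing
downstream.  Pseudo-bulk PSI is the unweighted mean of quantified
single-cell values (averaging estimates, not pooling reads), and dispersion
is the sample (n−1) standard deviation across cells.

## Cell model versus gene model

Two limiting explanations of cross-cell PSI variance:

* **cell model** — each cell commits to one isoform; per-cell PSI is a
  Bernoulli indicator, so SD(PSI) = √(p(1−p));
* **gene model** — both isoforms are co-expressed and reads sample the
  inclusion isoform binomially; at read depth n, SD(PSI) ≈ √(p(1−p)/n).

The gene-model expectation is estimated by Monte Carlo at each exon's own
observed per-cell read depths: each replicate draws per-cell inclusion
counts Binomial(n_c, p), forms PSI and takes the across-cell sample SD; the
returned value is the mean over 400 replicates.  Per-exon (rather than
global) depth conditioning was chosen because the comparison is made per
exon and depth varies by orders of magnitude between exons.  The Monte-Carlo
standard error of the returned value at 400 replicates is ≈ σ_SD/20, which
the tests use as the agreement tolerance against the analytic binomial
proportion SD.

## Cassette-exon candidates and filters

Candidates are extracted from the annotation: an internal exon A of a
transcript is a candidate when another transcript of the same gene joins
A's two transcript-adjacent neighbours C1 and C2 directly (A skipped).
Coordinates are converted to 0-based half-open on read.  Filters: autosome
whitelist, A's interval intersecting no other candidate's A interval,
flanking introns strictly longer than 100 bp, 50 ≤ len(A) ≤ 450, at least
500 bp from the host gene's most extreme transcript start/end, and canonical
dinucleotides in transcript orientation (AG closing the upstream intron, GT
opening the downstream intron).  Two underdetermined points were resolved
as: overlap is checked against other *candidates* only (not constitutive
exons of other genes), and TSS/TTS distance uses the most extreme transcript
boundaries of the host gene.

## Sequence contexts and features

Each cassette exon is decomposed into seven transcript-oriented contexts:
C1, A, C2 and the 5′/3′ ends (≤300 bp, anchored at their own end) of the two
flanking introns; for introns shorter than 600 bp the two end contexts
overlap but remain distinct.

The genomic block has exactly 607 features:

| family | count |
|---|---|
| k-mer frequencies, k ≤ 3 over ACGT, per context | 7 × 84 = 588 |
| mean conservation per context | 7 |
| log length + relative length per region (C1, I1, A, I2, C2) | 10 |
| splice-site strengths at A's acceptor and donor | 2 |

k-mer frequencies are overlapping-window counts divided by the number of
valid windows of that length; windows containing N are excluded from both
numerator and denominator, so each k-block sums to 1 whenever any valid
window exists.  Relative length is the region length divided by the span
from C1 start to C2 end — a normalization that keeps the feature in (0,1)
and comparable across genes.  Splice-site strength is a position-weight-
matrix log-odds score (base 2, uniform background) over a window spanning
the exon–intron boundary; the shipped default PWMs encode the canonical
U2-type donor (C/A)AG|GTAAGT and acceptor (polypyrimidine tract + AG)
consensus, and are replaceable via `features.load_pwm` since no specific
motif model is canonical for this purpose.

The methylation block has exactly 826 features: in each context, the 116
k-mers over the extended alphabet {A, G, T, M, U} (k ≤ 3) that contain at
least one M or U, plus the methylation mean and variance across the
context's CpG cytosines (7 × 118).  The count 116 = (5+25+125) − (3+9+27)
is asserted by brute-force enumeration in the tests.

Methylation states are binarized from probabilities: ≤ 0.3 → unmethylated,
> 0.7 → methylated, intermediate → missing (missing calls carry no
information and are excluded from the nearest-neighbour fill).  Every
cytosine of a context sequence is then rewritten as M or U: informed
cytosines use their own call; uninformed cytosines take the state of the
nearest informed cytosine within ±900 bp of genomic distance, defaulting to
unmethylated beyond that.  Calls are indexed by the plus-strand position of
a CpG's cytosine; a cytosine read on the minus strand looks up position − 1
(the CpG dyad is palindromic).  Cell-level features are computed per cell;
"mean" mode averages every coordinate across cells.

## Methylation–splicing association

For every (exon, context), the per-cell context methylation rate — the mean
filled M/U state over the context's CpG cytosines, i.e. the same quantity as
the `meth_mean` feature — is correlated with per-cell PSI by Spearman rank
correlation (average ranks for ties, which matter because binarized means
are discrete).  Pairs with fewer than 10 complete cells, or without
variation on either side, are skipped rather than reported; the floor of 10
mirrors the exon-level quantification floor.  P values are adjusted with
Storey's q-value by default (pi0 estimated on a 0.05–0.90 lambda grid,
averaging the upper half of the grid as a spline-free smoother; BH is the
fallback and is used automatically below 100 tests, where pi0 estimation is
unstable).  Replication between two states counts a discovery (Q < 0.05) as
replicated when the replication-set p is below 0.05 with the same effect
sign, among discoveries testable in the replication set.

## Prediction models

Single-cell and pseudo-bulk PSI are modelled by linear ridge regression;
categories by multinomial logistic ridge.  Performance is the squared
Pearson correlation between out-of-sample predictions and observations
under tenfold cross-validation repeated four times with different splits
(mean ± SD across repeats).  Three choices the evaluation depends on:

* **Fold unit.** Single-cell rows are (exon, cell); folds are stratified by
  exon so no exon contributes to both training and validation.  This is the
  stricter choice and prevents the methylation block from acting as an exon
  fingerprint that would leak exon identity across folds.
* **Penalty.** The ridge strength is selected on the training folds from a
  log-spaced grid (10⁻²…10⁴) by efficient leave-one-out ridge CV; features
  are standardized on training folds only, since ridge penalties are
  scale-sensitive and the |weight|·SD relevance score presumes comparable
  scales.
* **Clipping.** Predictions are not clipped to [0,1] before computing r²;
  Pearson r² is invariant to any affine map, so clipping is cosmetic.

Per-feature relevance is the signed Pearson correlation (and r²) for linear
targets, and |weight|·SD(feature) plus the single-feature AUC for logistic
targets.  The cell-by-feature relevance matrix (each cell's feature–PSI
correlations across its quantified exons) is decomposed by centered PCA;
with state labels, PC1's ability to separate states is summarized as an AUC,
and the five largest positive and negative PC1 loadings are reported.

## Splicing categories

Exons with mean PSI < 0.2 are *excluded* and > 0.8 *included*.  Within the
band, observed SD is compared with a scaled binomial expectation
SD ≈ c·√(p(1−p)), with c fitted to all exons by least squares (the simplest
form consistent with a "scaled binomial SD"; a per-exon read-depth term was
deliberately omitted because the Tukey fences absorb overall scale).
Deviations above Q3 + 1.5·IQR are *overdispersed*, below Q1 − 1.5·IQR
*underdispersed*, the rest *multimodal*.  Quartiles use linear
interpolation, and the fences are computed over intermediate-band exons
only — the three dispersion categories exist only there, so including the
near-degenerate deviations of extreme exons would distort the fences.
Switch analysis between two states is restricted to exons categorized in
both; switching is predicted per source category by logistic ridge, and
per-category methylation contrasts use the two-sample Wilcoxon rank test
(distribution-free, appropriate for bounded rates) with BH adjustment over
the (category × context) family and a difference-of-medians effect.

## The synthetic-data generator

The generator emulates the scale and noise structure of single-cell
parallel methylome-and-transcriptome data in two cell states:

* **Scale.** Default 300 exons and 80 cells per state.
* **Geometry.** One gene per cassette exon: flanks of 550 bp, constitutive
  exons of 200 bp, introns drawn 620–900 bp (long enough to keep the
  intron-end contexts disjoint and the alternative exon ≥ 500 bp from the
  TSS/TTS), alternative exons 80–250 bp, AG/GT planted at A's boundaries;
  strands alternate.  Every emitted exon passes the candidate filters.
* **Coverage.** Per (exon, cell) read depth is negative binomial
  (mean 10, shape 1.5), leaving roughly a third of entries below the 5-read
  floor — the "many exons missing per cell" property of shallow
  single-cell libraries.  The missing fraction is checked against the
  analytic negative-binomial tail in the tests.
* **Mean PSI is sequence-determined.** Each exon's mean PSI is a logistic
  function of ten active k-mer frequencies of its own emitted sequence.
  The lowest-scoring exons form the excluded class (PSI ≈ 0.05), the
  highest the included class (≈ 0.95), and the dispersion regimes
  (over/under/multimodal) are drawn at random among the intermediate exons.
  Conservation over A is elevated in proportion to mean PSI, so
  conservation is an informative, recoverable feature.
* **Dispersion regimes.** Under/gene regimes sample reads binomially at the
  exon mean; overdispersed and multimodal regimes draw per-cell inclusion
  probabilities from Beta distributions with concentrations 0.8 (U-shaped,
  modes near 0 and 1) and 6.0.
* **Methylation.** CpG sites are the CG dinucleotides of the emitted
  sequence; each is observed with probability 0.3 (the typical 20–40%
  genomic coverage of single-cell bisulfite libraries) and the observed
  state is Bernoulli in the cell's context rate, which is Beta-distributed
  around a per-(exon, context) mean with concentration 2.5.
* **Planted coupling.** A configurable fraction of *intermediate* exons
  carries a monotone methylation–splicing coupling: the cell's coupled-
  context rate displaces its inclusion probability on the logit scale
  (default effect 8, giving |ΔPSI| well above 0.3 across the methylation
  range).  Coupling is restricted to intermediate-splicing loci because an
  exon pinned near PSI 0 or 1 cannot respond measurably, making couplings
  there unfalsifiable.  The effect direction is a property of the context
  (exonic methylation promotes inclusion, intronic represses), and coupled
  contexts concentrate on A and the downstream intron end — mirroring the
  observation that methylation information in these contexts carries most
  of the predictive signal — so that global linear models can in principle
  exploit the couplings.  At coupled loci reads sample binomially around
  the methylation-shifted per-cell rate: the cross-cell heterogeneity there
  *is* the methylation response.
* **Two states.** State B reuses the same loci and couplings; a
  configurable fraction of exons shifts mean PSI by ±1 logit, producing
  category switches (never included ↔ excluded at that magnitude).
* **Determinism.** One root seed is split hierarchically (genome / truth /
  reads / methylation / conservation, then per state), and repeated runs are
  byte-identical file-for-file.

What the generator does **not** emulate: alignment artifacts, bisulfite
conversion errors, transcript-level expression variation and dropout
correlated with expression, CpG-density structure of real genomes (CpG
islands), linkage between neighbouring loci, or batch effects.  Passing the
recovery tests therefore demonstrates the pipeline's statistical machinery
is calibrated and able to recover planted structure at realistic noise
levels — not that effect sizes in real tissue match the planted ones.

## Problem sizes in the test suite

The acceptance checks run the association calibration at 300 exons × 80
cells over five seeds, and the prediction contrast at 200 exons × 40 cells
(5-fold CV, strong planted coupling at full prevalence concentrated on the
A and downstream-intron contexts).  These sizes were chosen so the suites
characterize calibration and recovery with comfortable statistical margins
on a single CPU; all thresholds (power ≥ 0.8, empirical FDR ≤ 0.1, null
uniformity, Δr² directions) are properties of the method, not of the
specific size, and scale-up only sharpens them.

## Known limitations

* The Storey pi0 estimator uses a grid-average smoother rather than the
  original cubic-spline fit; on small test families it conservatively falls
  back to BH (pi0 = 1).
* The splice-site PWMs are consensus-derived defaults, not fitted to an
  annotated splice-site corpus; scores are comparable within a run but not
  calibrated against external motif databases.
* The scaled-binomial dispersion fit omits read-depth dependence; datasets
  with extreme depth heterogeneity may see depth leak into the deviation
  statistic (partially absorbed by the per-dataset fences).
* Pseudo-bulk aggregation weights cells equally regardless of coverage.
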