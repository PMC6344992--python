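# Methods

`dlocal` implements a soma-vs-dendrite sub-cellular RNA localization
analysis for paired single-neuron data: each cell contributes one somatic
and one dendritic sample, and every statistic in the package is built
around that pairing.

## Quantification features

Gene-level expression is measured over the **union 3'UTR**: the base-set
union of all annotated 3'UTR intervals of a gene's transcripts. Isoform-level
expression is measured over **terminal windows**: the last `window`
(default 500) nt of transcript sequence upstream of each distinct annotated
3' end. Windows are computed in spliced transcript coordinates, so a window
crossing an exon junction still covers 500 nt of transcript sequence; a UTR
shorter than the window is used whole.

Two rules make the terminal windows a valid partition for ambiguity-free
counting:

* 3' ends closer than `merge_dist` (default 500 nt; single-linkage along
  the strand, genomic distance by default, spliced distance via
  `coord_space="transcript"`) are merged into one feature whose span is the
  union of the member windows. The merged feature records all member ends.
* Any residual overlap between adjacent features of one gene is resolved by
  truncating the more 5' feature at the more 3' feature's start, so the
  final feature set is non-overlapping within each gene.

A proximal/distal isoform pair is classified **tandem** when the
full-length 3'UTRs of the two isoforms overlap or directly abut (gap 0) —
the geometry produced by alternative cleavage/polyadenylation within one
terminal exon — and **ALE** (alternative last exon) otherwise.

## Counting and normalization

A read counts toward a feature when it overlaps it by at least one base on
the same strand. Reads overlapping features of more than one gene are
discarded as ambiguous; within a gene, ties go to the feature with the
larger overlap, then the more 3' feature. Reads are assumed uniquely
mapped and are never counted twice.

Library sizes are normalized with median-of-ratios size factors:
s_j = median_i K_ij / (prod_j' K_ij')^(1/m) over features with positive
counts in every sample, with a total-count fallback (and a warning) when no
such feature exists.

## Gene-level localization calls

* **deDend / deSoma** — per gene, the per-cell differences of normalized
  counts (dendrite − soma) are tested with a two-sided Wilcoxon signed-rank
  test; Benjamini–Hochberg correction is applied over the tested genes.
  deDend requires q ≤ 0.05 and a positive median difference. Genes with
  fewer than 6 complete pairs are untestable. The signed-rank test is
  computed **exactly** for n ≤ 25 non-zero differences: zeros are dropped,
  tied absolute differences receive midranks, and the null distribution of
  the positive-rank sum is built by the shift algorithm over doubled
  midranks (so the p-value is exact under arbitrary tie configurations —
  important because count differences tie often). Beyond n = 25 a
  tie-corrected normal approximation is used. An adapter seam exists for
  substituting externally computed negative-binomial GLM results: any
  DataFrame with `stat`/`p`/`call` columns drops into the downstream steps.
* **consDend** — genes with at least one read in at least
  ceil(0.9 × n_dendrite) dendrite samples (15 of 16 at the default design),
  capturing constitutive presence rather than concentration enrichment.

## Localization variability

The dendritic read fraction of a gene in one cell is f = d/(d+s); cells
with fewer than `min_total` (default 10) reads are excluded. Variability is
the cross-cell sample variance of f (ddof = 1, hence bounded by 0.25 for
fractions). Because read depth itself inflates variance estimates, a
downsampling control re-draws every included cell at exactly `n_down` = 10
reads as Binomial(n_down, f_cell) per replicate (1000 replicates), and
reports the mean replicate variance with a nonparametric 2.5/97.5
percentile interval. Cells with fewer than n_down reads are excluded from
the control rather than sampled without replacement, keeping the binomial
model exact. All-or-nothing profiles (f ∈ {0,1}) are invariant under this
control, which the tests exploit.

## Isoform-level localization (isoDend)

Per gene, the top two isoforms are chosen by summed per-sample read
fractions (samples under 10 gene reads are skipped, giving each informative
sample equal weight); ties break by raw reads, then distality. The more 5'
of the two is *proximal*, the more 3' *distal*. The distal fraction
DF = distal/(distal+proximal) is undefined below 10 combined reads;
ΔDF = DF_dendrite − DF_soma per cell where both are defined. A gene is
**isoDend** when the exact Wilcoxon signed-rank p of its ΔDF vector is
< 0.1 over at least 5 valid pairs. The preferred isoform follows the sign
of the median ΔDF (mean breaks a zero median); non-isoDend genes use the
mean-ΔDF sign where a preference is needed for cohort backgrounds.

Cohort comparisons:

* **Distal preference** — 2×2 Fisher of distal/proximal preference in
  isoDend genes vs the *complement* of the tested set.
* **DF variability** — 2×2 Fisher of soma-more-variable DF in isoDend
  genes vs the *full* tested set, plus a soma read-depth control that
  resamples each soma DF at 10 reads per replicate. These two set
  constructions are the ones that reproduce the published odds ratios (2.4
  and 3.6) from the printed cohort fractions; both are implemented as
  stated.
* **Length comparison** — paired t-test of dendrite-preferred vs
  non-preferred full-length 3'UTR lengths, separately for ALE and tandem.

## Backgrounds and enrichment

Motif enrichment compares localized foregrounds against a length-matched
background: the pool of soma-higher genes (minus any localized or known
dendritic genes), ordered by somatic specificity (here the signed
standardized Wilcoxon statistic, most soma-specific first; the ordering key
is pluggable), scanned greedily — first pool gene within 100 nt of the
foreground gene's 3'UTR length is taken and removed; if none qualifies, the
closest remaining length (earlier pool position breaks ties). Enrichment is
a two-sided Fisher exact test counting at most one motif hit per gene;
fold = (fg hit rate)/(bg hit rate), odds ratio = cross-product ratio with
an infinity convention for zero cells.

## Sequence motifs

G-quadruplex candidates are matches of `([gG]{3,}\w{1,7}){3,}[gG]{3,}`
(four or more runs of ≥ 3 G separated by 1–7 nt loops), non-overlapping
left to right. PWM scanning scores each window by
Σ log2(p_pos,base / q_base); N contributes 0. The per-motif threshold is
c × (number of positions with information content ≥ 0.5 bits), c = 1 by
default, so longer and more specific motifs need higher scores — the
constant and the cutoff are both settable.

## SINE covariance models

B1 (88 nt) and B2 (70 nt) hairpins are modeled as single-exemplar profile
SCFGs built from the canonical sequence plus its dot-bracket structure: one
PAIR node per base pair (16-entry emission table), one LEFT node per
unpaired base (4-entry table), bifurcations at multiloop branch points.
Emissions are pseudocount-smoothed log2-odds against a uniform null,
maximized at the exemplar base(s); with pseudocount α = 0.05 a matched pair
scores +3.22 bits and a matched single +1.81. Insertions cost
open + extend per run (−4/−2 bits); deleting a node costs open + extend per
base it would emit (deletions are charged per node rather than affine
across deleted runs — at these model sizes the extra DP states buy
nothing). Scoring is CYK max dynamic programming over the guide tree with
free flanking insertions at the root (glocal alignment), compiled with
numba. Scanning tiles each UTR with windows of min(250, 2 × model length)
nt and slide 75, keeping one best hit per gene; a hit passes at ≥ 50 bits
(B1) or ≥ 35 bits (B2). With the shipped defaults the exemplar self-scores
are 147.7 and 117.9 bits and the 99th percentile of dinucleotide-shuffled
exemplar scores is below −10 bits, so the cutoffs cleanly separate
structure-conserved matches from composition-matched noise. Absolute bit
scores are specific to this model parameterization and are not comparable
to scores from other covariance-model software.

## Master list integration

Study gene lists are normalized to mouse title case and combined into an
observation table (gene, number of studies observing it, study ids),
ordered by observation count. No alias or cross-species ortholog mapping is
applied — rat and mouse symbols are taken at face value — which is a known
limitation when integrating microarray-era lists.

## Synthetic data

The generator emulates the reference design: 16 cells × 2 compartments,
1000 genes, 1–4 isoforms per gene (P = .35/.40/.17/.08), lognormal baseline
expression (median ≈ 150 soma reads), dendrites capturing half the somatic
concentration by default, negative-binomial counts (dispersion 0.3),
whole-gene dropout (5%), and lognormal library factors (σ = 0.3). Planted
classes: deDend (10× dendrite/soma ratio), consDend (guaranteed present —
generated without dropout), isoDend (per-cell ΔDF shift of 0.3, directed
toward the distal isoform in 64% of genes, mirroring the observed
preference), and non-localized. Sequences are drawn from a fixed base
composition with motif instances (G-quadruplex, PWM consensus, verbatim
B1/B2) planted at configurable foreground/background rates.

What the generator does **not** model: positional read bias within
features, ambiguous multi-gene overlap, amplification-induced length bias,
batch structure, or correlated dropout — so passing recovery tests
demonstrate the estimators behave correctly under the stated noise model,
not that the pipeline is robust to every artifact of real sub-cellular
sequencing. Problem sizes in the shipped tests (300–1000 genes, 1000
shuffles, 1000 resampling replicates) were chosen as the smallest scales at
which the binomial tolerances of the recovery checks are informative.

## Numerical conventions

0-based half-open genomic intervals throughout; GTF converted on read.
Sample variance uses ddof = 1 everywhere. Fisher odds ratios are
unconditional cross-product ratios (inf for a zero denominator with
positive numerator, NaN for fully degenerate tables). All stochastic stages
take explicit seeds and are bit-reproducible; fixed seeds propagate through
`simulate_study` via a single root generator.
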