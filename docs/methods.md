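# Methods

`chromstate` reconstructs, at desk scale, a chromatin-state analysis of
CUT&RUN profiles (H3K4me3, H3K27ac, H3K27me3, BRG1, with an IgG control) and
RNA-seq counts from two cell types. This note describes the models, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Signal normalization and binarization

Spike-in scaling assumes exogenous (E. coli) reads are proportional to
material, so comparable samples are obtained by multiplying each track by
`C / spike-in reads`. `C` defaults to 10,000, a common CUT&RUN convention;
it is a pure rescaling and cancels out of every downstream ratio. Optional
running-mean smoothing (default 3 bins, the analogue of a 60 bp smooth on a
20 bp grid) is applied only to exported browser tracks — the binarization
path consumes raw counts, as ChromHMM-style binarizers do.

Binarization is a Poisson tail rule: replicate counts for a mark are summed
per bin, and a bin is called present when `P(X >= count) <= p` (default
`p = 1e-4`) under `X ~ Poisson(lambda)`. The background rate `lambda` is the
larger of the track-wide mean count per bin and, when an IgG control is
given, the control count scaled by total signal/control depth. The pooled
control is running-mean smoothed over 75 bins (15 kb at 200 bp) before
scaling: a shallow control (mean well below 1 read/bin) has large relative
local noise, and the depth ratio amplifies it — a raw control count of 2 in
a track with mean 0.4 is sampling noise, not a 5x local background, and
even a 5 kb window leaves enough relative noise to double lambda over whole
regions occasionally. A 15 kb window keeps the estimate regional while
bounding its relative error; a uniformly elevated control still suppresses
calls globally.

## Chromatin-state model

States are latent labels over fixed 200 bp bins. Given the state, marks are
independent Bernoulli draws: `P(obs | k) = prod_m E[k,m]^x (1-E[k,m])^(1-x)`.
The defaults follow ChromHMM's conventions: K = 10 states, learning by
Baum-Welch EM on per-chromosome sequences (no transition across chromosome
ends), decoding by per-bin posterior argmax (Viterbi is available).

Numerical choices:

- Forward/backward use per-step scaling; log-likelihoods are exact up to
  float64 rounding (checked against exhaustive path enumeration to 1e-10).
- Emission log-probabilities of exactly 0 are clamped to -1e30 inside the
  vectorized emission computation so that `0 * log(0)` contributes nothing;
  a truly impossible sequence still reports `-inf`.
- Initialization: emission rows are the overall mark frequencies with
  uniform jitter (+-0.1, clipped to [0.01, 0.99]); transitions start at 0.9
  self / uniform off-diagonal; the start distribution is uniform. Three
  restarts by default, best final likelihood wins.
- Emission and transition probabilities are floored at 1e-6 after each
  M-step to avoid absorbing zeros.
- Convergence: relative log-likelihood change below 1e-4 or 200 iterations.
  The likelihood is asserted non-decreasing (tolerance 1e-8) every
  iteration.
- Learned states are re-indexed 1..K by descending H3K4me3 emission, ties
  broken by H3K27ac, so the promoter-proximal states take the low indices
  regardless of the EM start point.

One model is learned on both cell types' binarized matrices concatenated as
extra sequences and decoded per cell type (default); a per-cell-type mode
learns separate models. The shared-model default keeps state identities
directly comparable between cell types.

## State labels and annotation

States get functional labels from a first-match rule ladder over emissions
and fold enrichment at TSS windows (TSS +-1 kb): bivalent (H3K4me3 and
H3K27me3 both high) takes precedence, then TSS Active / TSS Flanking (high
H3K4me3 at TSS-enriched states), enhancer classes (H3K27ac away from TSSs),
repressed classes (H3K27me3), quiescent (everything silent), else Other.
Thresholds are configurable; defaults are 0.5 (strong), 0.2 (weak), 0.3
(flanking H3K4me3), 2.0 (TSS fold).

Feature annotation assigns each interval one category by its midpoint with a
fixed priority ladder: promoter bands by absolute distance to the nearest
TSS (<=1 kb, 1-2 kb, 2-3 kb; a midpoint exactly on the TSS falls in the
first band), then exon/intron for midpoints inside a gene, then downstream
(<= 3 kb past the TES), else distal intergenic. UTR categories exist in the
vocabulary but require transcript-level annotation the gene models do not
carry, so they are never assigned. Category percentages always sum to 100.

Interval intersection is a per-chromosome sorted sweep under half-open
arithmetic (`a.start < b.end and b.start < a.end`); it is checked against a
quadratic all-pairs oracle in the tests.

## Broad TSS domains

Maximal runs of consecutive bins in TSS states form TSS regions; a region of
at least 4,000 bp (inclusive) is a broad domain. In the pipeline the TSS
state set is derived from the model rather than fixed at {1, 2}: all states
labeled TSS Active, TSS Flanking, or Bivalent, plus any state whose H3K4me3
emission is at least 0.5. EM sometimes represents the high-H3K4me3
population with more than two states, and the fold-based TSS label can miss
a genuine TSS state whose bins lie mostly inside broad domains, beyond the
TSS +-1 kb window that defines the fold — the scientific object is "bins in
predicted TSS states", not a pair of indices. The standalone function
defaults to {1, 2}. Genes attach to a region when their
TSS +-1 kb window overlaps it.

## Expression normalization and specificity

TMM factors are computed with M-values on raw counts (not depth-normalized
counts), so a factor absorbs both sequencing depth and composition bias, and
CPM divides by (geometric-mean library size x factor). Consequence: scaling
one sample's counts by c scales its factor by c and leaves its CPM fixed.
M is trimmed 30% from each tail and A 5% from each tail; kept M-values are
averaged with inverse-variance (precision) weights, which makes the
c-scaling law exact only to ~1e-3 — the weights themselves shift with the
counts. The reference sample is the one whose upper-quartile count is
closest to the mean of upper-quartiles; factors are re-centered to geometric
mean 1.

Cell-type specificity is a Welch (unequal-variance) two-sample t on
log2(CPM+1): target-type replicates versus all samples whose biological
category differs from the target's. Samples of *other* cell types in the
same category are excluded entirely, so sister cell lines cannot deflate
specificity; a strict target-vs-all-others mode is provided for comparison.
Genes are ranked by t descending (ties by gene id) and the top
ceil(0.10 * G) are flagged specific. When both groups have zero variance and
equal means, t = 0 by convention.

Overrepresentation uses the upper-tail Fisher exact test (hypergeometric
survival function) against a term-to-gene map, Benjamini-Hochberg adjusted
across all tested terms in the run, filtered at p <= 0.05 and q <= 0.05.
Genes without term annotation stay in the universe by default. The qPCR
utility implements 2^-ddCt against a reference gene and calibrator sample.

## Synthetic study generator

The generator emulates the study design end to end: a 2 x 2 Mb genome
binned at 200 bp, 400 non-overlapping genes (600-3,000 bp, both strands),
two cell types x 2 CUT&RUN replicates x 5 antibodies, spike-in totals
~ Poisson(5,000), and 3 RNA-seq replicates per cell type.

- Hidden paths: a sticky background Markov chain (self-transition 0.96,
  quiescent-dominated stationary weights) over 8 non-TSS states, shared
  between cell types. Each gene gets a planted TSS-state run centered on its
  TSS: 1-2 kb for ordinary genes, 4.2-6.2 kb for the 5% "developmental"
  broad genes. 10% of genes are cell-type specific: their run exists in
  their own cell type and the locus is Repressed in the other. 35% of broad
  genes per cell type are also specific, so the broad/specific overlap
  readout is non-degenerate. Genes are placed one per equal-width slot with
  random offsets and enough clearance that neighbouring runs can never
  merge.
- Counts: per-bin Poisson with state x mark rates; IgG is flat. The TSS
  states' H3K4me3/H3K27ac rates (24/18 expected reads per bin against a
  background mean of ~6-7) are the package's separation condition: they give
  per-bin binarization fidelity of ~99.99%, so a planted >=4 kb run is
  essentially never split by a mis-called bin — one missed bin turns a broad
  run into two sub-4 kb runs, which is a run-level error the recovery
  analysis treats as decoding failure. Marginal call frequencies stay at
  ~2-13% of bins per mark, matching sparse histone-mark occupancy.
- Expression: negative binomial with var = mu + 0.1 mu^2, gene base means
  lognormal around 300; specific genes have mean x 2^3 in their own cell
  type. The dispersion -> 0 limit reduces to Poisson exactly.
- Everything derives from one master seed; each component uses
  `default_rng([seed, offset])` with fixed offsets, so artifacts are
  byte-identical across runs and components are independently stable.

What the generator does **not** emulate: read-level sampling (fragment
lengths, GC bias, duplicates), mappability and blacklist artifacts,
replicate batch effects, correlated mark backgrounds, isoform structure, or
a realistic GO term graph. Passing tests therefore demonstrate correctness
of the computational pipeline under its statistical assumptions, not
robustness to the artifacts of real sequencing data.

## Problem sizes used in checks

The end-to-end checks run the default 2 x 2 Mb / 400-gene study (about 30 s
for a full pipeline run); parameter recovery uses a 3-state, 4-mark model on
50,000 bins; EM monotonicity is probed with 50 random starts of 10
iterations each on a 5,000-bin input (monotonicity is asserted at every
iteration performed); forward-algorithm exactness is checked against path
enumeration on instances up to K = 3, T = 8. Determinism is verified by
hashing every non-log output of two identically-seeded runs.

## Known limitations

- Posterior-argmax decoding can fragment long runs when the learned
  transition matrix is dominated by short planted runs; the labels-based
  TSS-state set absorbs most of this, but recovery of planted broad domains
  is only guaranteed under the generator's separation condition.
- The Bernoulli emission model ignores count magnitude beyond the 0/1 call.
- TMM here is the raw-count-M variant described above, not the edgeR
  library-normalized variant; factors are not interchangeable between the
  two conventions.
- The t-ranking flags a fixed top decile; it is a ranking, not a calibrated
  test, and carries no error-rate guarantee.
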