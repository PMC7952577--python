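# Methods

## The measurement model

An iSort-seq experiment observes each library variant i as raw read counts
R(i,j,k) over six inducer levels j and eight fluorescence bins k, together
with the sorter's per-(level, bin) cell fractions %cells(j,k) and bin
upper-edge fluorescences Bin(j,k). Because every bin is sequenced to
(approximately) equal depth while holding very different numbers of cells,
raw reads measure a variant's *share of the cells in a bin*, not its cell
density; multiplying by %cells converts shares back to densities,
N = R · %cells. That is also why the strict read-support filter (every bin
above 30 raw reads) is meaningful: raw reads in a sparsely populated gate
are dominated by whichever variants are relatively closest, so read support
reflects sampling adequacy, not absolute fluorescence probability.

Per retained (variant, level), the renormalised 8-bin histogram is
cumulated and fitted with a cumulative Gaussian evaluated at the bin upper
edges; the fitted location μ(i,j) is the variant's reporter level, σ(i,j)
its spread, and levels with fit R² ≤ 0.5 are discarded. μ is normalised per
variant by its maximum over usable levels and rescaled by the per-level
mean over negative controls, which cancels any multiplicative per-level
("day-effect") distortion exactly: if every μ(i,j) carries a common factor
d_j, μ_norm carries it too, and dividing by the negative-control mean
removes it. All filter inequalities are strict as worded (> 30 reads,
> 300 total, R² > 0.5, basal below 15% dropped).

Numerical choices: the fit abscissae are the bin upper edges (a CDF is
naturally evaluated at interval upper boundaries); the least squares is
unweighted; μ is initialised at the read-weighted mean of the edges and
bounded to [min edge/10, max edge·10], σ > 0; a failed optimisation falls
back to the weighted-moment initialiser. Variants need at least three
usable levels to proceed (the downstream regression needs a slope, a fit
quality and a high-level spread).

## Responsiveness scoring

Features per variant: the slope and R² of an ordinary least-squares line of
μ̃ against the inducer *index* (present levels only) and the population
standard deviation of μ̃ over the three highest levels. Control populations
are fitted by maximum likelihood (sample mean, 1/N covariance); a ridge
ε·I with ε = 1e-8·trace/3 is added when the covariance is near-singular
(degenerate control sets). The responsiveness score is the natural-log
density ratio; natural logarithms and population (1/N) standard deviations
are used throughout, consistent with the ML Gaussian fit — including in the
binder-threshold rule (across-protein mean of mean − std of the strictly
positive positive-control scores). Scores are averaged over a design's
surviving barcodes; designs with no surviving barcode are absent rather
than imputed.

The non-parametric companion score replaces the Gaussians with mean squared
Euclidean distances to the control dose-response 6-vectors,
R_ANN = ln(S_neg/S_pos), defined only for variants (and controls) with all
six levels present; coincidence with an entire control class yields an
infinite sentinel rather than an arbitrary large number.

The affinity calibration maps scores to binding free-energy differences via
the linear relation score ≈ a + b·K_d: calibration pairs are screened at
ΔΔG > −6.667 and score > 3.5, the normalised score ratio is regressed on
exp(ΔΔG) (the relative K_d), and ΔΔG(i) = ln[(score_i/score_wt − a)/b],
flagged undefined when the argument is non-positive. The regression
direction is a convention (the linear form does not dictate one); the
reverse direction is available via a flag. The ΔΔG formula is implemented
exactly as the source analysis states it; note that combined with
ΔG = −k_BT·ln K_d it carries a sign tension (higher score ↦ higher K_d),
which we reproduce rather than silently "fix".

## Binding models

Sites are encoded as (4+5)×50 binary matrices: one-hot sequence over the
50-nt padded transcript context, plus one-hot structural contexts (lower
stem LS, bulge B, upper stem US, loop L, no-hairpin N) zeroed outside the
site span. Padding uses the true flanks: the last 10−|δ| nt of the
ribosomal initiation region followed by the prefix δ ∈ {C, GC} upstream
(10 nt in total), and the 5' mCherry sequence downstream. Because the
flanks are constant and the first layer is a convolution, they carry no
discriminative signal.

WT-specific models are dense networks (1–3 hidden layers, 5–50 nodes,
identity/tanh/relu, dropout 0.2 per hidden layer, batch 8); whole-library
models are convolutional (kernel length 4–10, 4–35 kernels, relu, global
max pooling, 1–3 dense layers of 5–40 nodes, batch 16); both use Adam at
learning rate 0.001 with MSE loss and an identity output node.
Hyper-parameters are chosen from 25 uniform random draws by 3-fold
cross-validated mean Pearson correlation, ties to the earliest draw,
degenerate (zero-label-variance) folds scored −∞. The networks are
implemented in a compact NumPy engine (`sortbind.nn`) whose gradients are
verified against finite differences in the test suite; weight
initialisation is seeded He/Glorot-style normal and intra-epoch shuffling
is seeded, so training is bit-reproducible single-threaded. Global max
pooling after the convolution follows standard motif-CNN practice. Pearson
correlation with a zero-variance vector is defined as 0 with a warning.

Model evaluation reports held-out Pearson correlation and, binarising
labels at the 3.5 threshold, ROC AUC (optional label-shuffle empirical
p-value). The structure-ablation comparison retrains, per repetition, the
same architecture with and without the five structural rows on a fresh
80/20 split and applies a paired Wilcoxon signed-rank test over
repetitions.

## Structure services

Folding is pluggable: the `vienna` backend shells out to `RNAfold`
(thermodynamic; required for design runs — the CLI refuses the builtin
backend for prediction unless `--allow-builtin-fold` is passed), and the
`builtin` backend is a deterministic Nussinov-style maximum base-pairing
fold with minimum loop length 3 — explicitly non-thermodynamic, for tests.

The context parser assigns: loop = the unpaired run enclosed by the
innermost pair; interior unpaired runs on either strand side = bulge;
paired positions whose pair interval encloses a bulge = lower stem,
otherwise upper stem (so bulge-free hairpins are all upper stem); exterior
unpaired = no-hairpin; multi-hairpin strings are annotated all-N with a
warning. These rules are this package's convention.

Structure-altering mutagenesis edits upper-stem length (paired insertions
just inside a random upper-stem pair / random pair deletions), loop length
and bulge size; inserted positions are encoded as the uniform composition
vector [0.25]*4 so structural effects stay decoupled from sequence effects,
and only instantiated to concrete bases (complementary A–U/C–G for pairs)
under a logged seed when a concrete sequence is required. Degenerate
outcomes (upper stem deleted, bulge merged into the loop, loop under the
minimum) are flagged, and a post-check hook re-folds instantiated sequences
and compares context profiles. SNP maps score all three substitutions at
loop/bulge positions; DNP maps apply the three complementary pair swaps
jointly to both stem partners.

## The synthetic experiment

The simulator is the package's ground-truth instrument; its defaults are
the study conditions it emulates:

- six inducer levels 0, 0.02, 0.2, 2, 20, 200 µM; repression follows a
  Hill form mean_j = basal / (1 + (c_j/K_d)^h) with h = 1 and protein level
  proportional to inducer; non-binders have K_d = ∞;
- libraries of 10,000 mutated sites (half structure-preserving →
  binders with K_d log-uniform in [60, 600], half structure-altering →
  non-binders), each at both prefixes and five barcodes, plus wild-type
  positive controls (K_d = 100) and random-sequence negatives; basal
  log-uniform in [3·10³, 8·10³] a.u.; suffixes chosen to preserve the
  reading frame;
- single-cell fluorescence is log-normal around the (day-distorted) mean
  with CV 0.3, plus a 5% background of events spread log-uniformly over
  the sorter range — the debris/doublet/maturation events any real sort
  contains, and the reason every gate holds every variant at some level;
- eight log-spaced bin upper edges partition the fluorescence range
  [10², 3·10⁴] up to its 95% point (the top 5% is excluded, as the sorter
  operators did); day-effect multipliers (0.5, 1, 1, 0.5, 1, 0.5) mirror
  the grouping of levels 1/4/6 onto one experimental day;
- each (level, bin) is sequenced to equal depth (reads_per_level/8, default
  4·10⁶ per level), reads multinomial across variants in proportion to
  their cell counts in the bin — the scheme under which the %cells
  normalisation is exactly the right correction.

What the simulator does *not* emulate: PCR amplification bias, barcode
sequencing errors, sorter spillover/compensation, growth-rate differences
between bins, and any sequence-dependence of the ground-truth affinity
beyond the structure-preserving/altering dichotomy. Passing
parameter-recovery tests therefore demonstrates that the estimator inverts
the simulated measurement process faithfully — not that real libraries are
free of those additional effects. One visible consequence: synthetic
control populations are far tighter than real ones, so responsiveness
scores sit on a much larger numeric scale than measured data produce, and
the computed positive-control threshold is correspondingly large; the
canonical 3.5 remains the package's default classification boundary.

Test and acceptance problem sizes (chosen as the package's own fixture
scale): recovery on a 200-site library, discrimination on a 400-site
library (200 binders / 200 non-binders), planted-motif CNN on 4,000
padded sites, structure ablation on 600 sites × 100 repetitions, balanced
sampling at 10⁶ sequences.

## De-novo design

The design space is substitution-only (Hamming 3–7); its closed-form size
Σ_k C(L,k)·3^k is cross-checked against exhaustive enumeration on toy
lengths in the tests. Sampling draws the shell k proportional to its size
(uniform over the neighbourhood), balanced per wild type at the quota
floor(n/3) — for 10⁶ requested, the printed 333,333 per part — with
rejection of duplicates and training-library members. Classification at
the 3.5 threshold is strict on both sides, so a score exactly at the
boundary is unclassified rather than silently assigned. Cassette assembly
is greedy by descending intended score (the weaker of the two proteins for
dual intent; lexicographic tie-break for reproducibility) under certified
constraints: pairwise Hamming ≥ 4 (edit distance for mixed lengths), edit
distance ≥ 5 from every wild type, and rejection of sites containing the
two cloning restriction motifs (BamHI/ApaLI) as a practical extension.
Inter-site linkers are user-supplied; emission produces a DNA FASTA record
plus a 0-based half-open annotation table, and a suffix-scan utility
verifies the absence of repeated 20-mers.

## Known limitations

- The cumulative-Gaussian fit is performed on a linear fluorescence axis
  against log-normal-ish data; for CV ≳ 0.5 the fitted μ acquires a
  skew-dependent bias of several percent. At the emulated noise level
  (CV 0.3) the bias is ~3% median.
- The builtin fold maximises pair count, not free energy; it exists so the
  structural pipeline is testable without ViennaRNA and must not be used
  for production design.
- The ΔΔG calibration is only as good as the external reference pairs; the
  package ships no reference dataset and treats the calibration table as
  user input.
- Whole-library models accept any site ≤ 40 nt, but training data in the
  19–25 nt range dominates what the models can be expected to extrapolate.
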