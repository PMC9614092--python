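# Methods

## The prediction problem

A multi-environment trial observes a quantitative trait *y*ᵢⱼₖ on line
*j* (of *J*) in environment *i* (of *I*), replicate *k*. Three nested
mixed models describe the data, differing in the random effects beyond
the intercept μ and i.i.d. residual ε ~ N(0, σ²_ε):

- **E+L**: environment main effect *E*ᵢ ~ N(0, σ²_E) and a non-genomic
  line effect *L*ⱼ ~ N(0, σ²_L). The marker-free baseline.
- **G+E**: *E*ᵢ plus a genomic value **g** ~ N(0, σ²_g **G**) with
  **G** = *XX*′/*d* the genomic relationship among lines.
- **G+E+G×E**: additionally a genotype-by-environment deviation
  **gE** ~ N(0, σ²_gE [**Z**_g**G Z**_g′] ∘ [**Z**_e**Z**_e′]), the
  reaction-norm construction in which the interaction covariance is the
  Schur product of the observation-level genomic and environment
  kernels: two observations share interaction covariance **G**ⱼⱼ′ when
  they sit in the same environment and zero otherwise.

*X* is centered and scaled per marker with the population (divisor-*n*)
standard deviation, so trace(**G**) = *n* holds exactly; this is the
scale convention all kernels and tests rely on. Projected
(feature-extraction) reductions are re-standardized column-wise before
**G** so kernels stay on this common scale across reduction methods,
which the accuracy comparisons implicitly require.

## REML fitting

Writing Cov(y) = Σ_r σ²_r **K**_r + σ²_ε **I** over the training rows,
the residual variance is profiled out analytically and the restricted
likelihood is maximized over the log variance ratios γ_r = σ²_r/σ²_ε
with Nelder–Mead (derivative-free; nonnegativity is automatic in the
log parameterization). Tolerances: function 1e-6, parameter 1e-4 in log
space, 500 evaluations per start with up to two restarts from the
incumbent — a restart rebuilds the simplex, which resolves the slow
creep that occurs when a component is pinned at the zero boundary
(log-ratio → −∞, a flat direction). Log ratios are clipped to ±30; a
component with γ below 1e-8 is reported as exactly 0. The intercept is
the GLS estimate at the optimum. Non-convergence after the restarts
raises an error carrying the last iterate.

Prediction of held-out observations is the conditional mean of the
fitted joint Gaussian, μ̂ + **C**ₜₑ,ₜᵣ **V**ₜᵣ⁻¹(y_tr − μ̂), assembled
from the same kernels; a 1e-8 relative jitter is added to the diagonal
only if the Cholesky of **V**ₜᵣ fails. For a test observation in an
environment absent from training, the environment and interaction
cross-covariances vanish and the prediction reduces to the intercept
plus the genomic (or line) term — the mechanism behind CV0.

## Randomized linear algebra

Sketch operators map length-*d* vectors to length-*k* vectors and are
scaled so E‖**S**v‖² = ‖v‖²: Gaussian entries N(0, 1/k); Rademacher
±1/√k; sparse Rademacher with 2/3 zeros and ±√(3/k) otherwise; the
count sketch with exactly one ±1 per input coordinate; and the FJLT
(subsampled randomized Hadamard transform) **P H D** — random signs, a
normalized Hadamard rotation computed by an in-package fast
Walsh–Hadamard transform after zero-padding *d* to the next power of
two, and uniform coordinate subsampling without replacement scaled by
√(d_pad/k).

Exact leverage scores of marker columns are the squared column norms of
the top-*k* right-singular-vector matrix (scores sum to *k*); the
importance distribution normalizes by the score total, which coincides
with dividing by the column count exactly in the full-rank square-basis
case and is a proper distribution in every case.

The approximate scores follow the two-stage scheme on the transposed
(tall) matrix: an FJLT with r₁ rows compresses the long axis, the
pseudo-inverse is computed on the sketched matrix (SVD, singular values
below 1e-10 of the largest treated as zero), and a second-stage
projection with r₂ columns compresses the row-norm computation.
Defaults r₁ = 2·min(n, d) and r₂ = ⌈8 ln d⌉ follow the
small-first-stage / large-second-stage recipe: r₁ drives runtime, r₂
drives quality. Two numerical choices reduce the estimator's variance
without changing its expectation: the second-stage Gaussian is
orthonormalized column-wise (an orthogonal random projection, scaled
√(r₁/r₂); when r₂ ≥ r₁ this becomes an exact rotation), and the
returned scores are rescaled to sum to the sketch rank — the constraint
the exact scores satisfy by construction. A sketch that loses the rank
the caller requires is retried with a fresh seed up to three times.

## The five reducers

All operate on the standardized matrix and record method, size and seed
provenance. Selection modes return exact column submatrices with marker
IDs; the projection mode returns linear combinations without IDs.

- Random projection uses the FJLT sketch (the fast, low-storage choice
  among the catalogued sketches).
- Random sampling draws *k* distinct markers without replacement from
  the leverage importance distribution (sequential renormalization);
  with-replacement draws would be degenerate for a selection method.
- Deterministic sampling takes the top-*k* scores, ties broken toward
  the lower column index (so top-*k* sets are nested); a threshold
  variant returns the smallest count whose score sum exceeds θ. In the
  experiment grid the ranking uses exact scores truncated to a Kaiser
  rank (components with above-average variance) by default: full-rank
  leverage on near-exchangeable markers rewards atypical columns
  (e.g. rare-allele outliers) rather than the dominant LD structure,
  while the truncated scores target the subspace that actually carries
  the genomic relationship.
- Clustering builds one Ward tree over marker columns (Euclidean
  distance on the standardized vectors — the conventional pairing with
  Ward), caches it per matrix content, cuts it into exactly *k*
  clusters and samples one representative per cluster, fresh per
  (size, replicate).
- Ridge ranking fits the whole penalty grid via one thin SVD of the
  centered design per CV fold (the closed-form ridge path), picks the
  penalty with minimal cross-validated squared error, and ranks markers
  by |coefficient|, ties toward the lower index. The line-level
  response defaults to the per-line mean phenotype across environments.

## Cross-validation and the trend summary

CV0 is deterministic leave-one-environment-out; CV1 partitions *lines*
into 5 folds; CV2 partitions observations into 5 folds ignoring line
and environment structure. CV1/CV2 are repeated with independent
partitions reproducible from (seed, replicate). Accuracy is the Pearson
correlation between observed values and predictions, computed per
environment among the test observations; environments with fewer than
3 test pairs or numerically constant vectors are flagged undefined and
excluded with a count (constant predictions genuinely occur, e.g. the
E+L baseline under CV1, where held-out lines have no trained line
effect). Averaging is per-environment correlation per fold → mean over
folds and replicates per environment → mean over environments for the
headline number.

By default `run_cv` re-estimates variance components in every training
fold. The experiment grid instead estimates them once per reduced set
on the full data and re-solves only the BLUP system per fold
(`refit_per_fold=False`) — the standard shortcut for large grids; the
small-scale refit path is what the oracle tests exercise.

`summarize_trend` reports, per method × model × scheme, the mean
accuracy per size and **size_95**, the smallest evaluated size whose
mean accuracy reaches 95% of the grid maximum.

Replicate seeds fan out deterministically from one master seed as a
pure function of (method, size, replicate), so any single cell can be
reproduced in isolation; stage failures are recorded per cell and the
grid continues.

## The synthetic generator

The generator emulates the shape of a multi-environment screening
nursery (hundreds of lines, ~10 environments, 10³–10⁴ SNPs) with known
truth; defaults are 315 lines × 9 environments × 1 replicate.
Genotypes: each line draws two latent Gaussian "haplotypes" whose
markers share an equicorrelated factor within consecutive blocks
(`block_size`, `within_block_rho`; optionally a per-block correlation
range for heterogeneous LD); each latent value is thresholded at the
quantile of the marker's allele frequency, drawn uniformly from
`maf_range`, and the two alleles sum to a 0/1/2 dosage. Phenotypes
follow the G+E+G×E generating model with an optional independent line
effect: environment effects are i.i.d. normal draws, genomic values are
built from `n_causal` standardized markers with i.i.d. normal effects
and then rescaled so their realized population variance across lines
equals σ²_g exactly (making parameter-recovery targets exact rather
than in-expectation), and the interaction deviation is drawn by
Cholesky of the Schur-product covariance restricted to observed cells
(1e-8 diagonal jitter). One integer seed fans out to independent
substreams for genotypes, effects and noise.

What the generator does not emulate: coalescent or pedigree ancestry,
population structure or kinship among lines, realistic allele-frequency
spectra, linkage between blocks, or non-Gaussian residuals. Passing
tests therefore demonstrate the pipeline's internal correctness and its
qualitative behaviour under tunable marker redundancy — not accuracy
levels attainable on any particular crop data set.

## Quality control

Marker filters (missingness > 10%, MAF < 5%, monomorphic), line filter
(missingness > 10%), then per-marker mean imputation — conventional
genomic-selection practice, fully configurable; the operation is
idempotent at fixed thresholds. VCF import converts diploid GT fields
to ALT-dosages, treats phased and unphased alike, and drops
multi-allelic sites with a logged count.

## Study sizes used by the tests

The self-contained checks run at desk scale on one CPU: leverage
approximation on a 4096 × 50 Gaussian matrix (r₁ = 500, r₂ = 200);
parameter recovery on 200 lines × 5 environments with 600 markers and
20 replicate fits per model; the accuracy-plateau study on 150 lines ×
3 environments with 5,000 markers (blocks of 100 at correlation 0.85,
MAF 0.15–0.5), 500 causal markers, per-cell heritability 0.5, a 6-point
size grid, 10 reduction replicates and 5 CV repartitions under CV1 for
the G+E model. The full study grid (26 sizes, 100 reduction replicates,
20 CV repartitions, all models and schemes) is expressed by the default
`ExperimentConfig` and scales linearly in those counts.

## Known limitations

- REML uses dense Cholesky factorizations, O(n_obs³) per likelihood
  evaluation; trials beyond ~5,000 observations need the shared-fit
  shortcut and patience.
- With i.i.d. simulated lines the leverage profile of markers is nearly
  flat, which understates how well leverage-based selection works on
  structured real panels (where scores decay like a power law).
- The undefined-correlation rule excludes degenerate (environment,
  fold) cells rather than imputing zeros; headline means are over the
  defined cells only, with the exclusion count reported.
- Ridge ranking (like the study design it follows) selects markers
  using all lines' phenotypes before cross-validation, so its
  accuracies carry selection bias relative to the other methods and
  peak at small sizes.
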