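# Methods

`ftirharvest` implements a complete chemometric workflow for deciding when
to harvest a medicinal plant from its ATR-FTIR fingerprint and its
morphology: spectral pretreatment, generalized two-dimensional correlation
spectroscopy (2DCOS), month classification (PLS-DA, GA-tuned SVM, a small
residual CNN on correlation images), PLS calibration of dry matter content
(DMC), and a trait-table factor analysis that ranks the twelve months.
Because no field data ships with the package, a seeded simulator generates
datasets with the statistical structure the workflow assumes; this note
records the models, the defaults and the design choices, and what the
synthetic results do and do not demonstrate.

## Spectral model and pretreatments

Spectra live on a strictly monotone wavenumber grid, nominally 4000 to
452 cm⁻¹ in 4 cm⁻¹ steps (888 points); replicate scans of one sample are
averaged before analysis. Pretreatments are the standard chemometric set:

* **SG smoothing / FD / SD** — Savitzky–Golay filtering and first/second
  derivatives, default window 9 points, polynomial order 2. Derivatives are
  taken with respect to wavenumber (the sign convention accounts for the
  descending grid), and the fitting polynomial is extended to the edges so
  the grid length is preserved.
* **MSC** — each spectrum is regressed on the set's mean spectrum by
  ordinary least squares, x ≈ a + b·ref, and corrected to (x − a)/b. A flat
  reference or a zero slope raises a degenerate-spectrum error naming the
  offending row.
* **SNV** — row-wise centring and scaling by the row's own sample standard
  deviation.

**Kennard–Stone split.** The calibration set (default 70 %) is selected by
classical maximin: seed with the two most distant rows (Euclidean), then
repeatedly add the row whose minimum distance to the selected set is
largest. Ties break to the lowest row index and the train size is
round-half-up of n × fraction, so the split is fully deterministic. The
distance space is the preprocessed absorbance rows, uncompressed. Note
that KS deliberately moves the most extreme samples into the calibration
set; test-set variance (and hence test R² and RPD) is therefore slightly
conservative.

## Two-dimensional correlation spectroscopy

For a perturbation-ordered series of m spectra, dynamic spectra S are
obtained by subtracting a reference (the series mean by default; `first`
and `none` are options). Then

* synchronous map: Φ = SᵀS / (m − 1)
* asynchronous map: Ψ = SᵀNS / (m − 1), with the Hilbert–Noda matrix
  N_jk = 0 on the diagonal and 1/(π(k − j)) off it
* integrated map: I = Φ ⊙ Ψ (elementwise).

Φ is symmetric with non-negative diagonal; Ψ is antisymmetric with zero
diagonal; both are verified against brute-force summation in the tests.
Per-sample maps use the sample's replicate scans as the perturbation
series, optionally extended with seeded bootstrap copies (a randomly
chosen replicate plus Gaussian noise at the per-wavenumber
replicate-residual scale). Month-level maps use the sequence of monthly
mean spectra. The grid is decimated by uniform stride to ≤ 256 points
before the O(p²) computation; rendering min–max scales a map to [0, 1]
(a constant map renders uniform mid-scale), applies a matplotlib colormap
and resamples bilinearly to the requested size — byte-identical PNGs for
identical inputs.

Two readings of the per-sample perturbation deserve note. With the mean
reference, replicate dynamics contain only the within-sample variation
(scatter and noise); those maps characterise the instrument more than the
sample. With `reference='none'` the static spectrum dominates and the map
is essentially the outer product of the sample's band structure — the
robust choice when the maps feed an image classifier, and the one used in
the CNN checks.

## Latent-variable models (NIPALS)

One NIPALS engine powers both tasks. X and Y are mean-centred, X is not
variance-scaled (the spectroscopy convention); components are extracted by
the usual power iterations with deflation of X and Y, and regression
coefficients are B = W(PᵀW)⁻¹Qᵀ. With the full number of components on a
full-rank system the fitted values coincide with ordinary least squares
(tested to 1e-8), and X-scores are mutually orthogonal.

**PLS-DA.** The response is a one-hot dummy matrix over the sorted class
labels. Diagnostics follow chemometric practice: RMSEE on the training
fit, RMSECV and Q² = 1 − PRESS/SS pooled over stratified 7-fold
cross-validation, RMSEP on the external test set, R² on the training dummy
response, accuracies in percent. A permutation test refits the model under
n (default 200) seeded label shuffles and reports the permuted R²/Q²
distribution plus each shuffle's correlation with the original labels; a
sound model places the original Q² above the permuted 95th percentile.

*Decision rule.* The classical reading assigns a sample by the largest
predicted dummy-Y value. With twelve classes whose centroids lie largely
along one smooth seasonal intensity continuum, least-squares regression on
indicator responses suffers the well-known class-masking defect: interior
classes are systematically absorbed by their neighbours (on the synthetic
study the argmax rule plateaus near 85 % test accuracy even in its OLS
limit, while the same splits are perfectly linearly separable). The
default decision rule is therefore distance-based, as in the standard
PLS-DA implementations of the multivariate-omics ecosystem: a sample goes
to the nearest class centroid in latent-score space under the pooled
within-class covariance metric (a Mahalanobis distance; the pooled
covariance is regularised by a 1e-10 relative ridge and inverted by
pseudo-inverse). `rule='argmax'` retains the classical reading, and a
per-class 0/1 membership output at the 0.5 dummy-Y threshold is kept for
the one-vs-rest interpretation.

**PLSR.** Univariate calibration of DMC (%) against spectra. The test-set
report carries the factor count, the least-squares slope of predicted
versus reference, RMSE, R² = 1 − SSres/SStot, and RPD = SD(reference)/RMSE
with the sample (n−1) standard deviation, so RPD·RMSE = SD holds exactly.
RPD bands: < 1.4 inadequate for quantitative use, 1.4–2.0
semi-quantitative, > 2.0 quantitatively reliable. The factor count is
chosen by cross-validated RMSECV on contiguous-block folds; the default
rule takes the smallest count within one standard error of the minimum
(with a 1e-9 relative slack so an exactly-zero CV error is stable), and
`rule='min'` takes the plain minimiser — the better choice when the signal
is known to be high-dimensional, and the one the pipeline uses.

## Auxiliary classifiers

**GA-SVM.** An RBF support-vector classifier whose penalty c and kernel
coefficient g are tuned by a real-coded genetic algorithm on
(log₁₀ c, log₁₀ g): tournament selection (size 3) with elitism, uniform
crossover (p = 0.8), Gaussian mutation (p = 0.1, σ = 0.3 log units),
population 20, 30 generations, fitness = stratified cross-validated
training accuracy. Default bounds c ∈ [1e-2, 1e3], g ∈ [1e-5, 1e2] span
both very smooth and very sharp kernels. The search is fully seeded.

**Residual CNN.** A 14-weighted-layer residual network written directly in
NumPy (im2col convolutions, batch normalisation, manual backpropagation —
the backward pass is verified against numeric differentiation in float64).
The budget is one 3×3 stem convolution, three stages of [Conv block +
Identity block] (two 3×3 convolutions per block; the Conv block adds a 1×1
projection shortcut, not counted in the depth, where the shape changes),
global average pooling and one linear classification layer: 1 + 12 + 1 =
14. Channel widths 16/32/64; spatial downsampling by stride 2 at stages 2
and 3. Training is SGD with momentum 0.9, learning rate 0.01, weight decay
1e-4 on convolution/linear weights, batch size 16, softmax cross-entropy,
on a seeded stratified 60/30/10 train/test/external split; the best model
by test accuracy (ties to lower loss) is restored before the one-shot
external validation. All randomness (init, split, batch order) flows from
one seed, and images at 64–224 px train small datasets in minutes on one
CPU. Optional early stopping ends training once train and test accuracy
both reach 100 %.

## Phenotype statistics

CV is the sample standard deviation over the mean (cells above 0.20 are
flagged unstable); DMC = dry/fresh × 100 %; water content is its exact
complement. The factor analysis extracts principal components of the
trait correlation matrix (so results are invariant to affine rescaling of
any trait), retains eigenvalues > 1 by default (an explicit override is
available), varimax-rotates the loadings (statsmodels' rotation), fixes
signs so each factor's dominant loading is positive, and orders factors by
post-rotation explained variance. Factor scores use the regression
method, F = Z R⁻¹ Λ. Because water content is the exact complement of DMC,
the correlation matrix is exactly rank-deficient by construction; the
pseudo-inverse supplies the least-squares regression scores on the
degenerate matrix, and an error is raised only for zero-variance traits,
naming them. Composite month scores weight mean factor scores by
contribution/cumulative-contribution and months are ranked descending.

Spearman correlations between monthly trait means and solar
radiation/precipitation use exact permutation p-values (two-sided, all n!
orderings) for n ≤ 8 paired months — the harvest window has six — and the
t-approximation otherwise; constant traits report a missing ρ.

The harvest report composes the composite ranking, monthly mean stem/leaf
DMC and the CV flags. The "suitable window" collects months in the top
half of the composite ranking or with leaf DMC above the annual mean; the
"optimal" month maximises leaf DMC within the window. These rules are an
explicit, configurable heuristic rendering of the agronomic narrative
(rank by overall performance, decide by yield proxy), not a statistical
test; months whose trait means are flat relative to the trait magnitudes
(relative range < 1e-6 on the raw scale) are reported as having no
distinct window.

## Synthetic study design

The simulator draws a year-round study: 12 months × 12 plants × stem and
leaf × 3 replicate scans. Each clean spectrum is a sum of ten Gaussian
bands at the carbohydrate/protein positions 3417, 2920, 2850, 1702, 1595,
1440, 1380, 1322, 1260 and 1027 cm⁻¹. Three structures are layered on the
bands:

* a **month amplitude profile** (0.85–1.35) with November–March elevated
  and December maximal, so December has the strongest integrated
  absorbance;
* a **month band signature**: a deterministic zero-mean Fourier design
  over the prime modulus 13 (cosine/sine characters at frequencies 1–5
  across the band index), added to the non-carbohydrate band amplitudes at
  scale 0.2. The design guarantees near-uniform pairwise separation of all
  twelve month patterns — a random signature can leave two months
  accidentally collinear — and an additive (not multiplicative) signature
  keeps low-intensity summer months as distinguishable as winter ones;
* a **latent DMC level** per plant and part: the part's seasonal DMC
  pattern (stem accumulating towards April, leaf peaking sharply in
  December, matching the agronomic narrative and keeping the two patterns
  decorrelated) times (1 + 0.12·u) with u a standard-normal plant
  deviation. The four carbohydrate bands (3417, 1322, 1260, 1027 cm⁻¹) are
  directly proportional to this level, so the spectra → DMC map is linear
  up to the per-band jitter.

Replicates add multiplicative slope (0.98–1.02), additive offset (0–0.01
AU) and white noise (SD 0.002 AU). `class_separation` scales every
between-month difference; at 0 the months are statistically identical up
to plant variation and classification falls to chance.

Traits derive from three independent latents — a shared lognormal size
latent for X1–X5, and the stem and leaf DMC latents for X6/X8 and X7/X9 —
so the factor analysis should retain exactly three factors. Dry weights
are computed as fresh weight × DMC/100, water contents as exact
complements. DMC adds Gaussian linkage noise (default SD 0.3 %; the
calibration-recovery checks run at 0.15 %, the "low linkage noise"
condition). Fresh stem weight carries a planted negative monotone link to
solar radiation (a 50 % drop from the least to the most irradiated month),
and the environment table holds subtropical-highland scale radiation and
monsoon precipitation values.

**What passing tests show — and don't.** The synthetic study exercises the
full pipeline logic: deterministic I/O, oracle-exact correlation maps and
PLS algebra, recovery of planted structure (classes, a linear calibration,
three factors, a December optimum, a negative environment link). It does
not demonstrate performance on real plant material: real FTIR fingerprints
have correlated baselines, water-vapour artefacts, Lorentzian/Voigt band
shapes, month differences far less orthogonal than the Fourier signature,
and reference DMC measured with its own error. Published-scale accuracies
(100 % CNN classification, RPD near 9) are reproduced here only in the
sense that the same algorithms reach them under clean, separable
conditions.

## Numerical choices and degenerate inputs

Grids match if pointwise |Δ| ≤ 1e-6 cm⁻¹; no resampling is implemented.
NIPALS stops an iteration at relative score change ≤ 1e-12 (max 1000
iterations) and truncates cleanly if Y is exhausted early; zero-variance X
columns are kept with zero weight and a warning. KS ties break to the
lowest index everywhere. The CNN uses float32 with He initialisation;
batch-norm uses eps 1e-5 and momentum 0.1. Exact permutation p-values cap
at n = 8 (40 320 orderings). Empty spectra sets average to empty sets
without error; single spectra cannot form a perturbation series unless
augmented.

## Problem sizes used in the checks

The bundled checks run the default study (144 plants per part, 888-point
grid), a 200-shuffle permutation test, 100 seeded Kennard–Stone instances
at n ≤ 8, and a 60-image, 3-class correlation-image set at 64×64 px for
the CNN — sizes chosen so the whole verification runs in a few minutes on
a single CPU while still exercising every stage at full algorithmic
fidelity.

## Known limitations

* The CNN is CPU-bound NumPy; it is meant for small correlation-image
  datasets, not GPU-scale training, and has no data augmentation beyond
  the COS bootstrap copies.
* PLS-DA diagnostics (R², Q² on the dummy response) follow the common
  SIMCA-style conventions but are not numerically interchangeable with any
  specific commercial implementation.
* The harvest-window rule is a documented heuristic; its thresholds (top
  half, annual-mean DMC) are configurable but arbitrary at the margins.
* The simulator's scatter model is affine per scan; it does not emulate
  ATR penetration-depth wavelength dependence or atmospheric compensation
  residuals.
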