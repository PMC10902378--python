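# Methods

This note documents the models, defaults and numerical choices behind
`mlde`, and what the synthetic benchmarks do and do not establish.

## Assay model

The screening readout is photometric: substrate depletion tracked by
absorbance at 340 nm, recorded every 5 minutes for 80 minutes (17
samples per well). A well's initial rate is the ordinary-least-squares
slope of its trace, reported as a positive magnitude of decline in
ΔA·min⁻¹.

**Linear-range detection.** Initial-rate logic demands a window anchored
at t = 0, so `estimate_slope` scans *prefix* windows: the longest prefix
with at least `min_points` samples (default 4) whose linear fit reaches
`linearity_threshold` (default R² ≥ 0.99) is used. If no window
qualifies, the first `min_points` samples are used and the record is
flagged rather than silently accepted; flags propagate into the
normalization report. A constant trace counts as perfectly linear with
slope 0 (the zero-variation case is resolved in favour of R² = 1 when
the residuals are at round-off level). The default threshold tolerates
mild measurement noise; for noiseless or very clean traces a stricter
threshold (e.g. 0.999) pins the window to the exactly linear prefix,
because at 0.99 a window containing one saturated point can still
qualify.

**Plate normalization.** Activities are slopes divided by the mean
parent-control slope on the same plate (FIOP). This makes labels
invariant to any multiplicative per-plate factor — reader gain, lysate
batch, temperature — which is exactly the nuisance the generator
simulates. Parent identification is by exact variant-name match against
a declared parent per library, because successive campaign rounds use
different parents (wild type, then successively evolved hits).
Fold-improvement over wild type (FIOWT) is the product of FIOP values
along the lineage; reported values are rounded toward zero at two
significant figures (a 22.5-fold product prints as 22), stored values
stay unrounded. Replicate wells of one variant are aggregated by mean
by default (max is available) before model training.

## Variant encoding

Variants are identified by substitution strings (wild-type letter,
1-based position, new letter; underscore-joined, e.g. `F97W_L241M`) and
validated letter-by-letter against the parent FASTA. The feature vector
concatenates, per modulated site, 13 amino-acid descriptor values —
giving 39 dimensions for a 3-site library and 65 for a 5-site library.

The default table is a curated set of 13 classical scales
(Kyte–Doolittle hydropathy, Zamyatnin volume, Grantham polarity,
isoelectric point, net charge at pH 7, Hopp–Woods hydrophilicity,
Bhaskaran–Ponnuswamy flexibility, the three Chou–Fasman propensities,
maximum solvent-accessible surface area, residue mass, and
Charton–Charton polarizability). The identity of the scales changes the
numbers but not the pipeline structure, so every operation accepts a
user-supplied table (20 residue rows × property columns) to reproduce
any specific choice. Descriptors are standardized to zero mean and unit
population variance across the 20-residue alphabet, *not* across a
training set: encodings are therefore dataset-independent, and train and
prediction encodings are identical by construction. The default table
has no duplicate residue rows, so distinct residue combinations at the
listed sites always encode distinctly.

## Gaussian-process model

A zero-mean GP with squared-exponential kernel
k(x, x′) = σ_f²·exp(−‖x−x′‖²/(2ℓ²)) and i.i.d. Gaussian noise σ_n².
A single shared length scale is the default; the kernel family is the
standard choice of the GP-regression ecosystem for this kind of
moderate-dimensional, smooth-response problem.

Fitting follows the classical Cholesky route: factor
K + σ_n²I = LLᵀ, α = Lᵀ\(L\y), predictive mean k*ᵀα, latent variance
k(x*,x*) − vᵀv with v = L\k*, and log marginal likelihood
−½yᵀα − Σᵢ log Lᵢᵢ − (n/2)log 2π. Numerical choices:

* **Jitter policy.** If the factorization fails, a diagonal jitter of
  1e−10 is added and escalated ×10 up to 1e−6 before raising an error
  that reports the attempted jitter.
* **Variance clipping.** Predictive variances are clipped to zero from
  above −1e−10; anything more negative raises, since it would indicate
  a genuine numerical fault rather than round-off.
* **Hyperparameter optimization.** L-BFGS-B on (log σ_f², log ℓ,
  log σ_n²) with analytic gradients, bounds ℓ ∈ [1e−2, 1e3] and
  variances ∈ [1e−8, 1e3]; one data-driven start (label variance,
  median pairwise distance, a tenth of the label variance) plus 5
  seeded random restarts by default.
* **Cross-validation.** Seeded shuffled k-fold (default 10),
  hyperparameters re-optimized per fold for an honest generalization
  estimate, scored by held-out R². Per-fold refits default to 2
  restarts — across a 10-fold loop the multi-start rarely changes the
  optimum but multiplies the cost. Folds whose held-out labels have
  zero variance have undefined R²; they are reported as missing,
  flagged, and excluded from the mean. Fixed-hyperparameter CV is also
  supported, since either convention may be wanted when comparing runs.

Ranking is greedy exploitation: descending predictive mean, ties broken
lexicographically by variant name for full determinism. Acquisition
supplements the top n with uniformly drawn exploratory picks from the
remainder (seeded), labelled by provenance. Acquisition functions that
balance exploration and exploitation through the predictive variance
are deliberately out of scope.

## Library design

Degenerate codons expand by per-position IUPAC degeneracy and translate
under the standard genetic code (via biopython's codon table). The
22-codon trick mixes NDT/VHG/TGG at 12:9:1 — proportional to the pools'
codon counts, which makes all 22 concrete codons equiprobable and
residue probabilities uniform up to the leucine/valine duplication; the
ratio is user-overridable.

Expected coverage uses the independent-draws model: after T
transformants a variant with per-draw probability p is seen with
probability 1 − (1−p)^T, and coverage is the mean over the design
space. This is the standard oversampling approximation (validated
against Monte Carlo in the tests to within 1%); the exact multivariate
occupancy distribution is not implemented. Parent or off-target
contamination enters only through probabilities summing to less than 1.

Filtered libraries enumerate the Cartesian product of per-site allowed
residues (sites ascending, residues in declared alphabet order — a
reproducible plate map), appending the design's fixed substitutions to
every member. A residue choice equal to the wild type contributes no
substitution but still counts as a distinct member. The worked
75-member example uses a 5 × 5 × 3 split across the three modulated
sites with two fixed positions; the split is illustrative.

## Kinetics

Apparent Michaelis–Menten parameters are fit by unweighted nonlinear
least squares (scipy's Levenberg–Marquardt/TRF machinery) with
initialization k_cat⁰ = max rate / [E] and K_M⁰ at the interpolated
half-maximal substrate, followed by a ladder of perturbed starts
(×0.3/×3, ×3/×0.3, ×10, ×0.1) on non-convergence; persistent failure
returns a flagged result instead of raising. Standard errors come from
the curvature (covariance) at the optimum. Relative-error weighting is
available but off by default, as unweighted fitting is the common
plate-kinetics convention.

The saturation flag marks fits whose largest substrate concentration is
below 2·K_M — beyond that the plateau was genuinely probed; below it,
k_cat and K_M are strongly correlated and the "apparent" caveat is
load-bearing. Catalytic efficiency is reported as k_cat/K_M in
min⁻¹·mM⁻¹.

Defaults surfaced in reports rather than hidden: NADPH molar
absorptivity 6220 L·mol⁻¹·cm⁻¹ at 340 nm and a 0.56 cm path length for
a 200 µl microplate well (Beer–Lambert conversion from ΔA·min⁻¹ to
molar rates). Datasets are pooled before fitting by default;
per-replicate fitting with averaging can be composed from the same
primitives.

## Synthetic generators

The landscape model is parent-anchored: activity = intercept + additive
per-site effects (parent residue fixed at 0) + sparse pairwise
interaction terms restricted to non-parent residues at both sites, so
parent and single-substitution variants are unaffected by epistasis
terms and the parent's true activity is exactly the intercept.
`epistasis_fraction` sets the proportion of enumerable cross-site
residue pairs that receive a term; interaction effects default to half
the main-effect scale, reflecting that epistatic contributions in
saturation-mutagenesis data are typically weaker than main effects.

Two additive-effect models are provided. "Free" draws i.i.d. normal
effects per residue — the general case, but one a
physicochemical-descriptor GP has no reason to extrapolate well on.
"Descriptor-linear" makes each site's effects a random linear
functional of the standardized descriptor vectors, so the true activity
is an exactly linear function of the encoding; this is the regime the
model class assumes, and it is what the model-performance benchmarks
use. The null benchmark (flat landscape, pure noise) bounds spurious
skill from the other side.

Simulated screens draw a multiplicative log-normal batch factor per
plate — normalizing per-plate by parent controls implies a
multiplicative nuisance, and log-normal keeps it positive and exactly
removable — and assign each well
slope = plate_factor · max(activity + noise, 0) · slope_scale, clipping
at zero because an inactive enzyme cannot un-consume cofactor. The
default slope scale of 0.008 ΔA·min⁻¹ per activity unit puts parent
wells near typical plate-reader slopes. Traces decline linearly from an
initial absorbance (default 1.0 AU) until a configurable absorbance
budget (default 1.0 AU, the simulated cofactor supply) is exhausted,
then floor — reproducing the linear-range problem the slope estimator
exists to solve. Four parent-control wells per 96-well plate is the
default control layout; real screens vary, and the value is a flagged
configuration choice, not data-derived.

Michaelis–Menten datasets use a default 8-point log-spaced substrate
grid from K_M/10 to 10·K_M (a standard identifiable design) with
relative Gaussian noise.

**What the generators do not emulate:** expression-level variation,
inactive-protein and mis-folding artefacts, sequencing errors in
variant identity, well-position (edge) effects, substrate or product
inhibition, and the two-substrate kinetics of the coupled cofactor
recycling system. Passing benchmarks therefore demonstrate the
correctness and statistical behaviour of the pipeline under its own
model assumptions, not predictive performance on any particular
laboratory dataset — held-out R² on real campaign data depends on the
true landscape's epistasis and noise, which only real data can supply.

## Benchmark problem sizes

The model-performance suite runs at sizes chosen to exercise the
statistics while keeping the full test run in the minutes range:
noiseless-landscape CV at n = 200 with 10 folds; null-landscape CV
averaged over 20 seeds; ranking enrichment over 50 replicate campaigns
with 500 training variants and 2000-candidate pools; Michaelis–Menten
recovery over 200 replicates; expected-coverage validation against a
100,000-experiment Monte Carlo.
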