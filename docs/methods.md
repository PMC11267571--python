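# Methods

## Data model and preprocessing

A `RamanSpectrumSet` couples an `n_spectra × n_wavenumbers` intensity matrix
with a strictly increasing wavenumber axis (cm⁻¹) and per-spectrum metadata
(class label, cell line, replicate, cell id). Every filtering or restriction
operation preserves row order and subsets metadata in lockstep, which makes
splits reproducible. Failed measurements are defined as spectra that are
*exactly* zero in every channel — no tolerance, since real failures record
literal zeros. Analyses of measured cell spectra restrict to the 320–1800
cm⁻¹ fingerprint region, which carries most biochemical contrast.

Baselines are estimated by asymmetric least squares: minimize
Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)² with the asymmetric weight update wᵢ = p if
yᵢ > zᵢ else 1−p, starting from uniform weights. Defaults λ = 10⁶, p = 0.1,
10 iterations — the values standard in the Raman literature. Each iterate is
a sparse banded solve; the tests cross-check it against an independent dense
solve. The ALS operator is shift-equivariant (baseline(y+c) = baseline(y)+c)
and positively homogeneous, which makes the subsequent sum normalization
scale-invariant. A baseline-corrected spectrum whose intensities sum to ≤ 0
cannot be sum-normalized; set-level preprocessing excludes such spectra with
a warning.

"Largest variability across cell types" for feature selection is defined as
the variance of the per-class mean intensity (between-class variance), not
the pooled variance: the quantity contrasts classes, which is what matters
for choosing discriminative wavenumbers. Ties break toward the lower index.
Binning uses equal *index-count* intervals with the remainder assigned to
the leading bins; on a uniform grid this coincides with equal cm⁻¹ spans and
it remains well defined on non-uniform grids.

## The filter network

Architecture: input (K) → dense N, **no bias**, ReLU → normalization layer
(γ init 1, β init 0) → dense 10, ReLU → dense C, softmax. Hidden layers are
He-uniform initialized, the output layer Glorot-uniform. Plain SGD, sparse
categorical cross-entropy; no input normalization of any kind, because in
deployment the inputs are raw detector counts.

The first layer is built without a bias deliberately: its pre-activation
h_i = w_i·s is then *exactly* the compressive measurement, so a detector
reading can replace it with no correction term, and the extracted 0/1
filter bank satisfies (B·s)·c = W₁ᵀs identically.

Constraints are projections applied after every SGD update:

* **non-negativity** — elementwise max(w, 0);
* **binarity** — with m the mean of all kernel entries, H = {w > m} and
  c = mean(H): entries above c/2 become c, the rest 0.

Training directly with the binarity projection fails in practice, so
training is two-stage: 200 epochs non-negative at learning rate 0.01, then
the weights seed an identical network trained 200 further epochs at 0.001
under the binarity projection (defaults; the simulated-spectra preset uses
N = 3 units, 20 epochs, batch 128, and measured-spectra runs use batch 16).
The binarity rule is applied to the whole kernel at once by default; a
per-filter variant is available (`binarize_per_filter=True`). The rule has
one degenerate corner: a kernel whose entries all exceed c/2 maps to a
constant matrix, which the next application zeroes. Trained kernels, which
always carry a spread of small weights, never enter this regime; the tests
document the chain explicitly rather than hiding it.

Normalization: layer norm standardizes each sample across its N filter
outputs (so predictions are invariant to a global positive rescaling of the
measurements, up to the ε = 10⁻³ variance guard); batch norm standardizes
each filter output across the batch and carries exponential-moving-average
running statistics (momentum 0.99) for inference. Layer norm is the
recommended setting — scale invariance is exactly what raw per-cell
intensity variation requires.

Model selection mirrors how the accuracy numbers are reported: for each of
5 stratified 80/20 train-test splits, 3 candidates are trained, each holding
out its own randomly drawn 20% validation subset of the training pool
(different split seeds — "bootstrapped" validation sets); the best
validation accuracy picks the candidate evaluated once on the test set.

The network is implemented directly in numpy (forward, backprop through
both normalization variants, SGD, projections); at these sizes (≤ 443 × 50
kernels, thousands of spectra) this is fast and keeps the dependency
surface minimal.

## Photon-noise simulator

Reference spectra: K = 50 channels drawn i.i.d. from a unit-mean
exponential, raised to α = 3 (sharpens peaks: mass concentrates in few
channels) and sum-normalized. M class spectra with controllable correlation
come from convex mixing with a common spectrum, s_j = (1−β)r_j + βr_common —
the unique affine form with the right limits (β = 0 independent, β = 1
identical), and convexity preserves normalization so no renormalization
question arises. Photon counting distributes N_phot photons multinomially
over channels; filter-level counting uses probabilities p_ij = μ_ij/Σμ_ij
with μ_ij = F_i·s_j the optical efficiency. Because a sum of multinomial
coordinates is again multinomial, introducing noise before or after a
disjoint filter bank is distribution-identical — verified by exact
enumeration in the tests.

## Bhattacharyya bound and MLC

The multiclass bound is the pairwise union form Σ_{j<j'} √(P_j P_j')·ρ_jj',
which reduces to (1/M)Σρ under equal priors. For multinomials with a shared
trial count the pairwise coefficient factorizes to
(Σ_i √(p_ij p_ij'))^N_phot; for Gaussians ρ = exp(−B) with
B = ⅛ dᵀΣ̄⁻¹d + ½ ln(det Σ̄ / √(det Σ_j det Σ_j')), Σ̄ the average
covariance. Gaussian class statistics are the per-class sample means and
covariances of the filter outputs with an unconditional relative ridge
ε = 10⁻⁸·trace(Σ)/N on the diagonal; priors are class frequencies.

Classification is pure maximum likelihood (argmax of the class-conditional
density; ties to the lowest class index). A prior-weighted MAP variant is
available behind a flag, but the default matches the estimator the bound
addresses.

The swap optimizer initializes each filter with round(K/3) ones and
proposes within-filter 0↔1 exchanges, accepting only strict decreases of
the bound — per-filter element counts are invariant by construction, and
orthogonality between filters is *not* enforced. Stopping: 50·N·K
consecutive rejections or 500·N·K total proposals, whichever first; the
walk is greedy and converges quickly on all tested problems (the tests
include an exhaustive-search optimality check at small K). Note the
distinction between a filter's *element fraction* (1/3 here) and its
intensity-weighted *optical efficiency* μ: on sharply peaked (α = 3)
spectra the two can differ by orders of magnitude, so both are reported by
`FilterBank`.

## Synthetic cell fixture

The fixture emulates the structure of public single-cell Raman deposits
without shipping any data: 3 classes × 3 cell lines × 3 replicates × 4
cells × 3 repeated measurements (324 spectra, 200 channels across 320–1800
cm⁻¹). All classes share a dominant 12-peak set and differ through ±25%
class-specific amplitude modulation plus two weak class-exclusive peaks —
giving class-mean correlations around 0.97, the moderate-overlap regime
real cell types occupy. Nuisances: a smooth per-cell additive baseline
comparable in integrated intensity to the peaks, lognormal per-cell
intensity scaling (σ = 0.35, ≈ 2-fold spread), optional multiplicative
smooth spectral tilts per cell line/replicate (off by default; switched on
for batch-effect stress tests), and Poisson counting noise at ≈ 2·10⁴
expected counts per spectrum. Cell ids are nested within replicates, so
grouped splits never leak repeated measurements of one cell.

What the fixture does *not* emulate: cosmic-ray spikes, detector
read noise/etalonning, wavenumber miscalibration between batches, and the
long-tailed heterogeneity of real cell populations. Passing tests therefore
demonstrate the correctness and the qualitative behaviour of the method
(filters beat raw-spectrum SVM at matched splits, batch effects degrade
held-out-line accuracy), not a performance guarantee on any particular real
data set.

## Problem sizes and numerical choices

The scripted experiments run at desk scale: the simulation study uses 2000
samples per species at N_phot = 100 and the fixture experiments use the
324-spectrum fixture with the full 200+200-epoch schedule — sizes chosen so
the whole suite and the acceptance script each run in well under a minute
on one CPU while keeping every Monte-Carlo margin (binomial σ) explicit in
the assertions. Softmax is computed with max subtraction; log-likelihoods
use slogdet and linear solves rather than inverses; multinomial
log-likelihood treats 0·log 0 as 0. Training aborts with a diagnostic on
non-finite loss rather than continuing silently.

## Known limitations

* Bit-for-bit reproducibility of training holds for a fixed seed on a given
  BLAS; across BLAS builds results are statistically, not bitwise,
  reproducible.
* The printed closed forms of the bound assume the pairwise-union multiclass
  combination; other multiclass Bhattacharyya variants differ by constant
  factors.
* The Gaussian route estimates covariances from filter outputs, so with
  very few spectra per class (< N+1) it refuses rather than regularizing
  aggressively.
* The binarity projection's degenerate corner (uniformly high kernels) is
  documented above; it does not arise in training but callers projecting
  arbitrary matrices should be aware of it.
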