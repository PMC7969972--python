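# Methods

## Scope

`drsix` is a self-contained simulation benchmark: it generates six-channel
diffuse reflectance data from a Monte Carlo forward model of skin-like
tissue, and compares trained regression models against the classical
lookup-table inverse for recovering the five physiological parameters that
generated the data. Everything is seeded; no external data are read.

## Photon transport and the lookup table

The medium is a homogeneous semi-infinite half-space (refractive index 1.40
under a 1.45 probe face). Photon packets launch uniformly over the source
fiber face into the fiber's acceptance cone, propagate with exponential
step lengths at the transport scattering coefficient μs = μs′/(1−g),
scatter by Henyey–Greenstein sampling (g = 0.9 by default), and lose weight
by implicit capture (factor μs/μt per interaction) with Russian roulette
(threshold 10⁻⁴, survival 0.1). At the surface the packet weight splits by
the unpolarised Fresnel coefficients; the transmitted part is scored if the
exit lies in the detector footprint within the fiber NA, the reflected part
continues. Scoring uses azimuthal ring averaging: an exit at surface radius
r contributes the analytic arc fraction of the circle of radius r inside
the detector face, which is unbiased under the source's azimuthal symmetry
and substantially reduces variance for a 40-µm-wide detection annulus.
Specular reflection at launch is excluded (packets start below the
surface), so the tallied quantity is diffuse reflectance per launched
packet.

Packets are terminated when they dive deeper than ~10 transport mean free
paths (bounded to [0.2, 2] cm). At that depth a returning packet is spread
laterally over centimetres and cannot meaningfully reach the sub-millimetre
detection annulus, so the truncation bias is far below the per-node Monte
Carlo error; the terminated weight is tracked, not silently dropped. A
`deep_boundary="mirror"` option replaces termination by specular reflection
at that depth — physically a bounded non-absorbing slab — which is used by
the energy-conservation oracle in the test suite: with μa = 0, a matched
boundary and a whole-surface detector, every packet must exit and the
tallied weight must equal unity exactly.

The 40×40 lookup table (LUT) spans 0–99.84 cm⁻¹ in both μa and μs′ at the
2.56 cm⁻¹ step. The default builder runs one absorption-free simulation per
μs′ column, records the path length of every detection event, and forms
each node of the column as Σᵢ wᵢ·exp(−μa·Lᵢ)/N ("white" or scaled Monte
Carlo). This shares every packet across the whole absorption axis (40×
cheaper than per-node simulation), is exactly non-increasing in μa, and
reports a per-node standard error from the per-packet contribution
variance. All columns reuse one random stream (common random numbers), so
sampled paths scale smoothly with 1/μs and the reflectance surface varies
smoothly along the μs′ axis instead of carrying independent column jitter.
A `per_node` mode (one independent seeded simulation per node, the plain
detected-weight estimator) is retained and cross-checked against the scaled
mode and against a naive analog (non-weighted, binary-scored) simulator
kept in the test suite. μs′ = 0 columns are stored as zero without
simulation: without scattering nothing returns diffusely. Bilinear
interpolation answers continuous queries; out-of-grid queries raise rather
than extrapolate.

Probe geometry defaults: 200 µm-radius source fiber, 300 µm-radius
detector fiber, 750 µm center separation, NA 0.50. The separation and
aperture were chosen by an identifiability analysis, not by convention: at very short separations (≲300 µm) the sampled photon paths
are so short that the melanin channel signature becomes >99% collinear with
combinations of blood volume, scattering amplitude and scattering slope,
and no extractor can recover melanin. At 750–1000 µm — a standard
physiological DRS configuration — the orthogonal component of the melanin
signal is ~40× larger and all five parameters are recoverable. The
scattering exponent is the mirror case: a millimetre-scale collection fiber
at this separation mixes path lengths enough to erase the scattering-slope
signal, while a 300 µm fiber with a high-NA (0.5) acceptance keeps it and
stabilises the estimate across Monte Carlo realisations of the table. All
geometry fields are configurable; the benchmark's comparative conclusions are
relative to whichever LUT is built.

## Chromophore fixture

`drsix/data/chromophores_synthetic.tsv` holds the wavelength-resolved
absorption inputs on a 1 nm grid over 410–650 nm. It is a synthetic,
literature-shaped approximation (regenerable via
`scripts/build_chromophore_table.py`): smooth curves through the canonical
hemoglobin landmarks (oxy Soret peak near 414 nm, deoxy Soret near 430 nm,
oxy α/β peaks at 577/542 nm, deoxy 555 nm band, isosbestic crossings near
500 and 570 nm, deoxy ≫ oxy in the red), scaled to whole blood at 150 g/l
hemoglobin. An effective vessel-confinement (pigment packaging) factor for
5 µm-radius vessels is folded into the blood columns; this flattens the
otherwise enormous Soret-band absorption so that every parameter
combination of the factorial design stays inside the LUT axis range (worst
case μa ≈ 73 cm⁻¹), while preserving the Q-band structure that identifies
blood. Melanin follows a λ^−3.46 power law normalised to 3 cm⁻¹ per mg/ml
at 630 nm, within the literature range for eumelanin and strong enough that
melanin is a first-class absorber, as in real skin. The runtime model stays
strictly linear in BVF and Mel; the packaging is a property of the fixture
data, not of the code. Absolute coefficient values therefore differ from
any particular published compilation, which shifts absolute reflectance
levels but not the benchmark's comparative structure.

## Spectral synthesis

100 wavelengths evenly spaced over 410–650 nm; 1% multiplicative Gaussian
noise applied per wavelength before down-sampling (negative values floored
at zero — reflectance is physical); six Gaussian channel responsivities
centred at 450/500/550/570/600/650 nm with 40 nm FWHM (σ ≈ 17 nm),
truncated to the grid and renormalised to unit row sum, so down-sampling is
a convex weighted average. The noise amplitude is a package default (the
appropriate value for real hardware depends on the instrument); the 40 nm
bandwidth matches the datasheet bandwidth of the six-channel sensor class
this design emulates. The full factorial at 10 levels per parameter gives
100,000 rows; a seeded permutation takes 10,000 training rows and 30,000
disjoint test rows (reduced designs scale these proportionally and record
it in metadata).

## Extractors

One regressor per parameter in all families, all trained on the same
10,000-row split and evaluated on the same 30,000-row split:

- **DL** — feed-forward network, two hidden layers of 200 rectifier units,
  exactly 10 epochs of Adam (batch 32, initial step 10⁻³), features and
  targets standardised on the training split. The optimizer settings were
  chosen, within the fixed architecture and epoch budget, for stable
  training: more aggressive step/batch settings fit marginally better on
  average but occasionally generalise catastrophically worse for the
  scattering exponent, the weakest-signal parameter.
- **RF** — 50 trees, depth ≤ 20, exact splits (the 20-bin histogram
  hyperparameter is recorded for parity with histogram-based forests but
  has no exact-split analogue).
- **GBM** — histogram gradient boosting, 50 trees, depth 5, 20 bins,
  learning rate 0.1.
- **GLM** — ordinary least squares on standardised features
  (identity-link Gaussian model).

Predictions are raw model outputs, deliberately not clipped to the
physiological bounds, so error metrics are not silently truncated near
range edges.

The **MCLUT inverse** minimises Σ(measured − model)² over the five
parameters within their physiological bounds. In its classical
`point_sample` form the model spectrum is the LUT forward value at the six
channel-center wavelengths — it ignores the 40 nm channel bandwidths, which
is precisely why it degrades on band-averaged data; a `weighted` mode using
the full band-averaging operator is provided to quantify that mismatch.
Optimisation is multi-start (mid-range start plus 4 seeded random in-bounds
starts) L-BFGS-B with numerical gradients, polished with bounded
Nelder–Mead; the returned residual never exceeds the initial residual, and
absolute (unweighted) squared channel error is used.

## Evaluation

MAE and MAPE per model and parameter; MAPE excludes zero-truth rows (the
ratio is undefined; the melanin grid contains 0 mg/ml) and reports the
exclusion count. Crosstalk is the 5×5 Pearson matrix of true parameter i
vs extracted parameter j; in a balanced factorial the truth columns are
exactly orthogonal, so off-diagonal structure isolates extractor-induced
coupling. Head-to-head win rates (fraction of rows where one model's
absolute error is strictly smaller — ties count against) are tabulated per
true parameter level together with error-difference quantiles. Model pairs
are compared by paired bootstrap: rows are resampled with replacement and
the MAE difference recomputed (default 1000 replicates, seeded, 95%
percentile intervals). A mixed-effects significance analysis was considered
and rejected because it would require inventing a random-effects
specification; the paired bootstrap addresses the same substantive question
(which model's errors are smaller) without that choice. Wall-clock
benchmarks over seeded random batches (1/10/50/100 spectra, 50 trials) are
recorded for trend inspection only — absolute timings are
hardware-dependent and never asserted.

## Problem sizes and numerical choices

The packaged defaults run the whole study on one desktop CPU: LUT builds
use 10⁵–4×10⁵ packets per scattering column (the study-scale runs use
4×10⁵, building in ~10 minutes), and the iterative inverse — at ~0.2 s per
spectrum — is evaluated on a seeded subsample (default a few hundred rows)
of the 30,000-row test set rather than all of it. Because the same LUT
generates the data and serves the inverse model, LUT noise perturbs the
benchmark's forward map rather than adding estimator bias; the trained
models learn whichever map was built.

Numerical details: bilinear LUT interpolation makes the inverse objective
piecewise-smooth — multi-start plus a derivative-free polish absorbs the
cell-boundary kinks; optimizer tolerances are 10⁻¹⁴ on the objective;
channel weights renormalise after grid truncation so edge channels (450,
650 nm) have slightly asymmetric effective passbands; the Monte Carlo
kernel uses an inline xorshift128+ generator seeded by splitmix64, so
results are bit-reproducible for a given seed independently of NumPy's
global state.

## What the generator does and does not emulate

The synthetic data reproduce the statistical structure of the target
study — factorial parameter coverage, band-averaged channels, multiplicative
noise — but not real-instrument effects (dark counts, integration-time
quantisation, wavelength calibration error, probe pressure), inter-subject
chromophore variability, or layered skin anatomy (a single homogeneous
layer carries both melanin and blood). Passing benchmarks here shows the
extraction pipeline is sound and that six channels carry enough information
under these assumptions; it does not certify accuracy on measured tissue
spectra.

## Known limitations

- The scattering exponent B is the least identifiable parameter from six
  channels in this design (percent errors ~10–13% where the other
  parameters reach 3–6%), and its trained-network error varies by a couple
  of percentage points across training seeds and LUT realisations.
- The linear model (GLM) is the weakest ML family and does not beat the
  iterative inverse on every parameter in every realisation — with these
  smoother packaged-blood spectra the point-sampling bias of the inverse
  model is milder than with unpackaged Soret bands, so the inverse is a
  stronger baseline here, while the nonlinear families still dominate it
  everywhere.
- Melanin percent errors exclude the zero-concentration truth level by
  construction of the metric.
- The chromophore fixture is an approximation; studies requiring absolute
  μa accuracy should swap in a measured compilation via
  `ChromophoreTable.from_tsv`.
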