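# Methods

This note documents the models implemented in `srmd`, the choices made
where the method's published description is open, and what the synthetic
test scenes do and do not establish.

## FVC inversion

NDVI is computed per reflectance snapshot and composited to the per-pixel
growing-season maximum, which suppresses clouds and off-peak phenology.
Cross-sensor harmonization is an OLS affine map fitted on paired NDVI
samples from overlapping scenes; maps compose, so a sensor without direct
overlap with the reference is harmonized through an intermediate sensor.
The coefficients are whatever the supplied pairs give — no fixed
coefficients are shipped.

The dichotomy model `FVC = (NDVI − NDVI_min)/(NDVI_max − NDVI_min)` is
**clipped to [0, 1]**: the formula exceeds the physical range when NDVI
falls outside the endpoints, and FVC is a fraction. Endpoints are read
from the cumulative distribution of NDVI over user-supplied pure-soil and
pure-vegetation pixels at the 5% / 95% cumulative-percentage points,
implemented as the **nearest-rank** (ceil(p·n)-th ascending) value rather
than an interpolated percentile — the reading consistent with a cumulative
count curve. Which pixels are "pure" is an input; the package does not
choose them.

## Driving factors

* Precipitation and temperature are single-station scalars per year
  (accumulated mm and mean °C over month windows ranked by |Pearson r|
  against an FVC summary; accumulation for rain, mean for temperature).
* Topography is the DEM, unchanged across years.
* Urban and mining activity follow `x = magnitude/(D + 1)` with
  `D` in **kilometres** (cells inside the source region get D = 0, so the
  intensity there equals the magnitude). Distances are centre-to-centre
  Euclidean in projected metres; polygons are rasterized by cell-centre
  membership first. Kilometres are the scale on which the method's
  disturbance distances are reported; a metre switch exists for
  sensitivity checks.
* Normalization is min–max to [0, 1]. Spatially varying factors (dem,
  urban, mine) are normalized over the pixels of each year; the spatially
  constant station scalars are normalized **across the study years**,
  since their within-year pixel range is zero. This is the only scope
  assignment under which every factor has a well-defined, non-degenerate
  normalization.
* For years with no mining, the mining factor is the **virtual** one: the
  latest mining year's boundary and production applied to the no-mining
  year. Stacks carry a `mining_is_virtual` flag and downstream code
  refuses to mix the two up.

## The network

Architecture: input layer of the 5 normalized factors for one pixel, one
tanh hidden layer (default width 16), and a tanh output layer with **one
neuron per anchor location**. During training every sample's squared error
at output neuron j is weighted by a Gaussian kernel
`D = exp(−d²/2b²)` of the distance between the sample's pixel and anchor
j. The kernel is distance-*decaying*; a raw distance weight would
up-weight far pixels, the opposite of geographic weighting. Prediction at
a pixel reads its nearest anchor's output neuron fed that pixel's own
drivers, clipped to [0, 1] for reporting (raw outputs are used inside the
attribution).

Choices the published description leaves open, and what this package does:

* **Bias terms** are included per neuron. Without them the
  spatially constant climate inputs would be inexpressible after
  normalization in some years.
* **Bandwidth** defaults to a quarter of the grid diagonal;
  config-exposed. No automatic bandwidth selection is provided.
* **Anchors** default to a regular stride subsample capped at 256 (the
  `anchor_budget`); output-layer width, and with it training cost, grows
  with the anchor count, and at desk scale the fit is indistinguishable
  from per-pixel anchors (noiseless training RMSE 0.008 against a 0.02
  oracle threshold).
* **Trainer**: full-batch gradient descent (one step per epoch from the
  mean per-sample gradient), η = 0.5, 200 epochs, stop early when the
  epoch-over-epoch error change falls below `tolerance`. These values come
  from a stability scan on noiseless linear scenes (η = 1.2 oscillates;
  η = 0.5 reaches RMSE 0.008 noiseless in 200 epochs). A per-sample
  online mode implementing the literal update `Δw = −η δ p` after every
  sample is config-selectable (`update_mode: online`) but roughly an
  order of magnitude slower.
* **Training scope** defaults to one model per year; a pooled mode trains
  one model on all years' samples. Per-year models cannot identify the
  coefficients of within-year-constant factors (climate); pooled training
  across years can, and the contribution-recovery tests use it for
  exactly that reason.
* Accuracy is RMSE and mean relative error (MRE) per year, with MRE
  computed over cells whose observed FVC ≥ 0.01 — the relative error
  diverges as the denominator approaches zero.

With all geographic weights set to 1 the trainer reduces *bit-identically*
to standard backpropagation; this, plus agreement of the analytic gradient
with central differences to 1e-6, are the core correctness oracles in the
test suite.

## Attribution, noise, significance

Each factor in turn is perturbed by the relative bias `ΔX = 0.001·X`
(cells where X = 0 receive an absolute floor of 1e-6, since a relative
bias of zero would leave the finite difference undefined), the trained
network is re-run, and `C_i = (Y_perturbed − Y)/ΔX` is the per-pixel
partial derivative. Halving the bias changes the contributions by well
under 1% on smooth fits (step-size robustness is tested).

**Share convention.** The shares are `W_i = |C_i| / Σ|C_k|` by default
(`share_convention: magnitude`), with the literal signed form
`C_i / ΣC_k` available (`signed`). The five derivatives generally have
mixed signs, so the signed denominator crosses zero and produces unbounded
shares — on synthetic scenes the pooled noise SD explodes by orders of
magnitude — whereas a one-sided test against a positive critical value,
and a positive noise mean, presuppose a positive share measure. Magnitude
shares are nonnegative, sum to 1 per cell, and on synthetic scenes yield
noise statistics of the same order as those reported for the method on
real data. Cells where the denominator's magnitude falls below 1e-9
become nodata rather than producing unbounded shares.

The noise model pools the virtual-contribution samples over **all**
no-mining years and pixels. The critical value is the **empirical**
(1 − α) cumulative-frequency point of the raw pooled samples —
bin-width-invariant, unlike reading it off a histogram — and the Gaussian
curve fitted to the histogram is kept purely as a normality diagnostic.
The significance test flags a pixel exactly when `W_mine > V_0.95`
(strict inequality; α = 0.05 by default). No multiplicity or
spatial-autocorrelation adjustment is applied: the method is a single
empirical-null threshold applied per pixel, and is replicated as such.

## Synthetic scenes

The generator emulates the study conditions the method targets: a
projected ~90 m grid (default 60×60, a 5.4 km square), ten no-mining
years plus one mining year, a semi-arid steppe FVC field

    FVC = clip₀¹( 0.55 + 0.35·X_pre − 0.15·X_temp − 0.10·X_dem
                  − 0.25·X_urban − A·exp(−D_M/λ) + ε ),  ε ~ N(0, σ)

built from the *pipeline's own* normalized drivers, so a perfectly
trained network has the generative coefficients as its partial
derivatives (the analytic attribution oracle). Coefficient signs follow
the emulated setting: precipitation helps vegetation; heat, elevation and
urban proximity suppress it. Defaults: σ = 0.05 FVC units (the scale of
the method's reported fit residuals on real data), suppression amplitude
A = 0.2 = 4σ at the mine with e-folding λ = 1 km. The ground-truth
disturbed region is defined as suppression > 2σ — an unambiguous, testable
convention; with the defaults its radius is λ·ln 2 ≈ 0.69 km beyond the
mine. Reflectance snapshots are synthesized so that the real
reflectance→NDVI→composite→FVC pipeline reproduces the generated FVC to
1e-6.

What the scenes do **not** emulate: radiative-transfer or phenological
realism, cloud/shadow artefacts, spatially correlated noise, multi-station
meteorology, and real-data spatial heterogeneity of the factor–FVC
relationship. Passing tests establish the machinery (fitting, attribution,
calibration, geometry) under known truth, not performance on real imagery.

## Known limitations

* **Detection reach vs. suppression truth at desk scale.** The
  attribution is a *derivative* measure: with the hyperbolic distance law
  inside the normalized mining driver, a perfectly learned network has
  `|C_mine| ∝ (A/λ)·e^{−D/λ}·(D+1)²`, which decays far more slowly than
  the suppression itself and stays above typical noise critical values
  across the whole 5.4 km default scene. The flagged region therefore
  extends well beyond the 2σ-suppression truth contour — on default
  disturbed scenes it covers essentially the grid (see
  `examples/04_attribution_and_srmd.py`). This is a property of
  derivative-based attribution at desk-scale extents, where every pixel
  is within the sensitivity reach of a 1 km decay; on much larger extents
  the far field genuinely decouples. Type-I error control is unaffected
  (the null pipeline flags ≈ α of pixels), but boundary-recovery
  expectations tied to the 2σ contour are not met at this scale.
* Per-year models leave within-year-constant factors unidentified; their
  derivatives are then arbitrary network sensitivities. The noise
  calibration absorbs this (the same arbitrariness is present in the
  virtual-contribution years), but per-factor interpretation of W for
  climate factors from a single year is not meaningful.
* Nodata handling is propagate-only; no gap-filling, reprojection,
  cloud masking or tiled rasters.
* The eight directional sectors are labelled by azimuth range
  (north-start, clockwise) — a package convention, since direction
  numbering is otherwise undefined.
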