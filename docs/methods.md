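# Methods

`tfmlab` quantifies the mechanics of cell–substrate adhesion from
time-lapse fluorescence microscopy of cells on compliant polyacrylamide
gels: traction forces from fiducial-bead displacements, actin retrograde
flow from lamellar texture motion, and focal adhesion (FA) dynamics from
paxillin movies. Every analysis stage is validated end to end against a
synthetic forward model whose ground truth is known exactly.

## Substrate mechanics

The gel is modelled as a linear-elastic, isotropic half space with shear
modulus G (default 2800 Pa, a 2.8 kPa polyacrylamide gel), Poisson ratio
ν (default 0.5, incompressible — standard for hydrated polyacrylamide;
only G is usually measured, so ν is configurable) and infinite
thickness. Surface displacement **u** and surface traction **t** are
related per wavevector k by the Boussinesq Green's tensor

    G(k) = 2(1+ν) / (E k³) · [[(1−ν)k² + ν k_y²,   −ν k_x k_y],
                              [−ν k_x k_y,   (1−ν)k² + ν k_x²]],

with E = 2G(1+ν). The forward model (`boussinesq_forward`) multiplies
the FFT of a prescribed traction map by G(k); the inverse
(`fttc_inverse`, Fourier-transform traction cytometry) solves the
Tikhonov-regularized normal equations t(k) = (GᵀG + λ′²I)⁻¹Gᵀu(k)
per wavevector. Both share one implementation of G(k), so the
forward–inverse pair is exact (≲1e−14 relative) on a common periodic
grid at λ = 0.

Numerical choices:

* **Padding.** Fields are zero-padded to ≥2× their extent
  (`pad_factor`, fast-FFT lengths) to suppress periodic images;
  accuracy against the aperiodic half-space solution is guaranteed on
  the interior ~50% of the domain (verified against direct real-space
  convolution of the Boussinesq kernel to <1%). `pad_factor=1` gives
  the exactly invertible periodic operator used in round-trip tests.
  Zero-padding a displacement field that is still nonzero at the crop
  boundary leaks stress into the reconstruction; the synthetic scenes
  therefore keep the cell small relative to the field of view, as real
  acquisitions do.
* **Zero frequency.** The k = 0 (rigid-body) mode of both operators is
  set to zero; force balance of the scene makes it physically empty.
* **λ convention.** λ is dimensionless: the value applied is
  λ′ = λ·s_max with s_max the largest singular value of G(k) over the
  grid, making λ comparable across grids and gels.
* **Choice of λ.** The classical L-curve corner (`select_lambda_lcurve`)
  is provided but degenerates on kriged displacement fields: kriging
  pre-smooths the data, the solution norm no longer diverges as λ → 0
  and the curve has no corner. The default is therefore Morozov's
  discrepancy principle (`select_lambda_discrepancy`): the smallest λ
  whose data residual matches the displacement noise, with the noise
  estimated robustly from the PIV vectors' neighbour-median residuals
  (MAD × 1.4826). Typical values on the synthetic suite are λ ≈ 0.02.

## Displacement estimation

Bead image pairs (strained vs. relaxed reference) are processed in four
stages.

1. **Drift alignment** — whole-image phase correlation; an ambiguous
   correlation peak (primary/secondary ratio below 1.1) warns and
   returns zero drift.
2. **MQD PIV** — block matching on a regular window grid (default 16 px
   windows, 50% overlap, ±8 px search): the integer shift minimizing
   the mean squared intensity difference, refined by a guarded
   three-point parabola per axis (offsets bounded to ±0.5 px; an exact
   zero minimum is never "refined"). Window quality is the ratio of the
   second-lowest to lowest local minimum of the MQD surface; textureless
   windows are flagged invalid. With ~5 beads per window
   (2 beads/µm² at 16 px = 1.6 µm windows) the per-vector noise is
   ≈0.05 px.
3. **Outlier filtering** — the normalized-median test (threshold 2.0,
   ε = 0.1 px) over the 8 grid neighbours plus the quality threshold;
   more than 50% invalid vectors is an error.
4. **Kriging** — each component is interpolated onto a regular physical
   grid (default 0.86 µm spacing) by ordinary kriging with an
   exponential variogram fit by least squares to the empirical
   variogram, nugget 0 (exact interpolation at samples). The grid is
   inset from the image border (default 2 µm) because PIV cannot measure
   inside the window margin and kriging should not extrapolate.
   `pykrige` is not part of the supported environment, so the
   dual-kriging solve is implemented directly (a dense LU factorization;
   fine up to ~10⁴ vectors).

## Traction-derived quantities

* **Total force** — the background level is the mean stress magnitude
  over a region outside the cell (by default the field's corner squares,
  which on both synthetic and published data sit near 20 Pa), and the
  total force is Σ max(|t| − background, 0) × cell area over the cell
  outline dilated by 6 µm (so edge-adhesion footprints are counted),
  in nN (1 Pa·µm² = 10⁻³ nN). Background subtraction makes the
  estimate conservative: on synthetic truth the full chain recovers
  ~90% of the prescribed total.
* **Per-adhesion stress** — Gaussian-weighted mean of |t| at the
  adhesion centre (weights renormalized at boundaries) plus the peak |t|
  within 2σ; the peak × the stress-footprint area gives the adhesion
  force. The footprint is the connected half-maximum region around the
  adhesion (the area is analytic for a Gaussian spot, π(σ√(2 ln 2))²,
  used as the oracle); a region covering more than a quarter of the
  domain is rejected as non-localized.

## Actin retrograde flow

Texture features (local maxima above a per-tile 50th-percentile floor,
non-maximum-suppressed) are tracked by normalized cross-correlation of a
1.6 µm template against the average of the next 3 frames. The temporal
average lags the current frame by (N+1)/2 frames and measured
displacements are divided by that effective lag — time integration
suppresses photon noise without biasing the speed (recovery is unbiased
to <1% over 0.1–0.6 µm/min at SNR 10). Region means are taken only over
tiles whose vectors are directionally coherent (mean resultant length
≥ 0.7, ≥ 10 vectors), an automated stand-in for the manual selection of
coherent lamellar regions; a manual region-label override is accepted.

## Focal adhesion dynamics

* **Length** — adhesions are segmented by Otsu thresholding in a ±3 µm
  window around a seed point (enlarged automatically when the object
  touches the window edge). The length is the major-axis FWHM computed
  from truncation-corrected intensity moments of the
  background-subtracted blob: for a Gaussian profile cut at q× peak the
  per-axis variance is σ²[1 − (1 − ln q)q]/(1 − q), so the estimate is
  sub-pixel and unbiased for the Gaussian-shaped synthetic adhesions
  (measured bias +2–3% over 0.5–6 µm, within the ±10% target). Windows
  whose object does not stand 4 robust SDs above the local background
  record a gap. A CSV import path (`read_manual_annotations`) provides
  parity with hand measurement.
* **Linking** — gaps ≤ 2 frames are linearly interpolated, longer gaps
  split the track, tracks shorter than 3 frames are dropped. The
  lifetime is the total time present (frame count × interval); tracks
  touching the first or last movie frame are censored and excluded from
  lifetime means by default (a flag includes them; both estimates are
  reported).
* **Phase rates** — length vs. time is fit by continuous
  piecewise-linear least squares with 0, 1 or 2 breakpoints (chosen by
  BIC; breakpoints searched on ≤25 quantile candidates). The growth
  phase is the steepest-positive segment (elongation rate), the
  disassembly phase the steepest-negative (disassembly rate, reported
  as a positive µm/min — the natural per-time reading of "change in
  length during disassembly"). The loading rate is the stress slope over
  the growth window with 10% trimmed from each end: breakpoint error
  that lets the window overhang the stress plateau only ever biases the
  slope low, and trimming removes that asymmetric bias (observed ~10%
  before the fix). Stability: lifetime > 30 min ⇒ "stable".

## Synthetic data: what it emulates, and what it does not

The generators state the wild-type world of the source measurements:
2.8 kPa gel; ~250 nN total traction per control cell; lamellar flow at
0.3 µm/min imaged every 30 s for 30 min; FA elongation 0.15 µm/min,
loading 25 Pa/min, lifetime 55 min. ROCK-inhibitor (Y-27632) presets
keep the elongation rate and flow speed (tension-insensitive) while
reducing loading rate (7 / 5 / ~1 Pa/min at 2 / 5 / 10 µM), lifetime
(30 / 25 / 10 min) and total force (90 / 60 / 25 nN); at 10 µM flow is
essentially abrogated (0.05 µm/min). Histogram shapes are only described
qualitatively in the source, so rates and lifetimes are log-normal with
a common coefficient of variation 0.3 (positive support, unimodal).
Where the rendering itself needed parameters that no paper states:
beads are 2/µm² Gaussian spots of σ 0.15 µm with additive noise sd 0.05
(SNR 20); traction scenes place 32 elliptical foci (σ 2.0 × 1.0 µm,
log-normal peak jitter cv 0.25) in exactly balanced diametric pairs on a
14 × 10 µm cell ellipse inside a 60 × 60 µm field; adhesions are
anisotropic Gaussians (minor σ 0.17 µm) whose major-axis FWHM *defines*
the ground-truth length; FA kinetics are piecewise linear
(30% growth / plateau / shrinkage capped so the length never falls below
the nascent-punctum size).

A green synthetic-recovery test therefore establishes that the
estimators are unbiased for smooth elastic fields, rigid texture
motion, isolated Gaussian adhesions and piecewise-linear kinetics at
the stated noise levels. It does not establish robustness to real-data
features the generator omits: bead polydispersity and focal drift,
substrate nonlinearity or finite thickness, flow-field divergence and
speckle turnover, adhesion splitting/merging or non-Gaussian shapes,
and segmentation on crowded fields.

## Known limitations

* The half-space assumption ignores finite gel thickness; tractions on
  thin gels are underestimated.
* Total-force recovery is conservative (~−10% on synthetic truth):
  background subtraction removes genuine signal equal to the background
  times the mask area, and spectral leakage from the finite field of
  view sets the background floor (~20 Pa at the default scene — the
  same order as reported experimental backgrounds).
* At the strongest inhibition preset (10 µM Y-27632) the total length
  change of an adhesion is comparable to the measurement noise;
  growth-phase rates are not statistically identifiable there and only
  lifetimes are asserted.
* PIV assumes locally rigid motion per window; no iterative window
  deformation or multi-grid refinement is implemented.
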