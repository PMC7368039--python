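# Models and methods

This note documents the models implemented in `hsafm_spt`, the defaults and
why they were chosen, the numerical decisions, and the limits of what the
synthetic-data tests can show about real HS-AFM data.

## Coordinate and unit conventions

Images are `(frame, row, col)` height maps in nm above the bilayer plane
(bilayer = 0). The image origin is the top-left pixel center; x = column,
y = row; pixel centers sit at integer pixel coordinates and physical
position = pixel × (field_size / n_pixels). Times are frame_index ×
frame_interval. All internal arithmetic runs in nm and s; diffusion
coefficients are reported in µm²/s (1 µm² = 10⁶ nm²), so a fitted MSD slope
of 4 nm²/s is exactly D = 10⁻⁶ µm²/s.

## Synthetic movie generator

The generator emulates the imaging regime the analysis targets: a
200×200 nm supported-bilayer field scanned at 128×128 pixels and 0.2–0.5 s
per frame, containing ~2.9 nm-high mobile bumps with D in the
10⁻⁴–10⁻³ µm²/s range, tilt excursions within 0–25° and free in-plane
azimuth drift.

- **Lateral motion** — independent Gaussian steps of per-axis variance
  2·D·Δt plus drift·Δt, specular reflection at the field edges. A particle
  must stay in frame to be rendered, and reflection is the simplest
  boundary that guarantees it; see "Field-of-view confinement" below for
  the statistical price.
- **Tilt** — an Ornstein–Uhlenbeck process (exact discrete update) with
  mean at the interval midpoint, stationary sd `theta_sd_deg` (default 5°)
  and correlation time `relaxation_time_s` (default 2 s), reflected into
  [θ_min, θ_max] = [0°, 25°]. The data motivating the package show a
  bounded, fluctuating tilt trace but no dynamical model; a reflected OU
  process is the simplest bounded mean-reverting choice. With the default
  bounds at ±2.5 sd the reflection barely distorts the stationary spread.
- **Azimuth** — angular Brownian motion with diffusivity
  `orientation_D_deg2_s` (default 20 deg²/s, i.e. per-frame steps of a few
  degrees at 0.5 s — slow rotation on the imaging timescale), stored
  modulo 180° because the rod's image is unsigned.
- **Apparent height** — the rigid-rod relation h(θ) = L·cosθ − T_b − T_w
  with L = 8 nm, T_b = 4.1 nm, T_w = 1 nm by default, giving the 2.9 nm
  upright bump height.
- **Rendering** — two bump models. The default `gaussian` renderer draws an
  anisotropic Gaussian of amplitude h, minor sd `gaussian_sigma_nm`
  (default 2.5 nm, about the tip-convolved footprint of a 1.5 nm-wide rod
  under a 5 nm tip) and major axis along the azimuth, elongated by
  `aspect_gain` (default 2% per degree of tilt, i.e. aspect ratio 1.5 at
  25°). The `cylinder_dilation` renderer builds the tilted-capsule height
  field (union of spheres along the protruding axis) and applies grayscale
  dilation with a spherical tip of `tip_radius_nm` (default 5 nm, required
  < 10 nm) — the standard tip–sample dilation model. Overlapping bumps
  combine by maximum (AFM measures topography, not density). Pixel noise is
  additive Gaussian, default sd 0.29 nm (SNR 10 against the 2.9 nm bump).
- **Scanner drift** — optionally a global per-frame translation applied at
  render time; richer drift models, raster-line skew within a frame
  (config flag reserved), tip–sample mechanics and lipid-phase texture are
  deliberately out of scope.
- **Reproducibility** — one master seed; per-particle streams and the pixel
  noise stream are spawned from it deterministically, so identical configs
  produce bit-identical movies.

## Tracking

- **Drift correction** operates by subpixel phase cross-correlation
  (plain, un-whitened correlation: the whitened variant is far noisier on
  these low-feature images). Two drift models: `cumulative` chains
  consecutive-frame estimates, which is faithful to common practice but
  accumulates per-step noise (~0.4 px on a sparse scene) into several
  pixels over hundreds of frames and can partially "track" a mobile
  particle; the default `linear` registers every frame against the first
  and extracts a constant drift velocity with a per-axis Theil–Sen fit —
  appropriate because mechanical drift is smooth on the movie timescale
  (and the generator's drift is exactly linear), and robust to the mobile
  particle contaminating individual estimates. Registration needs static
  scene features (defects, immobile particles); on a featureless field
  with a single mobile bump *any* registration scheme locks onto the
  particle itself.
- **Detection** proposes candidates by Laplacian-of-Gaussian blob detection
  over a 2–6 nm sigma range on the median-background-subtracted frame
  (per-frame median, not a plane fit — the bilayer is flat at this field
  size), keeps peaks at least `min_height_nm` (default 1.5 nm) above
  background, and refines position and peak height with an elliptical 2-D
  Gaussian fit (fallback: height-weighted centroid). The Gaussian refinement
  matters for the tilt readout: the raw maximum-pixel height is biased low
  by up to ~0.3 nm depending on subpixel position, which the arccos
  inversion would amplify to many degrees near upright.
- **Linking** is greedy nearest-neighbour per frame pair, smallest distance
  first with ties broken by lowest track id, gate radius `max_step_nm`
  (default 3·√(4·D_max·Δt) with D_max = 10⁻³ µm²/s, ≈134 nm at 0.5 s), gap
  closing up to `max_gap_frames` with the gate scaled by √(gap+1), and
  tracks shorter than `min_track_length` (default 10, enough for a
  first-third fit on ≥3 lags) discarded. At the particle densities of
  interest (a few bumps per field) this is adequate; multi-hypothesis/LAP
  linking is out of scope. Externally curated tracks enter through the
  TrackMate-style CSV reader instead.

## Diffusion analysis

- **MSD** is time-averaged with overlapping pairs (the standard
  msdanalyzer-style estimator); pairs spanning detection gaps are excluded
  and per-lag pair counts are kept for optional weighting.
- **Fits** use the first ⌊N_lags/3⌋ lags (minimum 2; curves with fewer than
  6 lags are rejected). Brownian: MSD = 4·D·lag + b; directed:
  MSD = 4·D·lag + (v·lag)² + b. Both are solved by bounded linear least
  squares (D ≥ 0, v² ≥ 0, intercept free by default with a config switch to
  force zero; unweighted by default, `weights="n_pairs"` available).
  Solving the constrained problem directly — rather than clamping an
  unconstrained fit — makes the Brownian model exactly nested in the
  directed one, so RSS(directed) ≤ RSS(brownian) holds structurally.
  Whether the original analyses included an intercept is not documented;
  the free intercept is the safer default because localisation noise adds a
  positive offset. MSDs are fitted in-plane (2-D, prefactor 4) everywhere,
  including centre-of-mass series from simulations.
- **Single-track precision.** With the fit window a fixed *fraction* of the
  track, the relative sd of a single-track D̂ is O(1) — about 50% — and
  does *not* shrink with track length (long-lag MSD points are averages of
  few effective pairs). Reliable D values therefore come from ensembles;
  the package's recovery checks use means over ≥20 tracks.
- **Field-of-view confinement.** A particle kept inside a 200 nm field
  cannot follow free-diffusion statistics: the in-plane MSD saturates near
  L²/3 ≈ 1.3×10⁴ nm², and at D = 10⁻⁴ µm²/s a first-third window of a
  300-frame movie already reaches lags where this depresses the fitted
  slope by >50%. This is a property of the measurement geometry, not of the
  estimator; estimator-validation simulations therefore use an effectively
  unbounded field, while end-to-end image tests accept the confinement bias
  as part of what they measure.
- **Ensembles** are summarised by the MLE log-normal fit to ln D (zero or
  negative fitted D excluded and counted), with the arithmetic mean as the
  headline per-composition average (that is the quantity customarily
  plotted) and the geometric mean exp(μ_log) reported alongside. The
  composition trend is the sign of the Spearman rank correlation between
  mean D and DMPC fraction; fewer than two compositions give "none".
- **Periodic boundaries.** Centre-of-mass series from periodic boxes are
  unwrapped by minimal-image displacement mapping into (−box/2, box/2],
  with a displacement of exactly half the box resolved to +box/2
  (documented convention), then cumulatively summed.

## Tilt and rotation

- The tilt formula is the unique relation consistent with the stacked
  water-layer/bilayer geometry and the convention that L is set by the
  maximum bump height (maximum height = upright rod):
  θ = arccos((h + T_b + T_w)/L). Heights overshooting the upright value —
  inevitable under measurement noise — clamp to θ = 0 with a flag rather
  than erroring; heights below the bilayer by more than T_b + T_w have no
  geometric solution and raise. Near θ = 0 the inversion has square-root
  sensitivity (dθ ∝ √dh), so per-frame tilt values of nearly upright
  particles are noisy even at SNR 10; averaging heights before inversion
  (as the validation tests do) is the robust readout. L may alternatively
  be calibrated from a high quantile (e.g. 99th percentile) of the height
  series to reject outliers.
- Apparent height is measured peak-to-per-frame-median-background; whether
  the original measurements used a fitted baseline instead is not
  documented.
- Orientation comes from the height-weighted second-moment tensor of a
  window around the detection (background = median of the window border,
  negative residuals clipped); φ = principal-axis direction in [0°, 180°),
  asymmetry ratio √(λ_major/λ_minor). Ratios below `min_asymmetry`
  (default 1.15) leave φ undefined — a near-circular bump carries no
  orientation signal.
- Rotation steps are Δφ between consecutive *defined* orientations, wrapped
  to (−90°, 90°]; undefined frames break the chain (no step across them by
  default). The headline (μ, σ) are a least-squares Gaussian fit to the
  binned counts (default 10° bins — the original histogram's binning is not
  stated — configurable), with the raw-sample mean/sd reported alongside;
  the binned fit is the headline because that is how such histograms are
  customarily fitted. Because φ is only defined modulo 180°, cumulative
  rotation and a rotational diffusion coefficient are deliberately not
  computed.

## MD companions

The charge bookkeeping takes atom-class counts directly (no structure-file
parsing — reproducing the exact builder roster is out of scope) and sums
partial charges in exact decimal arithmetic so the ±0.115 e
terminal-carbon/hydrogen pairs cancel exactly: wall carbons 0 e, terminal C
−0.115 e, terminal H +0.115 e, carboxylate C +0.34 e, carboxylate O
−0.67 e, six carboxylates per end — net −12 e, requiring a 12-cation excess
for monovalent neutralisation. Centre-of-mass CSVs declare their box and
units in comment headers; Ångström inputs are converted to nm, and
non-uniform timestamps are rejected.

## Problem sizes used in validation

The shipped tests and `scripts/acceptance.py` use: 200 random tracks
(length ≤ 50) against the exhaustive MSD oracle; 100 tracks × 200 frames
per level for ensemble recovery at 10⁻⁴, 5×10⁻⁴ and 10⁻³ µm²/s; one
300-frame movie (one mobile particle over three static anchors) for the
end-to-end image chain; six 240-frame movies for the 0–25° tilt read-back;
500 samples for the rotation-step σ; and five 20-track ensembles for the
composition trend. These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances for the ensemble quantities.

## What passing tests do and do not show

The synthetic movies share the real data's geometry, sampling, bump height
and noise scale, but not: tip asymmetry and tip-shape convolution beyond a
spherical cap (bump asymmetry is attributed to tilt azimuth alone), raster
line-time skew, height-dependent imaging artefacts, membrane texture or
phase separation, particle loss by leaving the bilayer, or any interaction
between porins and the supporting substrate. Recovery of D, θ and σ on
these fixtures validates the analysis chain's correctness and calibration —
it does not certify accuracy on instrument data, where the dominant
uncertainties (substrate interactions, confinement in the field of view,
heterogeneous porin lengths) are physical, not algorithmic.
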