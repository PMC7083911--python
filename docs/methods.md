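# Methods

This note documents the models, defaults and numerical choices behind
`nanospt`, and what the synthetic generators do and do not emulate.

## Photon budget (`photophysics`)

A two-level emitter under continuous or high-repetition pulsed excitation
emits at rate *I(P) = I_sat·P/(P + P_sat)*. Detected count rates are
divided by the overall detection efficiency **before** fitting (by
linearity this is equivalent to scaling afterwards); the fitted `I_sat`
is therefore always the *emitted* rate. Defaults for the efficiency
chain: 0.70 (collection of a 1.49 NA objective over randomly oriented
dipoles) × 0.50 (optics transmission) × 0.05 (Si-range detector QE near
910 nm) = 0.0175.

The fit is Levenberg–Marquardt least squares with initialization
`I_sat⁰ = 2·max(I)`, `P_sat⁰ = median(P)` and 10⁻¹⁰ relative tolerances.
`plateau_reached` is reported as `max(P) ≥ 5·P_sat`; below that the
asymptote is extrapolated, which is the realistic regime for bright
saturating emitters (the sweeps that motivated this package could not
reach the plateau either). Up- and down-sweep points are pooled; the
maximum |up − down| rate difference at matched powers is reported as a
hysteresis diagnostic.

An emitter with excited-state lifetime τ and quantum yield Φ emits at
most Φ/τ photons per second, so `N = I_sat·τ/Φ` counts independent
centres (defaults τ = 100 µs, Φ = 0.1; Φ = 0.1 rather than the bulk
10.5% figure, matching the convention the conversion was defined with).
At σ_Cu = 3.8 ions nm⁻² for a single layer, `side = √(N/σ_Cu)` is the
side of the equivalent **square** monolayer sheet; both the unrounded
value and a nearest-nm rounding are reported. Note the square-sheet
convention here versus the disc convention in the generator (below);
both are documented because the worked-example size bounds (6–18 nm)
assume a square.

Bleaching traces are normalized to their initial value and fitted with a
single exponential; a decay rate whose 95% CI (from the fit covariance)
covers zero is classified "no detectable bleaching". This is an α = 5%
significance rule: on truly photostable noisy traces it false-alarms at
~5% per trace by construction, which the tests assert as a rate rather
than per seed.

## Tracking (`tracking`)

Detection: Gaussian smoothing (σ = 1 px) minus a boxcar background of the
blob size, clipped at zero, with a floor of 10⁻⁶ of the filtered maximum
to suppress float-rounding ripple of flat backgrounds; local maxima above
the given percentile (default 64) of positive filtered pixels; iterated
centre-of-mass refinement within a circular window of the blob radius
(converges to <0.005 px). The blob **mass** is the raw-image sum over the
square blob window minus the frame-median background — on rendered
Gaussian spots this matches the analytic integral 2πAσ² to ~1%. Position
comes from the band-passed centroid, mass from the raw image.

Linking is greedy global nearest-neighbour per frame pair: all
(track, spot) candidate pairs within the search range are sorted by
squared displacement (ties broken lexicographically on frame, x, y) and
consumed in order. This is deterministic and permutation-invariant, and
adequate at the low particle densities of the intended use (a handful of
spots per field); it is not a crossing-trajectory solver. Tracks survive
gaps up to `memory_frames` (default 300) and shorter tracks than
`min_length` (default 300; 200 in the embryo scenario) are discarded.
Pixel parameters are in pixels; conversion to µm/s requires the camera
pixel size and frame interval, which have no protocol-derived default
and must be supplied (config or TIFF sidecar).

## MSD and sizing (`msd`)

The default MSD estimator is the overlapping time-averaged MSD at every
integer lag (needed for a lag-resolved curve); a `single_step` estimator
(mean of consecutive single-step squared displacements only) is provided
for fidelity with the simplest printed definition. The diffusion fit is
weighted least squares of *MSD = 4·D·τ* through the origin over lags
≤ 25 s, with weights equal to the pair counts. An optional intercept
absorbs the static localization-noise offset 4σ_loc². Negative fitted D
is clipped to zero and flagged; such particles are excluded from the
size–brightness table with a logged reason.

Caveat: pair-count weights do not reflect the lag-correlation of
overlapping displacements, so single-track D estimates carry substantial
noise and their median is a few percent low when the fit window is a
large fraction of the track; cohort-level conclusions should use many
tracks or an ensemble-mean MSD (as the consistency tests do).

`glycerol_viscosity` implements the Cheng (2008) exponent-mixing
correlation for glycerol–water over 0–100 °C and the full composition
range; it reproduces standard water (1.00 mPa·s at 20 °C) and glycerol
(1.41 Pa·s at 20 °C) table values to a few percent.

Stokes–Einstein sizing uses k_B = 1.380649×10⁻²³ J/K exactly. The
anisotropy correction *A* = 1.49 for disc-like sheets is treated as a
given constant (its spheroid derivation is not reproduced here); an
orientation-averaged Perrin oblate-spheroid friction helper is included
for exploration but is deliberately **not** used to derive 1.49. The
size–brightness power law is ordinary least squares in log–log space of
max-mass versus hydrodynamic *diameter* (2·R_hydro; the table stores
both radius and the diameter-scale fit, since captions and text disagree
on which axis is meant), with a seeded particle-level bootstrap
(default 1000 resamples) for the exponent CI. Because the regressor
(recovered size) is noisy, the fitted exponent is attenuated toward zero
(regression dilution, ~15% at 1000-frame tracks over a 20–300 nm
cohort); longer tracks reduce it.

## Van Hove analysis (`vanhove`)

Displacements are pooled **per axis** (x and y) at the chosen lag
(default 0.1 s), since the histograms of interest span negative and
positive values. The histogram uses symmetric zero-centred bins
(default width 5 nm) normalized to unit total probability. The core
Gaussian *A·exp(−x²/2σ²)* is fitted by unweighted least squares on the
bin heights inside ±0.03 µm (fit-on-binned-data, matching a fit overlaid
on a histogram; an MLE on the raw displacements would weight the tails
it is supposed to ignore). `tail_excess` is the probability mass outside
the window minus the fitted Gaussian's prediction there, floored at
zero; its standard error comes from a seeded bootstrap over
displacements (default 100 resamples), and the active-processes flag is
raised when the excess exceeds 3× that SE. Excess kurtosis of the
pooled displacements is reported alongside as a model-free tail
indicator.

Nucleus-proximity partitioning assigns each displacement by the distance
of its **starting point** to the nearest nucleus border (unsigned:
points inside a nucleus get their distance to the ring). The default
near/far threshold — not fixed by any protocol — is the median distance
over all points, and is always reported. The comparison is a two-sided
Mann–Whitney test on displacement magnitudes plus the near/far variance
ratio; groups under 50 displacements are flagged underpowered instead of
silently tested.

## Synthetic data (`synthdata`)

The generators state a world and keep it fixed:

* **Sheets** — diameters log-uniform over 20–300 nm; height =
  (13/300)·diameter with 0.15 log-normal scatter, floored at the 1 nm
  monolayer; layer count = height rounded to monolayers; Cu²⁺ count =
  3.8 nm⁻² × disc area × layers (disc convention for generated sheets;
  the photon-budget size estimate uses the square convention — see
  above). Brightness ∝ diameter^0.5 with 20% multiplicative scatter by
  default.
* **Trajectories** — cumulative i.i.d. Gaussian steps of per-axis
  variance 2·D·Δt with D from Stokes–Einstein; optional additive i.i.d.
  localization noise; optional active bursts as Laplace-distributed
  extra displacements at a per-frame rate (no generative model for
  active motion is claimed by the measurements this emulates — the
  Laplace mixture is chosen to produce the heavy-tailed Van Hove
  signature). Defaults: 8 fps, 1000 frames (glycerol protocol); the
  embryo scenario uses 10 fps for 60 s.
* **Movies** — spots are integrated symmetric Gaussians (erf-based pixel
  integration, so an unclipped spot contributes exactly 2πAσ²);
  out-of-frame centres are clipped and flagged, never dropped. Noise:
  none, Poisson, or additive Gaussian. Frames are stored
  (n_frames, height, width) and written as 16-bit multi-page TIFF with a
  JSON sidecar.
* **Saturation sweeps** — expected counts from the saturation law scaled
  by efficiency and integration time, Poisson shot noise, optional
  up-then-down stepping.
* **Nuclei** — 24-gon circles on a jittered hexagonal grid with a
  bounded-retry non-overlap guarantee, emulating the regular nuclear
  array of a syncytial blastoderm.

What the generators do **not** emulate: out-of-focus intensity loss,
rotational diffusion and polarization effects, anisotropic PSFs, camera
read noise and gain, sample drift, crossing trajectories at high
density, nucleus motion, and 3-D diffusion. A green test on synthetic
data therefore establishes estimator correctness under the stated model,
not robustness to these effects.

All generators are bit-reproducible from their integer seed
(numpy `default_rng`). All lengths are µm, times s, temperatures K
internally; pixels appear only at rendering/IO boundaries.

## Reproducibility and IO

One canonical trajectory CSV schema (particle_id, frame, t_s, x_um,
y_um, mass, with a versioned header comment) is shared by all modules.
All file writes are atomic (temp file + rename). Pipeline summaries
record the package version, seed, full resolved config and whether each
parameter was a default or user-set.
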