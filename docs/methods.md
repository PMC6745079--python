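# Methods

## Signal model

Magnitude signal from collagen-rich tissue (ACL graft, tendon, ligament) in a
multi-echo UTE acquisition is modelled as two water pools:

    S(TE) = S0 · [ f_bw · e^(−TE/T2s*) + (1 − f_bw) · e^(−TE/T2l*) ]

with `S0` the TE=0 signal (arbitrary units, default 1), `f_bw` the bound-water
signal fraction in (0, 1), and `T2s*` / `T2l*` the fast and slow effective
transverse relaxation times in ms (typically 0.5–2 ms and 15–25 ms here). No
T1 saturation, flip-angle, fat chemical-shift or excitation-profile effects
are modelled; all fitting is of magnitude data.

The abbreviated protocol acquires only three double echoes (TE1/TE2 of
0.1/4.0, 0.27/5.0, 0.5/6.0 ms). Over the three sub-millisecond TE1s the slow
pool has decayed by at most ~2.5% (at T2l* = 20 ms), so it is treated as a
constant baseline and the TE1 decay attributed to the fast pool alone:

    S(TE) = baseline/(1 − f_bw,app) · e^(−TE/T2s,app*) + baseline

The amplitude convention follows the estimator's published form: the fitted
amplitude `A` and the fixed baseline define the apparent fraction through
`f_bw,app = 1 − baseline/A`. Note this is *not* the TE=0 signal-fraction of
the fitted curve (that would be `A/(A + baseline)`): even in the ideal limit
of an infinitely slow free pool the apparent fraction maps to `(2f−1)/f`
rather than `f`. This definitional offset is deliberate — it is part of what
the downstream bias correction absorbs, and it is the convention under which
the calibration and all summary statistics in this package are defined and
validated.

## Estimators

**Abbreviated fit** (`fit_abbreviated`): the baseline is fixed to the
arithmetic mean of the three TE2 signals (never a free parameter — this keeps
the TE1 fit two-parameter, which is the point of the abbreviated paradigm).
`(f_bw,app, T2s,app*)` are then fitted to the three TE1 signals by bounded
trust-region least squares, bounds `f_bw,app ∈ [0, 0.9999]`,
`T2s,app* ∈ [0.05, 10] ms`. Initialization is deterministic and scale-free:
`T2s,app*` from the two-point log-slope of the baseline-subtracted first/last
TE1 signals clamped to [0.1, 5] ms, the fraction from the amplitude implied
by the first TE1 signal. Boundary-pinned solutions (typically `f_bw,app = 0`
when the fast amplitude falls below the baseline) are flagged, not silently
returned. Negative baseline-subtracted signals are kept as-is in the
objective; clipping would bias low-SNR fits.

**Bi-exponential fit** (`fit_biexp`): four parameters via variable
projection — for each candidate `(T2s*, T2l*)` (optimized in log space,
bounds [0.05, 5] and [5, 100] ms) the two pool amplitudes are the exact
linear least-squares solution. Multi-exponential objectives are multi-modal,
so the optimizer is multi-started from the log-spaced lattice
T2s* ∈ {0.3, 1, 3} × T2l* ∈ {10, 30} ms; with amplitudes solved exactly, no
amplitude/fraction starts are needed. A single warm start can be supplied
instead (used by the Monte-Carlo study, see below). All 10 echoes of the full
schedule are used by default; `drop_te=20.0` reproduces the in-vivo practice
of discarding the lowest-SNR echo.

**Long-component fit** (`fit_t2l_monoexp`): a mono-exponential fit of
variable-TE echoes at TE ≥ 3 ms (configurable), so a fast pool with
T2s* ≤ 2 ms has decayed ≥ 78% before the first included echo; initialized
from the closed-form log-linear regression. A non-decaying input pins T2l* at
the upper bound and is flagged.

## Bias calibration

`simulate_bias_grid` tabulates the noise-free estimation bias of the
abbreviated estimator on a ground-truth grid: default 61 × 41 nodes over
T2s* ∈ [0.5, 2.0] ms and the chosen f_bw range, at fixed T2l*. At this
density the grid summaries are stable to < 0.1 percentage points under
refinement. Relative bias is `(apparent − true)/true`; "±X%" summaries are
means of *absolute* relative errors (signed means are reported alongside).

`fit_correction` fits two bivariate polynomials of total degree 4 (15 terms)
by ordinary least squares, predicting the error (true − apparent) for each
parameter as a function of the *apparent* pair — the only quantities
available at inference time. Flagged nodes are excluded from the design; a
rank-deficient design raises. `apply_correction` adds the predicted error
and clamps the corrected fraction to (0, 1] with a flag; estimates outside
the calibration rectangle are corrected anyway but flagged as extrapolated.

An optional lookup-inversion mode interpolates the calibration grid's truth
directly at the apparent coordinates (piecewise-cubic on the scattered
calibration nodes, polynomial fallback outside their convex hull). Inside the
calibrated domain it is about an order of magnitude sharper than the
polynomial; the polynomial remains the default because it serializes to 30
coefficients and extrapolates smoothly.

On the clinical range (f_bw 0.75–0.95, T2l* = 20 ms) the noise-free
calibrate-then-apply residual is ≈ 0.004% for f_bw. With truth at
T2l* = 15 ms corrected by the 20 ms model, mean absolute residuals are
≈ 1.4% (T2s*) and ≈ 1.7% (f_bw) over the same range — the correction is
robust to realistic T2l* mismatch at high f_bw.

### The low-f_bw regime

For f_bw ≲ 0.45 the fast amplitude drops below the TE2 baseline and the
abbreviated model is infeasible: the constrained fit pins `f_bw,app` at 0 and
the apparent values no longer identify the truth. Grid summaries over
f_bw 0.25–0.75 are therefore dominated by how the solver behaves at
infeasible nodes (bound handling, clamping, inclusion rules) rather than by
the model itself, and are reported with that caveat; the package keeps
pinned nodes in the summaries (flagged) and documents the alternatives. This
regime is outside the abbreviated paradigm's intended use; a measured
subject-specific T2l* and the full protocol are the right tools there.

## Monte-Carlo SNR study

`run_snr_study` compares the corrected abbreviated pipeline against full
bi-exponential fitting at SNR ∈ {1000, 800, 600, 400, 200}. Noise is
additive zero-mean Gaussian per echo with σ = S0/SNR, drawn per curve (the
curve represents an already ROI-averaged signal; per-voxel single-voxel SNR
in vivo is far lower, but ROI averaging over thousands of voxels raises the
effective SNR into this range, which also makes Rician bias negligible — a
Rician option exists behind a flag). The grid is a coarse 7 × 6 lattice over
T2s* ∈ [0.5, 2.0] ms, f_bw ∈ [0.70, 0.95], T2l* = 20 ms, with 500 replicates
per node by default; these are desk-scale choices (the error means are stable
well below the tolerance of interest at this size). The bi-exponential fit
uses the node's noiseless multi-start solution as a warm start for its noisy
replicates — a continuation strategy that preserves the multi-start guarantee
where it matters (the basin structure is set by the noiseless curve) at a
sixth of the cost; per-replicate multi-start remains available via config.
The error metric is the mean over nodes and replicates of
|estimate − truth|/truth × 100, with the SD over the same population. All
randomness flows from one seeded generator; identical config + seed gives
identical tables.

## ROI geometry

Masks are 3D boolean arrays with explicit voxel size (default 1 mm isotropic)
and an explicit B0 axis (default array axis 2) — the field direction is never
inferred from image metadata. The graft/bone interface is the Euclidean-ball
dilation of the intra-bone graft mask by 2 mm (in physical mm, honouring
anisotropic voxels) minus the graft itself, hence disjoint from it by
construction; at 1 mm voxels the 2 mm ball is the 32-voxel neighbourhood with
lattice distance ≤ 2. Dilation is 3D; in-plane-only growth is available by
restricting the structuring element. ROI orientation is the acute angle
between B0 and the total-least-squares line through the per-slice in-plane
centroids (slices taken along the B0 axis by default, configurable); it is
translation- and reflection-invariant by construction. Intra-rater
reliability uses the Dice coefficient 2|A∩B|/(|A|+|B|) and a *symmetric*
relative error |x1 − x2|/mean(x1, x2) × 100 — the symmetric denominator is a
deliberate choice so the metric does not depend on which placement is called
"first".

## Synthetic phantom

`build_phantom` voxelizes labelled geometric segments (oriented cylinders,
axis-aligned boxes) with per-segment tissue parameters into S0/f_bw/T2s*/T2l*
maps plus masks; `render_echoes` evaluates the bi-exponential model voxelwise
at each echo time and adds seeded Gaussian noise (σ = segment S0/SNR).
Cylinder ends are cut flat perpendicular to the B0 axis so that every slice
along B0 is a complete elliptical cross-section; per-slice centroids then lie
exactly on the cylinder axis and the mask's measured orientation matches the
specified angle to within voxelization error (< 3°). The default phantom
carries three graft-like segments at 47°, 32° and 25° to B0 with
T2s* 1.4–1.9 ms, f_bw 0.82–0.93, T2l* = 20 ms — the reported graft regimes.
The phantom emulates piecewise-constant tissue with ideal co-registration;
it does not model partial-volume mixing beyond voxelization, field
inhomogeneity, streaking artifacts or orientation-dependent (magic-angle)
relaxation, so phantom-based recovery demonstrates pipeline correctness, not
robustness to those effects.

## Numerical choices

* Optimizer tolerances: 1e-12 (xtol/ftol/gtol) throughout; fits are
  deterministic given the documented initializations.
* Boundary detection: a parameter within 1e-4 of its bound span is flagged.
* Corrected fractions clamped to (0, 1] with a flag; never silently.
* Floating-point output in CLI artifacts uses 6 significant digits.

## Known limitations

* The apparent-fraction convention (`1 − baseline/A`) means `f_bw,app` is not
  a physical fraction before correction and can pin at 0 for low-f_bw tissue
  (see above).
* The correction assumes a single fixed T2l*; tissues far from the assumed
  value at low f_bw need a measured T2l* (vTE fit) instead.
* No Rician-bias correction of magnitudes; valid for ROI-averaged curves.
* Voxel-wise mapping exists only as an internal option for phantom tests;
  the supported product is ROI-mean fitting, which is what the abbreviated
  acquisition's artifact behaviour (streaking at TE1) requires anyway.
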