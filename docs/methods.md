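# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `longcal`. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic video model

Each session's frame is

    F_t = 10 * B + C_t^T A + b_t * G + eta_t,   then warped by the
    session's misalignment field and clipped at zero,

where

- `B` is a static baseline in [0, 1]: a smooth bright background crossed
  by dark procedural vessel trees (random walks, widths 3–9 px,
  12 branches plus occasional side branches). The factor 10 sets a
  realistic offset relative to the unit noise scale. Real recordings use
  tissue as the baseline; the procedural trees make testing download-free
  and provide an exact vessel skeleton for oracle tests.
- `A` holds K anisotropic Gaussian footprints (eccentricity 1–2, radius
  ~`gsiz_px`, truncated at 1% of peak, unit peak), placed by rejection
  sampling with a minimum pairwise centroid separation. Separation presets:
  26 µm (low overlap), 21 µm (medium), 8 µm (high); the single scale
  conversion is `um_per_px = 2.0`.
- `C` holds traces: per-neuron Bernoulli event trains convolved with
  g(t) = exp(−t/τ_d) − exp(−t/τ_r). The per-frame event probability p and
  the inverse time constants are lognormal, ln p ~ N(−4.9, 2.25²),
  ln τ_r⁻¹ ~ N(2.08, 0.29²), ln τ_d⁻¹ ~ N(0.55, 0.44²) (units s⁻¹),
  resampled until τ_d > τ_r. Every neuron must fire at least once per
  session (this biases mean rate slightly upward; we do not compensate).
  Traces are rescaled per neuron so peak amplitude / noise σ equals the
  configured peak-to-noise ratio (default 2).
- `G` is the sum-of-footprints image smoothed with a σ = 20 px Gaussian
  (diffuse background), modulated by `b_t`, a unit-variance smoothed random
  walk — the spatial model is standard; the temporal modulation scale
  (≈ noise σ) is our choice, as only the spatial part is well established.
- `eta_t` is white noise smoothed with a σ = 0.5 px Gaussian and rescaled
  to unit variance (weakly correlated sensor/photon noise).

Misalignment fields are gradients of white noise smoothed with a σ = 60 px
Gaussian, rescaled so the *maximum* displacement magnitude equals the
configured amplitude (presets ~8 µm and ~12.5 µm; "amplitude" is defined
as the max over pixels). In progressive mode the fields accumulate random
increments and are rescaled so drift grows linearly to the full amplitude
at the last session — gradual FOV drift, with neighbors one step apart.
Remapping silences a fraction of neurons in one randomly chosen session
each; SNR drops scale their transients by 0.2 instead.

What the simulator does *not* model: photobleaching, frame drops, z-axis
scanning, real footprint shapes (blobs only), non-stationary noise, or
within-session motion. Tests passing on this model therefore demonstrate
algorithmic correctness under controlled conditions, not performance on
every real preparation.

## Vessel enhancement

Frames are smoothed with separable 1-D Gaussians (columns then rows);
second partials come from central differences with replicate borders. The
per-pixel Hessian eigenvalues have the closed form
λ = (−a₁ ± sqrt(a₁² − 4a₂))/2 with a₁ = −(f_xx + f_yy),
a₂ = −(f_xx f_yy − f_xy²) as implemented, and the response keeps the
signed eigenvalue of larger magnitude (ties resolve to λ₂). Responses are
accumulated as Σ σᵢ·φᵢ over ten diameters linearly spaced on
[2.4, 3.5]·gSiz with σᵢ = dᵢ/4, then min-max normalized to [0, 1] so the
map can serve directly as a registration channel (the normalization is our
addition; a flat input returns zeros).

## Registration

Displacement fields are (2, H, W) arrays of (dy, dx) pixels; warping is
backward (`out(x) = in(x + f(x))`) with bilinear interpolation and
replicate padding; coordinates are 0-based (row, col). Field composition
follows `warp(I, compose(a, b)) == warp(warp(I, b), a)`, i.e.
`compose(a, b)(x) = a(x) + b(x + a(x))`.

The log-demons iteration: warp the moving image by the running field S,
compute the additive force v = (F−M)∇M / (|∇M|² + (σ_i²/σ_x²)(F−M)²),
smooth v with σ_fluid (fluid regularization), compose S with exp(v)
(scaling-and-squaring, N chosen so the scaled step stays below 0.5 px),
smooth S with σ_diffusion. Per-level parameters (coarse→fine):
σ_fluid = (1,1,3,3), σ_diffusion = (5,5,3,3), σ_x² = (1,1,1,2),
σ_i² = (1,1,1,1). Stopping: 60 iterations per level or relative energy
change < 1e-4. Energy may blip below 1% around the minimum; sustained
growth (>1% above the best for 5 iterations without net progress) raises a
divergence error. Returned fields must have positive Jacobian determinant
at all interior pixels; a violating field gets one extra diffusion pass and
errors if still folding. Images are min-max normalized before forces.

The multiscale schedule uses four pyramid levels at scales (¼, ½, ½, 1)
with channels (vessel, vessel, vessel/neuron average, neuron) — four
levels match the four-vector regularization defaults. Neuron-only mode
uses the neuron channel at every level. Each level's field is upsampled,
magnitude-rescaled, and used to initialize the next.

## Session summaries and the vessel similarity score

The vessel projection is the enhanced median frame (vessels live in the
static baseline). The neuron projection is the product of min-max
normalized correlation and peak-to-noise images computed on the spatially
band-passed (difference of Gaussians at gSig and 2·gSig), temporally
boxcar-smoothed (5 frames) detrended video, with the peak referenced to
the *unsmoothed* spectral noise σ. This matched-filter convention matters:
the plain max/σ image is dominated by the maximum-of-noise statistic
(≈ sqrt(2 ln T) ≈ 3.5–4 σ), leaving almost no neuron contrast at
peak-to-noise 2 and making the seed thresholds meaningless. With the
matched filter the pure-noise ceiling drops to ≈1.5 while slow transients
keep most of their amplitude, so the default thresholds separate cleanly.

The vessel similarity score z-scores the observed correlation of two
vessel maps against 100 surrogates in which one map is warped by a random
smooth field (σ = 15, max amplitude 6 px). Identical vessel-rich maps
score well above the 2.7 decision threshold; unrelated maps score ≈0.
Pairs below threshold are re-registered neuron-only; if a session's mean
pair score is below threshold the whole run switches to neuron-only, with
alerts either way.

## Groupwise atlas

All ordered pairs are registered explicitly (O(N²), acceptable to N ≈ 20).
Each session's atlas field is the weighted groupwise mean

    T_(s->CA) = -((N-1)/N) * Σ_i T_(i->s)·w_is / Σ_i w_is

where w_is is the smoothed, clipped local structural similarity (window
radius 5 px) of the *aligned* pair (i, s): a transformation between
sessions that do not match after alignment is unreliable and contributes
little. With uniform weights this reduces to the plain groupwise mean
−(1/N) Σ T_(i→s), which is centered (fields sum to ≈0 across sessions).
For more than two sessions one refinement pass re-registers the
atlas-aligned summaries and composes the solutions: after the first pass
every session has moved toward the common frame, so pairs initially too
far apart to register directly fall inside the registration basin. This
iterated, contribution-weighted scheme is what lets two sessions that fail
direct pairwise alignment still be linked through intermediates.

## Pipeline ordering

The end-to-end pipeline aligns the raw (motion-corrected) videos and
detrends afterwards: vessel projections come from the raw median frame
(detrending removes the static baseline that carries the vessels), and
warping the raw video once avoids interpolating noise-scaled data twice.
The alignment stage detrends internally when building its summaries, and
extraction always sees detrended, noise-scaled, aligned data.

## Preprocessing

Detrending subtracts a running 20th-percentile baseline (30 s window,
piecewise block percentiles linearly interpolated — the estimate is
edge-biased within half a window of the session ends) and divides by the
per-pixel noise σ estimated from the upper half of the power spectrum
(for white noise E|X_k|² = Tσ², so σ = sqrt(mean |X_k|²/T) over bins in
[0.25, 0.5] of the sampling rate). Zero-noise pixels are floored with a
warning and reported as zero signal. Concatenation records session
boundaries and reports the junction artifact metric (mean inter-session
frame difference vs the 99th percentile of within-session differences);
the check is reported, not enforced.

## Extraction

Seeds are local maxima of corr·pnr passing min_corr (0.15) and min_pnr
(2.5), thinned to gSig spacing, ordered by descending PNR. Initialization
tiles the FOV (~12 patches, margin 2·gSiz) and processes patches
concurrently; within a patch seeds run high→low PNR, each re-validated
against the current residual (its signal may already be explained),
rank-1 fitted on the band-passed video (so shared background cannot leak
into footprints), skew-vetoed (transient traces are right-skewed; noise
fits are not; threshold 0.5), and subtracted. Patches share no state, so
results are order-independent and match sequential processing for seeds in
different patches.

The factorization model is Y ≈ CᵀA + b0 + W·ring_mean(residual). The ring
background predicts each pixel from the mean residual on a surrounding
annulus (radius round(1.5·gSiz), FFT convolution) with a per-pixel
least-squares gain W — a deliberate restriction of the fully free
per-pixel ring-weight model, which is not tractable at this package's
intended single-core scale. Components are merged (trace correlation
> 0.65 with footprint overlap) *before* the first HALS pass — duplicates
still share their parent's transients then; after HALS they partition the
signal and become unrecognizable — and again after. HALS updates traces
then support-restricted footprints; the quadratic objective is logged and
non-increasing. Footprints are clipped to a (3·gSiz)² box around their
peak.

Deconvolution is AR(1) OASIS (pool adjacent violators) with the
coefficient estimated from the autocovariance ratio acov(2)/acov(1).
Events below a threshold are discarded and the trace rebuilt from the
survivors; the threshold is 1.5 trace-noise σ capped at a quarter of the
largest event — traces with many overlapping transients peak-normalize to
small individual events, and a purely noise-referenced floor would discard
genuine activity there (1–2 σ performs equivalently at the default
conditions; 1.5 is the middle of that plateau).

Batchwise processing uses one batch per session (or `batch_frames` within
long sessions): each batch fits existing components, seeds new ones from
its residual (vetoing seeds within max(gSig, gSiz/2) of an existing
component — those are alignment/fit leftovers), and factorizes.
Summarization averages ring gains, takes the elementwise-minimum baseline,
averages footprints weighted by squared mean batch activity, and
concatenates traces. A final unified sweep refits every trace against the
fused footprints batch by batch and deconvolves once at full length — a
neuron with one or two events per session otherwise loses substantial
trace fidelity to its noisy per-batch footprint. A component-level gate
(the seed PNR rule applied to the matched-filtered raw trace, plus at
least one surviving event) removes residual noise components. At most one
batch of frames is resident at a time.

## Sorting and evaluation

Footprints are centered at their intensity-weighted centroid before
cosine distances, so the comparison is about shape, not location (two
identical somata at opposite corners would otherwise be maximally
distant). Classical (Torgerson) MDS embeds the distances in d = 2
dimensions (deterministic, matches the strain criterion); Mahalanobis
distances from the accepted-set mean/covariance rank components with
shape outliers last; user-provided accept labels re-estimate the model.
Singular covariances are ridge-regularized with a warning.

Matching to ground truth multiplies footprint and denoised-trace cosine
similarity matrices elementwise and solves the linear assignment problem
exactly; pairs with temporal similarity above τ = 0.8 count as true
positives; unmatched components have similarity zero. Centroids are
intensity-weighted. The population vector distance splits each session in
half, takes mean activity per neuron per half, and reports mean
inter-session minus mean intra-session correlation distance (larger =
less stable); undetected neurons are excluded by default, zero-filled on
request.

## Benchmark problem sizes

The benchmark scenarios in `longcal.benchmarks` run the generative model
at 96×128 px, 300–600 frames per session, 30–80 neurons — scaled-down
versions of typical recordings chosen so the full battery completes on a
single core in minutes. All statistical parameters keep their standard
values. Two scenario-level choices: the batchwise-equivalence and low-SNR
scenarios render sessions without inter-session misalignment so the
comparison isolates the extraction strategy, and the drifting-FOV scenario
uses progressive drift accumulating to 32 µm with 50% remapping so that
the end pair genuinely cannot be registered directly — the regime the
groupwise atlas exists for. The low-SNR benchmark reports both the
session-segment F1 at τ = 0.8 (which neither pipeline can reach at 80%
amplitude reduction and peak-to-noise 2 at these problem sizes) and the
mean segment similarity, where the concatenation benefit is unambiguous.

## Known limitations

- Within-session motion correction registers every frame's
  vessel-enhanced image to the median-frame template; it is accurate but
  slow, and the pipeline leaves it off by default for simulated input
  (which has no within-session motion).
- The demons translation estimate decays to zero in featureless image
  regions (diffusion regularization); displacement summaries should be
  weighted by image gradient.
- The detrend baseline is edge-biased within half a window of session
  ends.
- The per-pixel scalar ring gain cannot represent anisotropic background
  structure the way fully free ring weights can.
- Trace crosstalk between overlapping components leaves residual energy
  in sessions where a neuron is truly silent; the activity split is a
  distributional property, not exact.
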