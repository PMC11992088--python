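# longcal

Longitudinal neuron tracking for multi-session one-photon calcium imaging.

Miniscope recordings taken days or weeks apart are misaligned by non-rigid
brain deformation, and the set of active neurons changes between sessions.
Tracking the same cells across sessions by matching independently extracted
footprints is fragile: neurons are homogeneous blobs, so registration
driven by neuron shape alone falls into local minima, and a neuron missed
in one session cannot be matched at all. `longcal` takes the
concatenation route instead:

1. **Vessel-guided non-rigid alignment.** Blood vessels appear as dark,
   elongated structures that are stable across sessions and far more
   distinctive than neuron blobs. A multiscale Hessian filter
   (sigma_i = d_i/4 over ten diameters 2.4–3.5 × gSiz, keeping the
   dominant-magnitude eigenvalue per pixel) enhances them, and a
   coarse-to-fine diffeomorphic log-demons registration aligns sessions —
   vessels at the coarse pyramid levels, neuron projections
   (correlation × peak-to-noise images) at the finest.
2. **Vessel similarity scoring and fallback.** The observed correlation
   of two vessel maps is z-scored against 100 randomly misaligned
   surrogates. Pairs scoring below 2.7 are re-registered neuron-only and
   an alert is raised.
3. **Weighted groupwise atlas.** With N sessions, every ordered pair is
   registered and each session is mapped to a common atlas,
   `T_(s->CA) = -((N-1)/N) * sum_i T_(i->s) w_is / sum_i w_is`, with each
   contribution weighted pixelwise by the aligned pair's local vessel
   similarity, then iteratively refined. Sessions that cannot be aligned
   directly are still linked through the intermediate sessions.
4. **Concatenated extraction.** Aligned sessions are detrended
   (running 20th-percentile baseline), noise-scaled per pixel,
   concatenated, and factorized with a seeded CNMF-E-style nonnegative
   factorization (ring background model, HALS updates, AR(1)
   deconvolution) that processes one batch of frames at a time and fuses
   the batches into a single component set spanning all sessions — so a
   neuron that is weak in one session inherits the footprint estimated
   where it was strong.
5. **Component sorting and evaluation.** Components are ranked by spatial
   congruence (classical MDS of pairwise cosine distances between centered
   footprints + Mahalanobis distance), and extractions can be scored
   against the bundled simulator's exact ground truth via optimal linear
   assignment of the spatio-temporal similarity matrix.

The package ships a first-class simulator reproducing the statistics of
dentate-gyrus recordings (lognormal transient rates and kinetics,
double-exponential transients, peak-to-noise ratio 2, procedural vessel
baselines, smooth random misalignment fields), so every stage can be tested
against exact ground truth without any external data.

## Worked example

```python
from longcal import (SimulationConfig, render_sessions, align_sessions,
                     detrend_and_scale, concatenate_sessions,
                     extract_batchwise, match_components)
from longcal.config import ExtractionConfig

cfg = SimulationConfig(fov_shape=(96, 128), n_neurons=30,
                       frames_per_session=400, n_sessions=2,
                       misalign_amplitude_um=8.0, seed=1)
videos, truth = render_sessions(cfg)

aligned, atlas, report = align_sessions(videos, seed=1)
print(report["pair_scores"], report["mode"])
# {'1->0': 3.23, '0->1': 3.77} bv+neuron

pre = [detrend_and_scale(v, fps=10.0, session_id=i)
       for i, v in enumerate(aligned)]
stack, index = concatenate_sessions(pre)
comps, info = extract_batchwise(stack, index.bounds, ExtractionConfig())
m = match_components(comps.A, comps.C, truth.footprints, truth.traces,
                     tau=0.8)
print(comps.n_components, round(m.f1, 3))
# 33 0.952
```

The vessel scores (≈3.2–3.8, above the 2.7 threshold) mean both sessions
carry usable vessel structure, so the full vessel+neuron schedule was used.
The run recovers 33 components for 30 simulated neurons, and 95% (F1 at
temporal-similarity threshold 0.8) of extracted traces match their
ground-truth neuron across both sessions.

The same pipeline is available from the shell:

```bash
longcal simulate --out sims/ --seed 1
longcal align --in sims/session_00.h5 --in sims/session_01.h5 --out aligned/
longcal run --out results/ --seed 1
```

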