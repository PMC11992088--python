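"""Synthetic-data benchmark scenarios exercising the full pipeline.

Each function builds a self-contained study from the simulator's generative
model, runs the relevant pipeline stages, and returns the measured
quantities. The problem sizes (~100x130 px fields, 200-400 frames per
session, 30-80 neurons) are scaled-down versions of typical miniscope
recordings chosen so a complete benchmark run finishes on one CPU core in
minutes; all statistical parameters of the generative model keep their
standard values.
"""

from __future__ import annotations

import numpy as np

from .config import ExtractionConfig, PipelineConfig, SimulationConfig
from .demons import jacobian_determinant, warp
from .evaluate import match_components
from .extract import extract_batchwise
from .multisession import (align_sessions, build_session_summary,
                           bv_similarity_score, multiscale_align_pair)
from .preprocess import concatenate_sessions, detrend_and_scale
from .projections import chunked_max_correlation, correlation_image
from .simulate import blend_fovs, render_sessions, synth_vessel_baseline
from .vessels import enhance_vessels

__all__ = [
    "registration_recovery",
    "bv_score_behavior",
    "drifting_atlas",
    "chunked_correlation_benefit",
    "batch_equivalence",
    "low_snr_benefit",
    "end_to_end",
]


def _centroid(img: np.ndarray) -> np.ndarray:
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    tot = img.sum()
    return np.array([(img * yy).sum() / tot, (img * xx).sum() / tot])


def _matched_centroid_distances(truth, field_obs, align_field=None):
    """Distance between each neuron's reference centroid and its observed
    (misaligned, optionally re-aligned) centroid."""
    out = []
    for fp in truth.footprint_images():
        obs = warp(fp, field_obs)
        if align_field is not None:
            obs = warp(obs, align_field)
        out.append(float(np.hypot(*(_centroid(obs) - _centroid(fp)))))
    return np.array(out)


def registration_recovery(seed: int = 0) -> dict:
    """Two-session pairwise alignment on the high-overlap preset (8 um
    separation) with 4 px non-rigid misalignment: median matched-centroid
    distance after the vessel+neuron schedule, compared with neuron-only.
    """
    cfg = SimulationConfig(fov_shape=(96, 128), n_neurons=80,
                           frames_per_session=300, n_sessions=2,
                           min_separation_um=8.0, misalign_amplitude_um=8.0,
                           seed=seed)
    videos, truth = render_sessions(cfg)
    summaries = [build_session_summary(v, fps=cfg.fps, session_id=i)
                 for i, v in enumerate(videos)]
    f_obs = truth.misalignment_fields[1]
    pre = _matched_centroid_distances(truth, f_obs)
    fields = {}
    medians = {}
    for schedule in ("bv+neuron", "neuron-only"):
        T = multiscale_align_pair(summaries[0], summaries[1], schedule=schedule)
        fields[schedule] = T
        medians[schedule] = float(np.median(
            _matched_centroid_distances(truth, f_obs, T)))
    return {
        "pre_median_px": float(np.median(pre)),
        "bv_neuron_median_px": medians["bv+neuron"],
        "neuron_only_median_px": medians["neuron-only"],
        "fields": fields,
        "n_neurons": cfg.n_neurons,
    }


def bv_score_behavior(seed: int = 0, n_seeds: int = 50) -> dict:
    """Vessel similarity score on identical, independent, and progressively
    blended vessel phantoms."""
    cfg_a = SimulationConfig(fov_shape=(64, 80), seed=seed)
    cfg_b = SimulationConfig(fov_shape=(64, 80), seed=seed + 7919)
    img_a = synth_vessel_baseline(cfg_a, np.random.default_rng(cfg_a.seed))
    img_b = synth_vessel_baseline(cfg_b, np.random.default_rng(cfg_b.seed))
    bv_a = enhance_vessels(img_a).values
    bv_b = enhance_vessels(img_b).values
    identical = bv_similarity_score(bv_a, bv_a, seed=seed).score
    independents = np.array([
        bv_similarity_score(bv_a, bv_b, seed=seed + 1000 + i).score
        for i in range(n_seeds)])
    blend_ws = (1.0, 0.8, 0.6, 0.4, 0.2)
    blend_scores = []
    for w in blend_ws:
        bv_w = enhance_vessels(blend_fovs(img_a, img_b, w)).values
        blend_scores.append(bv_similarity_score(bv_a, bv_w, seed=seed + 13).score)
    return {
        "identical_score": float(identical),
        "independent_scores": independents,
        "independent_within2_fraction": float(np.mean(np.abs(independents) <= 2)),
        "blend_ws": blend_ws,
        "blend_scores": blend_scores,
        "n_seeds": n_seeds,
    }


def _segment_similarity(c_extr: np.ndarray, c_true: np.ndarray) -> float:
    ne, ns = np.linalg.norm(c_extr), np.linalg.norm(c_true)
    return float(c_extr @ c_true / (ne * ns)) if ne > 0 and ns > 0 else 0.0


def _tracking_f1(videos, sess_ids, truth, tau=0.8, seed=0):
    """Track neurons between the first and last listed sessions: align,
    concatenate, extract, and count neurons whose trace matches truth in
    BOTH end sessions (segment temporal similarity > tau)."""
    aligned, atlas, report = align_sessions(videos, seed=seed)
    pre = [detrend_and_scale(v, session_id=i) for i, v in enumerate(aligned)]
    stack, idx = concatenate_sessions(pre)
    comps, _ = extract_batchwise(stack, idx.bounds, ExtractionConfig())
    tr = np.concatenate([truth.traces[:, slice(*truth.session_bounds[s])]
                         for s in sess_ids], axis=1)
    m = match_components(comps.A, comps.C, truth.footprints, tr, tau=tau)
    inv = {j: i for i, j in m.assignment}
    first, last = sess_ids[0], sess_ids[-1]
    lb, le = idx.bounds[0], idx.bounds[-1]
    eligible = tracked = 0
    for j in range(truth.n_neurons):
        if not (truth.activity_mask[j, first] and truth.activity_mask[j, last]):
            continue
        eligible += 1
        if j not in inv:
            continue
        i = inv[j]
        sim_first = _segment_similarity(
            comps.C[i][lb[0]:lb[1]],
            truth.traces[j][slice(*truth.session_bounds[first])])
        sim_last = _segment_similarity(
            comps.C[i][le[0]:le[1]],
            truth.traces[j][slice(*truth.session_bounds[last])])
        if sim_first > tau and sim_last > tau:
            tracked += 1
    # precision counts components that could have tracked the end pair:
    # those assigned to a neuron active in both end sessions, plus
    # unassigned (junk) components; components following neurons that are
    # genuinely silent in an end session are not candidates
    eligible_assigned = sum(
        1 for j, i in inv.items()
        if truth.activity_mask[j, first] and truth.activity_mask[j, last])
    candidates = eligible_assigned + (comps.n_components - len(inv))
    precision = tracked / max(candidates, 1)
    recall = tracked / max(eligible, 1)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"f1": f1, "recall": recall, "n_components": comps.n_components,
            "atlas": atlas, "report": report}


def drifting_atlas(seed: int = 0) -> dict:
    """Five sessions whose vessels and misalignment drift progressively so
    the end pair cannot be vessel-aligned directly: groupwise atlas
    alignment vs direct pairwise alignment of the end sessions."""
    cfg = SimulationConfig(fov_shape=(96, 128), n_neurons=60,
                           frames_per_session=300, n_sessions=5,
                           min_separation_um=8.0, fov_blend_w=0.35,
                           misalign_amplitude_um=32.0, remap_fraction=0.5,
                           misalign_progressive=True, seed=seed)
    videos, truth = render_sessions(cfg)
    res_atlas = _tracking_f1(videos, [0, 1, 2, 3, 4], truth, seed=seed)
    res_direct = _tracking_f1([videos[0], videos[4]], [0, 4], truth, seed=seed)
    atlas = res_atlas["atlas"]
    pair_score = res_atlas["report"]["pair_scores"]["4->0"]
    f5 = truth.misalignment_fields[4]
    pre = _matched_centroid_distances(truth, f5)
    post = []
    for fp in truth.footprint_images():
        p1 = _centroid(warp(fp, atlas.to_atlas[0]))
        p5 = _centroid(warp(warp(fp, f5), atlas.to_atlas[4]))
        post.append(float(np.hypot(*(p1 - p5))))
    reduction = 1.0 - float(np.median(post)) / float(np.median(pre))
    min_jac = min(float(jacobian_determinant(f)[1:-1, 1:-1].min())
                  for f in atlas.to_atlas)
    return {
        "end_pair_score": float(pair_score),
        "pre_median_px": float(np.median(pre)),
        "post_median_px": float(np.median(post)),
        "reduction": reduction,
        "f1_atlas": res_atlas["f1"],
        "f1_direct": res_direct["f1"],
        "min_atlas_jacobian": min_jac,
        "atlas_fields": atlas.to_atlas,
        "n_sessions": 5,
    }


def chunked_correlation_benefit(seed: int = 0) -> dict:
    """A neuron active only in the first of five chunks: chunked-max vs
    whole-video correlation at its pixels."""
    rng = np.random.default_rng(seed)
    T, chunk = 1500, 300
    video = rng.normal(size=(T, 16, 16))
    trace = np.zeros(T)
    trace[20:280] = np.abs(np.sin(np.linspace(0, 16, 260))) * 4
    pix = [(7, 7), (7, 8), (8, 7), (8, 8)]
    for y, x in pix:
        video[:, y, x] += trace
    chunked = chunked_max_correlation(video, chunk_frames=chunk).values
    full = correlation_image(video).values
    vals_c = np.array([chunked[p] for p in pix])
    vals_f = np.array([full[p] for p in pix])
    return {
        "chunked_minus_full_min": float((vals_c - vals_f).min()),
        "chunked_mean": float(vals_c.mean()),
        "full_mean": float(vals_f.mean()),
        "n_chunks": T // chunk,
    }


def _sim_two_sessions(seed: int, **overrides) -> tuple:
    cfg = SimulationConfig(fov_shape=(96, 128), n_neurons=30,
                           frames_per_session=400, n_sessions=2, seed=seed,
                           **overrides)
    videos, truth = render_sessions(cfg)
    pre = [detrend_and_scale(v, fps=cfg.fps, session_id=i)
           for i, v in enumerate(videos)]
    stack, idx = concatenate_sessions(pre)
    return cfg, stack, idx, truth


def batch_equivalence(seed: int = 0) -> dict:
    """Batchwise (one batch per session) vs single-pass extraction of one
    concatenated two-session stack, plus the peak-resident-frame count.
    Sessions are rendered without inter-session misalignment so the
    comparison isolates the batching strategy."""
    cfg, stack, idx, truth = _sim_two_sessions(seed, misalign_amplitude_um=0.0)
    ecfg = ExtractionConfig(batch_frames=cfg.frames_per_session)
    comps_b, info_b = extract_batchwise(stack, idx.bounds, ecfg)
    ecfg_single = ExtractionConfig(batch_frames=stack.shape[0])
    comps_s, info_s = extract_batchwise(stack, [(0, stack.shape[0])], ecfg_single)
    f1_b = match_components(comps_b.A, comps_b.C, truth.footprints,
                            truth.traces).f1
    f1_s = match_components(comps_s.A, comps_s.C, truth.footprints,
                            truth.traces).f1
    return {
        "f1_batchwise": float(f1_b),
        "f1_single_pass": float(f1_s),
        "abs_difference": float(abs(f1_b - f1_s)),
        "max_resident_frames": info_b["max_resident_frames"],
        "batch_frames": ecfg.batch_frames,
        "n_batches": info_b["n_batches"],
    }


def low_snr_benefit(seed: int = 0, tau: float = 0.8) -> dict:
    """30% of neurons have transients damped by 80% in one session:
    detection of the damped-session traces from concatenated extraction vs
    independent per-session extraction."""
    cfg, stack, idx, truth = _sim_two_sessions(seed, snr_drop_fraction=0.3,
                                               misalign_amplitude_um=0.0)
    dropped = np.where((truth.amplitude_scale == 0.2).any(axis=1))[0]
    drop_sess = {int(j): int(np.argmin(truth.amplitude_scale[j])) for j in dropped}
    ecfg = ExtractionConfig(batch_frames=cfg.frames_per_session)
    comps_c, _ = extract_batchwise(stack, idx.bounds, ecfg)
    m_c = match_components(comps_c.A, comps_c.C, truth.footprints, truth.traces,
                           tau=tau)
    inv_c = {j: i for i, j in m_c.assignment}

    sims_concat: dict[int, dict[int, float]] = {0: {}, 1: {}}
    for s, (a, b) in enumerate(idx.bounds):
        for j, i in inv_c.items():
            sims_concat[s][j] = _segment_similarity(comps_c.C[i][a:b],
                                                    truth.traces[j][a:b])
    sims_ind: dict[int, dict[int, float]] = {}
    for s, (a, b) in enumerate(idx.bounds):
        comps_s, _ = extract_batchwise(stack[a:b], [(0, b - a)], ecfg)
        m_s = match_components(comps_s.A, comps_s.C, truth.footprints,
                               truth.traces[:, a:b], tau=tau)
        sims_ind[s] = {j: float(m_s.sim_temporal[i, j])
                       for i, j in m_s.assignment}

    def f1_over(subset_sims, n_truth):
        tp = sum(1 for v in subset_sims if v > tau)
        prec = tp / max(len(subset_sims), 1)
        rec = tp / max(n_truth, 1)
        return 2 * prec * rec / (prec + rec) if prec + rec else 0.0

    low_c = [sims_concat[drop_sess[j]].get(j, 0.0) for j in dropped]
    low_i = [sims_ind[drop_sess[j]].get(j, 0.0) for j in dropped]
    high_c, high_i = [], []
    for j in range(truth.n_neurons):
        for s in (0, 1):
            if j in dropped and drop_sess[int(j)] == s:
                continue
            high_c.append(sims_concat[s].get(j, 0.0))
            high_i.append(sims_ind[s].get(j, 0.0))
    return {
        "f1_low_concat": f1_over(low_c, len(dropped)),
        "f1_low_independent": f1_over(low_i, len(dropped)),
        "mean_low_sim_concat": float(np.mean(low_c)) if low_c else 0.0,
        "mean_low_sim_independent": float(np.mean(low_i)) if low_i else 0.0,
        "f1_high_concat": f1_over(high_c, len(high_c)),
        "f1_high_independent": f1_over(high_i, len(high_i)),
        "high_abs_difference": abs(f1_over(high_c, len(high_c))
                                   - f1_over(high_i, len(high_i))),
        "n_dropped": len(dropped),
    }


def end_to_end(seed: int = 0, out_dir: str | None = None,
               check_reproducible: bool = False) -> dict:
    """Full pipeline (simulate, align, concatenate, extract, sort,
    evaluate) on a misaligned two-session study."""
    import tempfile

    from .pipeline import run_pipeline

    def run(tag):
        cfg = PipelineConfig(
            simulation=SimulationConfig(fov_shape=(96, 128), n_neurons=30,
                                        frames_per_session=600, n_sessions=2,
                                        misalign_amplitude_um=8.0),
            out_dir=out_dir or tempfile.mkdtemp(prefix=f"longcal_{tag}_"),
            seed=seed)
        return run_pipeline(cfg)

    res = run("a")
    out = {
        "f1": res["evaluation"]["f1"],
        "precision": res["evaluation"]["precision"],
        "recall": res["evaluation"]["recall"],
        "n_components": res["n_components"],
        "hashes": res["hashes"],
        "n_frames": 1200,
    }
    if check_reproducible:
        res2 = run("b")
        out["reproducible"] = res2["hashes"] == res["hashes"]
    return out
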