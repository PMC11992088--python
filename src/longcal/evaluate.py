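"""Ground-truth matching and tracking/alignment metrics.

Extracted components are matched to simulated ground-truth neurons by
maximizing the summed spatiotemporal similarity M = Sim_spatial . Sim_temporal
over one-to-one assignments (linear assignment problem); matches whose
temporal similarity exceeds a threshold tau count as true positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .projections import crispness

__all__ = [
    "MatchResult",
    "match_components",
    "centroid_distances",
    "alignment_metrics",
    "population_vector_distance",
]

TAU_DEFAULT = 0.8


@dataclass
class MatchResult:
    sim_spatial: np.ndarray    # K_e x K_s
    sim_temporal: np.ndarray   # K_e x K_s
    M: np.ndarray              # elementwise product
    assignment: list[tuple[int, int]]
    tp_set: list[tuple[int, int]]
    tau: float
    precision: float
    recall: float
    f1: float


def _cosine_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    nx = np.linalg.norm(X, axis=1)
    ny = np.linalg.norm(Y, axis=1)
    nx[nx == 0] = 1.0
    ny[ny == 0] = 1.0
    return np.clip((X / nx[:, None]) @ (Y / ny[:, None]).T, 0.0, 1.0)


def match_components(A_extracted: np.ndarray, C_extracted: np.ndarray,
                     A_truth: np.ndarray, C_truth: np.ndarray,
                     tau: float = TAU_DEFAULT) -> MatchResult:
    """Optimal one-to-one matching of extracted components to ground truth.

    Cosine similarity matrices on footprints and on denoised traces are
    multiplied elementwise; the assignment maximizing the total similarity
    is solved exactly. Unmatched components count as similarity zero.
    Precision is TP over extracted count, recall TP over truth count.
    """
    Ke, Ks = A_extracted.shape[0], A_truth.shape[0]
    if Ke == 0 or Ks == 0:
        Z = np.zeros((Ke, Ks))
        return MatchResult(Z, Z, Z, [], [], tau, 0.0, 0.0, 0.0)
    sim_sp = _cosine_matrix(A_extracted, A_truth)
    sim_tp = _cosine_matrix(C_extracted, C_truth)
    M = sim_sp * sim_tp
    rows, cols = linear_sum_assignment(-M)
    assignment = list(zip(rows.tolist(), cols.tolist()))
    tp = [(i, j) for i, j in assignment if sim_tp[i, j] > tau]
    precision = len(tp) / Ke
    recall = len(tp) / Ks
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MatchResult(sim_sp, sim_tp, M, assignment, tp, tau,
                       precision, recall, f1)


def match_to_truth(comps, truth, tau: float = TAU_DEFAULT) -> MatchResult:
    """Match an extracted :class:`~longcal.extract.ComponentSet` against a
    simulator :class:`~longcal.simulate.GroundTruth` record."""
    return match_components(comps.A, comps.C, truth.footprints, truth.traces,
                            tau=tau)


def _weighted_centroids(A: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    imgs = A.reshape((-1, h, w))
    tot = imgs.sum(axis=(1, 2))
    tot[tot == 0] = 1.0
    return np.stack([(imgs * yy).sum(axis=(1, 2)) / tot,
                     (imgs * xx).sum(axis=(1, 2)) / tot], axis=1)


def centroid_distances(match: MatchResult, A_extracted: np.ndarray,
                       A_truth: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Euclidean distance between intensity-weighted centroids of each
    matched extracted/truth footprint pair, in pixels."""
    ce = _weighted_centroids(A_extracted, shape)
    cs = _weighted_centroids(A_truth, shape)
    return np.array([np.hypot(*(ce[i] - cs[j])) for i, j in match.assignment])


def alignment_metrics(aligned_projections: list[np.ndarray]) -> dict:
    """Mean pairwise spatial (Pearson) correlation across sessions plus
    crispness of the mean aligned projection."""
    if len(aligned_projections) < 2:
        raise ValueError("need at least 2 aligned projections")
    cors = []
    n = len(aligned_projections)
    for i in range(n):
        for j in range(i + 1, n):
            a = np.asarray(aligned_projections[i], float).ravel()
            b = np.asarray(aligned_projections[j], float).ravel()
            cors.append(float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0
                        else 0.0)
    return {
        "spatial_correlation": float(np.mean(cors)),
        "crispness": crispness(np.mean(aligned_projections, axis=0)),
    }


def population_vector_distance(activity: np.ndarray,
                               session_bounds: list[tuple[int, int]],
                               zero_fill: bool = False,
                               detected: np.ndarray | None = None) -> float:
    """Excess of inter-session over intra-session correlation distance
    between mean-activity population vectors.

    Each session is split in half and the mean activity per neuron per half
    forms one population vector; PVD = mean(1 - r) over inter-session half
    pairs minus mean(1 - r) over intra-session half pairs. Larger values
    mean less stable population activity. Neurons not detected in all
    sessions are excluded unless ``zero_fill`` keeps them with zero
    activity (``detected`` is a K x n_sessions boolean mask).
    """
    activity = np.asarray(activity, dtype=float)
    n_sessions = len(session_bounds)
    if n_sessions < 2:
        raise ValueError("population_vector_distance needs >= 2 sessions")
    if detected is not None and not zero_fill:
        activity = activity[np.asarray(detected, bool).all(axis=1)]
    if activity.shape[0] == 0:
        return 0.0
    vectors = []
    labels = []
    for s, (a, b) in enumerate(session_bounds):
        mid = (a + b) // 2
        vectors.append(activity[:, a:mid].mean(axis=1))
        vectors.append(activity[:, mid:b].mean(axis=1))
        labels.extend([s, s])
    V = np.stack(vectors)
    intra, inter = [], []
    for i in range(len(V)):
        for j in range(i + 1, len(V)):
            si, sj = V[i].std(), V[j].std()
            r = float(np.corrcoef(V[i], V[j])[0, 1]) if si > 0 and sj > 0 else 0.0
            (intra if labels[i] == labels[j] else inter).append(1.0 - r)
    return float(np.mean(inter) - np.mean(intra))
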