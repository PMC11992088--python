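"""Rank extracted components by spatial congruence so likely
false-positives surface last.

Somatic footprints share a compact blob shape; dendrites and other
non-somatic structures do not. Pairwise cosine distances between footprints
are embedded by classical multidimensional scaling, and each component's
Mahalanobis distance from the accepted-set centroid in that embedding ranks
it: small distances are shape-consistent, large ones are suspect. Manually
discarding outliers and re-ranking refines the centroid estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SortModel", "cosine_mds_embed", "mahalanobis_rank"]


@dataclass
class SortModel:
    D_c: np.ndarray                  # K x K cosine distances
    Y: np.ndarray                    # K x d embedding
    mu: np.ndarray                   # accepted-set mean in the embedding
    cov: np.ndarray                  # accepted-set covariance
    m_d: np.ndarray                  # per-component Mahalanobis distances
    ranking: np.ndarray              # component indices, most shape-consistent first
    accepted_labels: np.ndarray | None = None
    stress: float = 0.0


def center_footprints(A: np.ndarray, fov_shape: tuple[int, int]) -> np.ndarray:
    """Shift each footprint so its intensity-weighted centroid sits at the
    FOV center. Cosine distances between centered footprints compare shape
    rather than location (two identical somata at opposite corners would
    otherwise be maximally distant)."""
    h, w = fov_shape
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.empty_like(A)
    for k, row in enumerate(A):
        img = row.reshape(h, w)
        tot = img.sum()
        if tot == 0:
            out[k] = row
            continue
        cy = (img * yy).sum() / tot
        cx = (img * xx).sum() / tot
        out[k] = np.roll(img, (int(round(h / 2 - cy)), int(round(w / 2 - cx))),
                         axis=(0, 1)).ravel()
    return out


def cosine_distance_matrix(A: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(A, axis=1)
    bad = np.where(norms == 0)[0]
    if bad.size:
        raise ValueError(f"zero-norm footprint for component(s) {bad.tolist()}")
    G = (A / norms[:, None]) @ (A / norms[:, None]).T
    D = 1.0 - np.clip(G, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return D


def cosine_mds_embed(A: np.ndarray, dims: int = 2,
                     fov_shape: tuple[int, int] | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Cosine distances between footprints embedded by classical
    (Torgerson) MDS. When ``fov_shape`` is given footprints are centered
    first (shape comparison); otherwise rows are compared as-is. Returns
    (D_c, Y, stress) with stress the summed squared discrepancy between
    input and embedded distances."""
    A = np.asarray(A, dtype=float)
    if A.shape[0] < 3:
        raise ValueError("need at least 3 components to embed")
    if fov_shape is not None:
        A = center_footprints(A, fov_shape)
    D = cosine_distance_matrix(A)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    Y = vecs[:, order] * np.sqrt(lam)[None, :]
    D_hat = np.sqrt(np.maximum(
        ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2), 0.0))
    stress = float(((D - D_hat) ** 2).sum())
    return D, Y, stress


def mahalanobis_rank(Y: np.ndarray,
                     accepted_labels: np.ndarray | None = None,
                     D_c: np.ndarray | None = None,
                     ridge: float = 1e-8) -> SortModel:
    """Rank components by Mahalanobis distance

        M_d(y) = (y - mu)^T Sigma^{-1} (y - mu)

    with mu, Sigma estimated from the accepted set (all components on the
    first pass). Re-calling with user labels recomputes mu, Sigma and the
    ranking. A singular covariance is ridge-regularized with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    if accepted_labels is None:
        accepted = np.ones(Y.shape[0], dtype=bool)
    else:
        accepted = np.asarray(accepted_labels, dtype=bool)
        if accepted.sum() <= Y.shape[1]:
            raise ValueError("accepted set must span the embedding dimensions")
    mu = Y[accepted].mean(axis=0)
    cov = np.cov(Y[accepted].T, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; applying ridge regularization")
        cov = cov + ridge * np.eye(cov.shape[0])
        inv = np.linalg.inv(cov)
    diff = Y - mu
    m_d = np.einsum("ij,jk,ik->i", diff, inv, diff)
    ranking = np.argsort(m_d, kind="stable")
    return SortModel(D_c=D_c if D_c is not None else np.zeros((0, 0)),
                     Y=Y, mu=mu, cov=cov, m_d=m_d, ranking=ranking,
                     accepted_labels=None if accepted_labels is None else accepted)


def sort_components(A: np.ndarray, dims: int = 2,
                    accepted_labels: np.ndarray | None = None,
                    fov_shape: tuple[int, int] | None = None) -> SortModel:
    """Convenience wrapper: embed footprints then rank by Mahalanobis distance."""
    if fov_shape is None and A.shape[0]:
        # assume square FOV when not told; centering only needs a consistent
        # reshape, and extraction always passes the true shape
        side = int(round(np.sqrt(A.shape[1])))
        fov_shape = (side, A.shape[1] // side) if side * side == A.shape[1] else None
    D, Y, stress = cosine_mds_embed(A, dims=dims, fov_shape=fov_shape)
    model = mahalanobis_rank(Y, accepted_labels, D_c=D)
    model.stress = stress
    return model
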