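"""Triple self-supervised clustering: Student-t soft assignments, the
sharpened target distribution, and the KL alignment losses.

A Student-t kernel turns distances between embeddings and cluster centers
into a soft assignment Q; squaring and frequency-normalizing Q yields the
target P, which emphasizes high-confidence cells while discounting large
clusters.  The branch embeddings Z_AE and Z_IGAE get their own assignments
Q'' and Q' against the *same* centers, and the triple loss aligns the
equal-weight mixture (Q + Q' + Q'')/3 with P:

    L_KL = sum_ij p_ij log( p_ij / ((q_ij + q'_ij + q''_ij)/3) )

The kernel uses the squared euclidean distance by default (the canonical
choice for this family; the literal unsquared distance is available via
``squared=False``), with one degree of freedom v = 1.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from ._exceptions import ParameterError

__all__ = [
    "init_centers",
    "soft_assign",
    "target_distribution",
    "clu_loss",
    "triple_kl_loss",
    "hard_labels",
]

_EPS = 1e-12


def init_centers(z: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means++ centers on the fused embedding; deterministic given seed."""
    from sklearn.cluster import KMeans

    n = z.shape[0]
    if not (2 <= k <= n):
        raise ParameterError(f"need 2 <= k <= n_cells, got k={k}, n={n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    km.fit(np.asarray(z, dtype=float))
    return km.cluster_centers_


def soft_assign(z, centers, v: float = 1.0, squared: bool = True):
    """Student-t soft assignment of embeddings to centers.

    q_ij is proportional to (1 + dist(z_i, mu_j)/v)^(-(v+1)/2) with dist the
    squared euclidean distance by default; rows are normalized to 1.
    """
    if v <= 0:
        raise ParameterError("degrees of freedom v must be > 0")
    diff = z[:, None, :] - centers[None, :, :]
    sq = anp.sum(diff**2, axis=2)
    dist = sq if squared else anp.sqrt(sq + _EPS)
    kernel = (1.0 + dist / v) ** (-(v + 1.0) / 2.0)
    return kernel / anp.sum(kernel, axis=1, keepdims=True)


def target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened target P: p_ij ∝ q_ij^2 / f_j with f_j the soft frequency.

    Clusters with zero soft frequency are dropped from the normalization
    (with a warning) rather than producing NaN.
    """
    q = np.asarray(q, dtype=float)
    f = q.sum(axis=0)
    if np.any(f == 0):
        import warnings

        warnings.warn("degenerate cluster with zero soft frequency", RuntimeWarning)
    weight = np.where(f > 0, q**2 / np.where(f > 0, f, 1.0), 0.0)
    return weight / weight.sum(axis=1, keepdims=True)


def clu_loss(p, q):
    """KL(P || Q) with 0 log 0 treated as 0 and an epsilon clamp inside logs."""
    p_arr = p
    return anp.sum(p_arr * (anp.log(p_arr + _EPS) - anp.log(q + _EPS)))


def triple_kl_loss(p, q_fused, q_igae, q_ae):
    """KL between the target P and the mixture (Q + Q' + Q'')/3."""
    mix = (q_fused + q_igae + q_ae) / 3.0
    return clu_loss(p, mix)


def hard_labels(q: np.ndarray) -> np.ndarray:
    """Argmax cluster per cell from the fused soft assignment."""
    return np.asarray(q).argmax(axis=1)
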