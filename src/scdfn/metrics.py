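"""Clustering and embedding-quality metrics: NMI, ARI, ASW, cLISI.

NMI and ARI compare two labelings; ASW and cLISI judge how well an embedding
separates known cell types.  cLISI is the cell-type local inverse Simpson's
index: for each cell, neighbors are weighted by a Gaussian kernel whose
bandwidth is calibrated to a target perplexity, the inverse Simpson index of
the label proportions under those weights is computed (1 = locally pure,
K = perfectly mixed), and the per-cell values are rescaled to [0, 1] as
(K_true - LISI)/(K_true - 1) and averaged, so 1 means perfect local purity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ._exceptions import ParameterError, ValidationError

__all__ = ["EvalReport", "nmi", "ari", "asw", "clisi", "evaluate"]


@dataclass
class EvalReport:
    nmi: float
    ari: float
    asw: float | None
    clisi: float | None
    n_cells: int
    k_true: int
    k_pred: int

    def to_text(self) -> str:
        lines = []
        for key, val in asdict(self).items():
            lines.append(f"{key}\t{'' if val is None else val}")
        return "\n".join(lines) + "\n"


def _check_labels(labels_true, labels_pred):
    a = np.asarray(labels_true)
    b = np.asarray(labels_pred)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"label vectors must be equal-length 1-d, got {a.shape} vs {b.shape}"
        )
    if a.size < 2:
        raise ValidationError("need at least 2 cells")
    return a, b


def nmi(labels_true, labels_pred, average_method: str = "arithmetic") -> float:
    """Normalized mutual information, MI / mean(H_true, H_pred).

    The arithmetic mean of entropies is the default normalization; the
    geometric variant is available since the convention is not universal.
    """
    from sklearn.metrics import normalized_mutual_info_score

    a, b = _check_labels(labels_true, labels_pred)
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


def ari(labels_true, labels_pred) -> float:
    """Adjusted Rand index: (RI - E[RI]) / (max RI - E[RI])."""
    from sklearn.metrics import adjusted_rand_score

    a, b = _check_labels(labels_true, labels_pred)
    return float(adjusted_rand_score(a, b))


def asw(embedding, labels) -> float:
    """Average silhouette width under euclidean distance.

    Singleton clusters contribute silhouette 0 by convention.
    """
    from sklearn.metrics import silhouette_samples

    x = np.asarray(embedding, dtype=float)
    lab = np.asarray(labels)
    if len(np.unique(lab)) < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    sil = silhouette_samples(x, lab)
    # scikit-learn defines singleton silhouettes as 0 already
    return float(sil.mean())


def _perplexity_weights(dists: np.ndarray, perplexity: float, tol: float = 1e-5,
                        max_iter: int = 64) -> np.ndarray:
    """Gaussian weights over one cell's neighbors with entropy = log(perplexity).

    Binary search on the precision beta, as in SNE-style calibrations.
    Degenerate rows (all distances equal) fall back to uniform weights.
    """
    target = np.log(perplexity)
    if np.ptp(dists) == 0:
        return np.full_like(dists, 1.0 / dists.size)
    beta_lo, beta_hi, beta = 0.0, np.inf, 1.0 / (np.mean(dists) + 1e-12)
    for _ in range(max_iter):
        w = np.exp(-beta * (dists - dists.min()))
        sw = w.sum()
        p = w / sw
        h = -np.sum(p * np.log(p + 1e-300))
        if abs(h - target) < tol:
            break
        if h > target:  # too flat -> increase precision
            beta_lo = beta
            beta = beta * 2 if beta_hi == np.inf else 0.5 * (beta + beta_hi)
        else:
            beta_hi = beta
            beta = 0.5 * (beta + beta_lo)
    return p


def clisi(embedding, labels, perplexity: float | None = None,
          return_raw: bool = False):
    """Cell-type local inverse Simpson's index, rescaled to [0, 1].

    Per cell, LISI_i = 1 / sum_l p_l(i)^2 where p_l(i) is the kernel-weighted
    proportion of label l among the other cells.  The reported score is
    mean_i (K_true - LISI_i) / (K_true - 1): 1 = every neighborhood is pure,
    0 = neighborhoods as mixed as the global label set allows.
    """
    from scipy.spatial.distance import squareform, pdist

    x = np.asarray(embedding, dtype=float)
    lab = np.asarray(labels)
    n = x.shape[0]
    uniq, lab_idx = np.unique(lab, return_inverse=True)
    k_true = len(uniq)
    if k_true < 2:
        return (1.0, np.ones(n)) if return_raw else 1.0
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    if not (0 < perplexity < n):
        raise ParameterError("perplexity must be in (0, n_cells)")
    d2 = squareform(pdist(x, "sqeuclidean"))
    lisi = np.empty(n)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        w = _perplexity_weights(d2[i][mask[i]], perplexity)
        props = np.bincount(lab_idx[mask[i]], weights=w, minlength=k_true)
        lisi[i] = 1.0 / np.sum(props**2)
    score = float(np.mean((k_true - lisi) / (k_true - 1)))
    score = float(np.clip(score, 0.0, 1.0))
    return (score, lisi) if return_raw else score


def evaluate(labels_true, labels_pred, embedding=None,
             perplexity: float | None = None) -> EvalReport:
    """Bundle all four metrics into one report.

    ASW and cLISI need the embedding; they are None when it is not given.
    """
    a, b = _check_labels(labels_true, labels_pred)
    return EvalReport(
        nmi=nmi(a, b),
        ari=ari(a, b),
        asw=asw(embedding, b) if embedding is not None else None,
        clisi=clisi(embedding, a, perplexity) if embedding is not None else None,
        n_cells=a.size,
        k_true=len(np.unique(a)),
        k_pred=len(np.unique(b)),
    )
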