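"""Attribute-topology information fusion (ATIF).

The two branch embeddings are combined in three steps:

1. convex combination          Z_I = alpha Z_AE + (1 - alpha) Z_IGAE
2. local graph propagation     Z_L = Ā Z_I
3. global self-correlation     S   = row-softmax(Z_L Z_L^T),
                               Z~  = beta (S Z_L) + Z_L

alpha is stored unconstrained and squashed through a sigmoid so the convex
reading always holds; it starts at 0.5 (raw 0).  beta starts at 0, so
training begins from the pure locally propagated embedding.  The Gram matrix
uses unnormalized dot products; the softmax subtracts the row max, which
changes nothing mathematically (softmax shift invariance) but guards
overflow.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from ._exceptions import ConfigurationError

__all__ = [
    "fuse_initial",
    "propagate_local",
    "self_correlation",
    "enhance_global",
    "fuse",
    "alpha_from_raw",
]


def alpha_from_raw(alpha_raw):
    """Sigmoid squashing of the unconstrained fusion weight; raw 0 -> 0.5."""
    return 0.5 * (anp.tanh(0.5 * alpha_raw) + 1.0)


def fuse_initial(z_ae, z_igae, alpha):
    """Z_I = alpha Z_AE + (1 - alpha) Z_IGAE."""
    if isinstance(z_ae, np.ndarray) and isinstance(z_igae, np.ndarray):
        if z_ae.shape != z_igae.shape:
            raise ConfigurationError(
                f"branch embeddings disagree: {z_ae.shape} vs {z_igae.shape}"
            )
    return alpha * z_ae + (1.0 - alpha) * z_igae


def propagate_local(z_i, a_norm):
    """Z_L = Ā Z_I — one step of message passing over the cell graph."""
    return anp.dot(a_norm, z_i)


def self_correlation(z_l):
    """Row-stochastic self-correlation S = row-softmax(Z_L Z_L^T)."""
    gram = anp.dot(z_l, anp.swapaxes(z_l, 0, 1))
    gram = gram - anp.max(gram, axis=1, keepdims=True)
    e = anp.exp(gram)
    return e / anp.sum(e, axis=1, keepdims=True)


def enhance_global(z_l, s, beta):
    """Z~ = beta (S Z_L) + Z_L — global enhancement of the local embedding."""
    return beta * anp.dot(s, z_l) + z_l


def fuse(z_ae, z_igae, a_norm, alpha, beta):
    """Full fusion chain; returns (z_i, z_l, s, z_tilde)."""
    z_i = fuse_initial(z_ae, z_igae, alpha)
    z_l = propagate_local(z_i, a_norm)
    s = self_correlation(z_l)
    z_tilde = enhance_global(z_l, s, beta)
    return z_i, z_l, s, z_tilde
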