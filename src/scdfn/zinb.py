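"""Zero-inflated negative binomial (ZINB) likelihood for raw counts.

scRNA-seq counts are overdispersed and zero-inflated: technical dropout adds
a point mass at zero on top of a negative binomial.  The model

    ZINB(x | pi, mu, theta) = pi * delta_0(x) + (1 - pi) * NB(x | mu, theta)

is used as the reconstruction likelihood of the *raw* counts (HVG subset).
A shallow decoder maps the fused embedding to a hidden representation, from
which three parallel affine heads produce the parameters:

    Pi    = sigmoid(W_pi  h)          dropout probability, in (0, 1)
    M     = s_i * exp(W_mu h)         mean, scaled by the per-cell size factor
    Theta = exp(W_theta h)            dispersion, clamped to [1e-4, 1e4]

The loss is the mean (over matrix entries) negative log-likelihood, so its
scale does not depend on the matrix size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd.scipy.special import gammaln

from ._exceptions import ConfigurationError, ValidationError
from .networks import _activation, _glorot, _sigmoid

__all__ = [
    "ZINBParams",
    "ZINBDecoder",
    "init_zinb_decoder",
    "zinb_heads",
    "nb_log_pmf",
    "zinb_log_pmf",
    "zinb_nll",
]

THETA_MIN, THETA_MAX = 1e-4, 1e4
_PI_EPS = 1e-6
_EXP_CLAMP = 12.0  # exp(±12) spans ~1e-6..1.6e5, ample for counts


@dataclass
class ZINBParams:
    """Per-cell-per-gene ZINB parameters (all N x d')."""

    pi: anp.ndarray
    mu: anp.ndarray
    theta: anp.ndarray


@dataclass
class ZINBDecoder:
    """Shallow decoder from the fused embedding plus three parameter heads."""

    dims: list[int]  # latent -> hidden widths -> (heads map last width -> d')
    n_genes: int
    activation: str = "leaky_relu"
    params: dict = field(default_factory=dict)


def init_zinb_decoder(
    latent_dim: int, n_genes: int, hidden: int = 128, seed: int = 0,
    activation: str = "leaky_relu",
) -> ZINBDecoder:
    rng = np.random.default_rng(seed)
    dims = [latent_dim, hidden]
    body = [
        {"W": _glorot(rng, a, b), "b": np.zeros(b)}
        for a, b in zip(dims[:-1], dims[1:])
    ]
    heads = {
        name: {"W": _glorot(rng, hidden, n_genes), "b": np.zeros(n_genes)}
        for name in ("pi", "mu", "theta")
    }
    return ZINBDecoder(
        dims=dims, n_genes=n_genes, activation=activation,
        params={"body": body, **heads},
    )


def zinb_heads(params: dict, z, size_factors, activation: str = "leaky_relu") -> ZINBParams:
    """Run the shallow decoder and the three heads.

    With all-zero weights this yields pi = 0.5, mu = size_factor, theta = 1 —
    a sane neutral starting point.  Exponent inputs are clamped so extreme
    activations cannot overflow, and theta is clamped to [1e-4, 1e4].
    """
    act = _activation(activation)
    h = z
    for layer in params["body"]:
        h = act(anp.dot(h, layer["W"]) + layer["b"])
    def head(name):
        return anp.dot(h, params[name]["W"]) + params[name]["b"]

    pi = _sigmoid(head("pi"))
    pi = anp.clip(pi, _PI_EPS, 1.0 - _PI_EPS)
    sf = anp.reshape(size_factors, (-1, 1))
    mu = sf * anp.exp(anp.clip(head("mu"), -_EXP_CLAMP, _EXP_CLAMP))
    theta = anp.clip(
        anp.exp(anp.clip(head("theta"), -_EXP_CLAMP, _EXP_CLAMP)),
        THETA_MIN, THETA_MAX,
    )
    return ZINBParams(pi=pi, mu=mu, theta=theta)


def nb_log_pmf(x, mu, theta):
    """log NB(x | mu, theta) via log-gamma arithmetic.

    NB(x) = Gamma(x+theta)/(x! Gamma(theta)) (theta/(theta+mu))^theta
            (mu/(theta+mu))^x
    """
    x = anp.asarray(x, dtype=float) if isinstance(x, (int, float, np.ndarray, list)) else x
    log_theta_mu = anp.log(theta + mu)
    return (
        gammaln(x + theta) - gammaln(x + 1.0) - gammaln(theta)
        + theta * (anp.log(theta) - log_theta_mu)
        + x * (anp.log(mu) - log_theta_mu)
    )


def zinb_log_pmf(x, pi, mu, theta):
    """log ZINB(x); the x = 0 branch uses log-sum-exp for stability."""
    x = anp.asarray(x, dtype=float) if isinstance(x, (int, float, np.ndarray, list)) else x
    nb_ll = nb_log_pmf(x, mu, theta)
    nb_zero = theta * (anp.log(theta) - anp.log(theta + mu))
    log_zero = anp.logaddexp(anp.log(pi), anp.log1p(-pi) + nb_zero)
    log_pos = anp.log1p(-pi) + nb_ll
    return anp.where(x < 0.5, log_zero, log_pos)


def zinb_nll(x_raw, params: ZINBParams):
    """Mean negative log-likelihood of raw counts under the ZINB model."""
    x = np.asarray(x_raw, dtype=float) if isinstance(x_raw, np.ndarray) else x_raw
    if isinstance(x, np.ndarray):
        if np.any(x < 0) or not np.allclose(x, np.round(x)):
            raise ValidationError("ZINB target must be non-negative integer counts")
        if isinstance(params.mu, np.ndarray) and x.shape != params.mu.shape:
            raise ConfigurationError(
                f"counts {x.shape} do not match ZINB params {params.mu.shape}"
            )
    ll = zinb_log_pmf(x, params.pi, params.mu, params.theta)
    return -anp.mean(ll)
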