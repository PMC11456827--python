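"""Attribute autoencoder (AE) and improved graph autoencoder (IGAE).

Both branches are expressed as pure functions of a parameter dictionary so
that reverse-mode automatic differentiation (autograd) can differentiate any
training objective assembled from them.  The AE is a plain fully connected
autoencoder on the processed expression matrix; the IGAE is a symmetric
graph-convolutional autoencoder whose every layer propagates through the
normalized adjacency, Z^(l) = sigma(Ā Z^(l-1) W^(l)), and which reconstructs
both the weighted attribute matrix ĀX and the adjacency.

IGAE losses:
    L_w    = 1/(2N) ||Ā X - Ẑ||_F^2
    L_a    = 1/(2N) ||Ā - Â||_F^2
    L_IGAE = L_w + gamma * L_a          (gamma = 0.1 by default)

The printed form of L_w in the source family omits the square; the squared
Frobenius norm is the default here for consistency with L_a, with the
unsquared variant behind ``squared=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from ._exceptions import ConfigurationError, NumericalError

__all__ = [
    "AEModel",
    "IGAEModel",
    "init_ae",
    "init_igae",
    "ae_forward",
    "ae_decode",
    "ae_loss",
    "igae_encode",
    "igae_decode",
    "igae_forward",
    "igae_loss",
    "save_weights",
    "load_weights",
]

CHECKPOINT_VERSION = "1"


def save_weights(path: str, params: dict) -> None:
    """Save a (nested) parameter dictionary to a single .npz archive.

    The archive carries a format version field; nested dicts/lists are
    flattened to slash-separated keys.
    """
    flat: dict[str, np.ndarray] = {}

    def walk(prefix, obj):
        if isinstance(obj, dict):
            for k, v in obj.items():
                walk(f"{prefix}/{k}" if prefix else str(k), v)
        elif isinstance(obj, (list, tuple)):
            for i, v in enumerate(obj):
                walk(f"{prefix}/{i}", v)
        else:
            flat[prefix] = np.asarray(obj)

    walk("", params)
    np.savez(path, checkpoint_version=np.array(CHECKPOINT_VERSION), **flat)


def load_weights(path: str) -> dict:
    """Inverse of :func:`save_weights`; validates the version field."""
    with np.load(path, allow_pickle=False) as f:
        if "checkpoint_version" not in f:
            raise ConfigurationError(f"{path} is not a weight checkpoint")
        version = str(f["checkpoint_version"])
        if version != CHECKPOINT_VERSION:
            raise ConfigurationError(
                f"unsupported checkpoint version {version!r}")
        items = {k: f[k] for k in f.files if k != "checkpoint_version"}

    root: dict = {}
    for key, arr in items.items():
        parts = key.split("/")
        node = root
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = arr

    def listify(node):
        if not isinstance(node, dict):
            return node[()] if node.ndim == 0 else node
        node = {k: listify(v) for k, v in node.items()}
        if node and all(k.isdigit() for k in node):
            return [node[str(i)] for i in range(len(node))]
        return node

    return listify(root)

# ---------------------------------------------------------------- activations


def _activation(name: str):
    if name == "leaky_relu":
        return lambda z: anp.where(z > 0, z, 0.2 * z)
    if name == "linear":
        return lambda z: z
    if name == "relu":
        return lambda z: anp.maximum(z, 0.0)
    raise ConfigurationError(f"unknown activation {name!r}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _check_finite(arr, where: str) -> None:
    # skipped while autograd is tracing (boxed values are not ndarrays)
    if isinstance(arr, np.ndarray) and not np.isfinite(arr).all():
        raise NumericalError(f"non-finite activations in {where}")


# ------------------------------------------------------------------------- AE


@dataclass
class AEModel:
    """Fully connected autoencoder; decoder dims mirror the encoder."""

    encoder_dims: list[int]
    activation: str = "leaky_relu"
    params: dict = field(default_factory=dict)

    @property
    def decoder_dims(self) -> list[int]:
        return list(reversed(self.encoder_dims))

    @property
    def latent_dim(self) -> int:
        return self.encoder_dims[-1]

    def forward(self, x):
        return ae_forward(self.params, x, self.activation)


def init_ae(
    encoder_dims: list[int], seed: int = 0, activation: str = "leaky_relu"
) -> AEModel:
    """Glorot-initialized AE with the given encoder widths (input first)."""
    rng = np.random.default_rng(seed)
    enc = [
        {"W": _glorot(rng, a, b), "b": np.zeros(b)}
        for a, b in zip(encoder_dims[:-1], encoder_dims[1:])
    ]
    dims_r = list(reversed(encoder_dims))
    dec = [
        {"W": _glorot(rng, a, b), "b": np.zeros(b)}
        for a, b in zip(dims_r[:-1], dims_r[1:])
    ]
    return AEModel(encoder_dims=list(encoder_dims), activation=activation,
                   params={"enc": enc, "dec": dec})


def _mlp(layers, x, act, final_linear: bool = True):
    h = x
    for i, layer in enumerate(layers):
        h = anp.dot(h, layer["W"]) + layer["b"]
        if not (final_linear and i == len(layers) - 1):
            h = act(h)
    return h


def ae_encode(params: dict, x, activation: str = "leaky_relu"):
    return _mlp(params["enc"], x, _activation(activation))


def ae_decode(params: dict, z, activation: str = "leaky_relu"):
    return _mlp(params["dec"], z, _activation(activation))


def ae_forward(params: dict, x, activation: str = "leaky_relu"):
    """Return (z_ae, x_hat). Hidden layers use the activation; the latent and
    output layers are linear."""
    if isinstance(x, np.ndarray) and x.shape[1] != params["enc"][0]["W"].shape[0]:
        raise ConfigurationError(
            f"input has {x.shape[1]} features, encoder expects "
            f"{params['enc'][0]['W'].shape[0]}"
        )
    z = ae_encode(params, x, activation)
    x_hat = ae_decode(params, z, activation)
    _check_finite(z, "AE encoder")
    return z, x_hat


def ae_loss(x, x_hat):
    """Mean squared reconstruction error, 1/(2N) ||X - X̂||_F^2."""
    if isinstance(x, np.ndarray) and isinstance(x_hat, np.ndarray):
        if x.shape != x_hat.shape:
            raise ConfigurationError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    n = x.shape[0]
    return anp.sum((x - x_hat) ** 2) / (2.0 * n)


# ----------------------------------------------------------------------- IGAE


@dataclass
class IGAEModel:
    """Symmetric graph-convolutional autoencoder.

    Every encoder/decoder layer propagates through Ā.  The adjacency is
    reconstructed from multi-level encoder representations, each projected to
    the latent width, summed and passed through a sigmoid inner product
    (``adj_recon="multilevel"``); ``"latent"`` uses the final latent alone.
    """

    encoder_dims: list[int]
    gamma: float = 0.1
    activation: str = "leaky_relu"
    adj_recon: str = "multilevel"
    params: dict = field(default_factory=dict)

    @property
    def latent_dim(self) -> int:
        return self.encoder_dims[-1]


def init_igae(
    encoder_dims: list[int],
    seed: int = 0,
    gamma: float = 0.1,
    activation: str = "leaky_relu",
    adj_recon: str = "multilevel",
) -> IGAEModel:
    if gamma < 0:
        raise ConfigurationError("gamma must be non-negative")
    rng = np.random.default_rng(seed)
    enc = [{"W": _glorot(rng, a, b)} for a, b in zip(encoder_dims[:-1], encoder_dims[1:])]
    dims_r = list(reversed(encoder_dims))
    dec = [{"W": _glorot(rng, a, b)} for a, b in zip(dims_r[:-1], dims_r[1:])]
    d_lat = encoder_dims[-1]
    proj = [{"P": _glorot(rng, w, d_lat)} for w in encoder_dims[1:]]
    return IGAEModel(
        encoder_dims=list(encoder_dims), gamma=gamma, activation=activation,
        adj_recon=adj_recon,
        params={"enc": enc, "dec": dec, "proj": proj},
    )


def igae_encode(
    params: dict, x, a_norm, activation: str = "leaky_relu",
    return_all: bool = False,
):
    """Z^(l) = sigma(Ā Z^(l-1) W^(l)); Z^(0) = X; final layer linear."""
    act = _activation(activation)
    outs = []
    h = x
    n_layers = len(params["enc"])
    for i, layer in enumerate(params["enc"]):
        h = anp.dot(anp.dot(a_norm, h), layer["W"])
        if i < n_layers - 1:
            h = act(h)
        if isinstance(h, np.ndarray) and not np.isfinite(h).all():
            raise NumericalError(f"non-finite activations in IGAE encoder layer {i}")
        outs.append(h)
    return (h, outs) if return_all else h


def _sigmoid(z):
    return 0.5 * (anp.tanh(0.5 * z) + 1.0)


def igae_decode(
    params: dict, z, a_norm, activation: str = "leaky_relu",
    enc_outputs=None,
):
    """Mirror the encoder and reconstruct the adjacency.

    Returns (z_hat, a_hat).  a_hat is the sigmoid inner product of the sum of
    per-layer encoder outputs projected to the latent width when
    ``enc_outputs`` is given, otherwise of the latent z alone; either way
    a_hat is symmetric with entries in (0, 1).
    """
    act = _activation(activation)
    h = z
    n_layers = len(params["dec"])
    for i, layer in enumerate(params["dec"]):
        h = anp.dot(anp.dot(a_norm, h), layer["W"])
        if i < n_layers - 1:
            h = act(h)
    z_hat = h
    if enc_outputs is not None:
        u = sum(anp.dot(o, p["P"]) for o, p in zip(enc_outputs, params["proj"]))
    else:
        u = z
    a_hat = _sigmoid(anp.dot(u, anp.swapaxes(u, 0, 1)))
    return z_hat, a_hat


def igae_forward(
    params: dict, x, a_norm, activation: str = "leaky_relu",
    adj_recon: str = "multilevel", z_override=None,
):
    """Full IGAE pass: (z_igae, z_hat, a_hat).

    ``z_override`` lets a fused embedding replace z_igae as decoder input,
    which is how the cross-network fusion feeds reconstructions.
    """
    z, outs = igae_encode(params, x, a_norm, activation, return_all=True)
    dec_in = z if z_override is None else z_override
    z_hat, a_hat = igae_decode(
        params, dec_in, a_norm, activation,
        enc_outputs=outs if adj_recon == "multilevel" else None,
    )
    return z, z_hat, a_hat


def igae_loss(x, a_norm, z_hat, a_hat, gamma: float = 0.1, squared: bool = True):
    """(L_w, L_a, L_IGAE): weighted-attribute + adjacency reconstruction."""
    n = x.shape[0]
    ax = anp.dot(a_norm, x)
    if squared:
        l_w = anp.sum((ax - z_hat) ** 2) / (2.0 * n)
    else:
        l_w = anp.sqrt(anp.sum((ax - z_hat) ** 2) + 1e-30) / (2.0 * n)
    l_a = anp.sum((a_norm - a_hat) ** 2) / (2.0 * n)
    return l_w, l_a, l_w + gamma * l_a
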