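"""The deep fusion-network clustering model and its results object.

:class:`SCDFN` bundles the attribute autoencoder, the improved graph
autoencoder, the attribute-topology fusion, the triple self-supervised
clustering head and the ZINB reconstruction head into one trainable model,
in the statsmodels spirit: build the model from data, call :meth:`SCDFN.fit`,
inspect the returned :class:`SCDFNResults`.

Training has two phases.  Pretraining first fits each branch on its own
reconstruction loss, then a short joint phase decodes both branches from the
fused embedding (fusion scalars frozen at alpha = 0.5, beta = 0).  Cluster
centers are then initialized by k-means++ on the fused embedding, and
fine-tuning minimizes the quadruple joint loss

    L = g1 L_AE + g2 L_IGAE + g3 L_KL + g4 L_ZINB

with everything (networks, fusion scalars, centers, ZINB heads) trained by
full-batch Adam.  The self-training target P is refreshed on a fixed epoch
interval, and training stops early once the fraction of cells changing
cluster between refreshes drops below 0.1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from autograd import value_and_grad
from autograd.misc.flatten import flatten

from ._exceptions import (
    ConfigurationError,
    NumericalError,
    ParameterError,
    ValidationError,
)
from . import fusion as fu
from . import networks as nets
from . import selfsup as ss
from . import zinb as zb
from .graph import CellGraph, build_graph
from .io import CountMatrix, PreprocessConfig, preprocess
from .metrics import EvalReport, evaluate

__all__ = ["TrainConfig", "SCDFN", "SCDFNResults", "joint_loss"]


@dataclass
class TrainConfig:
    """Hyperparameters and ablation switches for :class:`SCDFN`.

    gammas weight (L_AE, L_IGAE, L_KL, L_ZINB); the defaults (1, 1, 10, 0.1)
    put the four terms on comparable scales on the bundled fixtures.  Epoch
    counts are sized for desk-scale transductive training.
    """

    latent_dim: int = 20
    ae_hidden: tuple[int, ...] = (256, 64)
    igae_hidden: tuple[int, ...] = (256,)
    zinb_hidden: int = 128
    gamma_adj: float = 0.1  # weight of L_a inside L_IGAE
    gammas: tuple[float, float, float, float] = (1.0, 1.0, 10.0, 0.1)
    lr_pretrain: float = 1e-3
    lr_finetune: float = 1e-4
    epochs_pretrain: int = 30
    epochs_joint: int = 10
    epochs_finetune: int = 80
    min_epochs_finetune: int = 20
    # one epoch is a single full-batch step here, so the self-training target
    # must persist across several steps to stabilize training
    p_update_interval: int = 10
    label_change_tol: float = 1e-3
    student_dof: float = 1.0
    activation: str = "leaky_relu"
    adj_recon: str = "multilevel"
    device: str = "cpu"
    # ablation switches
    use_ae: bool = True
    use_igae: bool = True
    use_kl: bool = True
    use_zinb: bool = True
    fuse: bool = True

    def __post_init__(self) -> None:
        if not (self.use_ae or self.use_igae):
            raise ConfigurationError("at least one of use_ae/use_igae must be on")
        if any(g < 0 for g in self.gammas):
            raise ConfigurationError("loss weights must be non-negative")
        if self.p_update_interval < 1:
            raise ConfigurationError("p_update_interval must be >= 1")
        if self.device not in ("cpu", "accelerator"):
            raise ConfigurationError("device must be 'cpu' or 'accelerator'")


def joint_loss(l_ae, l_igae, l_kl, l_zinb, gammas) -> float:
    """Quadruple joint loss: the exact weighted sum of the four components."""
    g1, g2, g3, g4 = gammas
    return g1 * l_ae + g2 * l_igae + g3 * l_kl + g4 * l_zinb


class _Adam:
    """Plain Adam on a flat parameter vector."""

    def __init__(self, dim: int, lr: float, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = np.zeros(dim)
        self.v = np.zeros(dim)
        self.t = 0

    def step(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return x - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class SCDFNResults:
    """Estimates and diagnostics from a fitted :class:`SCDFN`.

    labels / embedding are the hard cluster assignment and the fused latent
    representation; loss_history has one row per executed epoch with the four
    loss components, their weighted total and the training phase.
    """

    labels: np.ndarray
    embedding: np.ndarray
    q_fused: np.ndarray
    centers: np.ndarray
    loss_history: pd.DataFrame
    alpha_final: float
    beta_final: float
    converged: bool
    seed: int
    n_clusters: int
    cell_ids: list[str]
    config: TrainConfig
    model: "SCDFN | None" = field(default=None, repr=False)

    def predict(self) -> np.ndarray:
        """Hard labels (argmax of the fused soft assignment); stable."""
        return self.labels.copy()

    def evaluate(self, labels_true: Sequence[int]) -> EvalReport:
        """Score the fit against reference labels (NMI/ARI/ASW/cLISI)."""
        return evaluate(labels_true, self.labels, embedding=self.embedding)

    def save_labels(self, path: str) -> None:
        pd.DataFrame({"cell_id": self.cell_ids, "cluster": self.labels}).to_csv(
            path, sep="\t", index=False
        )

    def save_embedding(self, path: str) -> None:
        pd.DataFrame(self.embedding, index=self.cell_ids).to_csv(
            path, sep="\t", header=False
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        hist = self.loss_history
        final = hist.iloc[-1] if len(hist) else None
        sizes = np.bincount(self.labels, minlength=self.n_clusters)
        lines = [
            "Deep fusion-network clustering results",
            "=" * 46,
            f"cells                 {len(self.labels)}",
            f"clusters (k)          {self.n_clusters}",
            f"latent dimension      {self.embedding.shape[1]}",
            f"epochs run            {len(hist)}",
            f"converged             {self.converged}",
            f"fusion alpha          {self.alpha_final:.4f}",
            f"fusion beta           {self.beta_final:.4f}",
            f"cluster sizes         {sizes.tolist()}",
        ]
        if final is not None:
            lines += [
                "-" * 46,
                f"final L_AE            {final['l_ae']:.6f}",
                f"final L_IGAE          {final['l_igae']:.6f}",
                f"final L_KL            {final['l_kl']:.6f}",
                f"final L_ZINB          {final['l_zinb']:.6f}",
                f"final total           {final['total']:.6f}",
            ]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Loss components over epochs (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for col in ("l_ae", "l_igae", "l_kl", "l_zinb", "total"):
            ax.plot(self.loss_history["epoch"], self.loss_history[col], label=col)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    def plot_embedding(self, labels=None, ax=None):
        """2-d PCA scatter of the fused embedding, colored by labels."""
        import matplotlib.pyplot as plt
        from sklearn.decomposition import PCA

        if ax is None:
            _, ax = plt.subplots()
        xy = PCA(n_components=2).fit_transform(self.embedding)
        lab = self.labels if labels is None else np.asarray(labels)
        ax.scatter(xy[:, 0], xy[:, 1], c=lab, s=8, cmap="tab20")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        return ax


class SCDFN:
    """Deep fusion-network clustering of a preprocessed count matrix.

    Parameters
    ----------
    data
        Processed :class:`~scdfn.io.CountMatrix` (HVG-selected, normalized);
        must carry raw counts and size factors for the ZINB loss.
    graph
        :class:`~scdfn.graph.CellGraph` with the normalized adjacency set.
    n_clusters
        Number of clusters k (>= 2), taken as given.
    config
        :class:`TrainConfig`; defaults are used when omitted.
    """

    def __init__(self, data: CountMatrix, graph: CellGraph, n_clusters: int,
                 config: TrainConfig | None = None):
        if not data.is_processed:
            raise ValidationError("SCDFN expects a processed CountMatrix; "
                                  "run scdfn.io.preprocess first")
        if graph.norm_adjacency is None:
            raise ValidationError("graph has no normalized adjacency")
        if graph.n_cells != data.n_cells:
            raise ConfigurationError("graph and data disagree on cell count")
        if n_clusters < 2:
            raise ParameterError("n_clusters must be >= 2")
        if n_clusters > data.n_cells:
            raise ParameterError("n_clusters exceeds number of cells")
        self.data = data
        self.graph = graph
        self.n_clusters = int(n_clusters)
        self.config = config or TrainConfig()
        self._x = data.values
        self._a = graph.norm_adjacency
        self._raw = data.raw_values
        self._sf = (data.size_factors if data.size_factors is not None
                    else np.ones(data.n_cells))
        self._p_target = None
        self._centers = None
        self._last_label_change = float("nan")

    # ------------------------------------------------------------ constructors

    @classmethod
    def from_raw_counts(cls, counts: CountMatrix, n_clusters: int,
                        n_hvg: int = 2000, knn_k: int = 15,
                        metric: str = "euclidean",
                        config: TrainConfig | None = None,
                        preprocess_config: PreprocessConfig | None = None) -> "SCDFN":
        """Preprocess raw counts, build the KNN graph and construct the model."""
        pcfg = preprocess_config or PreprocessConfig(n_hvg=n_hvg)
        proc = preprocess(counts, pcfg)
        graph = build_graph(proc, k=min(knn_k, proc.n_cells - 1), metric=metric)
        return cls(proc, graph, n_clusters, config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_clusters: int, **kwargs) -> "SCDFN":
        """Build from a cells x genes DataFrame of raw counts."""
        cm = CountMatrix(
            values=df.to_numpy(dtype=float),
            cell_ids=[str(i) for i in df.index],
            gene_ids=[str(c) for c in df.columns],
        )
        return cls.from_raw_counts(cm, n_clusters, **kwargs)

    # ----------------------------------------------------------------- forward

    def _init_params(self, seed: int) -> dict:
        cfg = self.config
        d_in = self.data.n_genes
        s = np.random.SeedSequence(seed).generate_state(4) % (2**31)
        params: dict = {}
        if cfg.use_ae:
            self._ae = nets.init_ae(
                [d_in, *cfg.ae_hidden, cfg.latent_dim], seed=int(s[0]),
                activation=cfg.activation)
            params["ae"] = self._ae.params
        if cfg.use_igae:
            self._igae = nets.init_igae(
                [d_in, *cfg.igae_hidden, cfg.latent_dim], seed=int(s[1]),
                gamma=cfg.gamma_adj, activation=cfg.activation,
                adj_recon=cfg.adj_recon)
            params["igae"] = self._igae.params
        if cfg.use_zinb:
            self._zdec = zb.init_zinb_decoder(
                cfg.latent_dim, d_in, hidden=cfg.zinb_hidden, seed=int(s[2]),
                activation=cfg.activation)
            params["zinb"] = self._zdec.params
        if cfg.fuse and cfg.use_ae and cfg.use_igae:
            params["alpha_raw"] = 0.0
            params["beta"] = 0.0
        self._kmeans_seed = int(s[3])
        return params

    def _embed(self, params: dict, train_fusion: bool):
        """Branch embeddings and the fused embedding for given parameters."""
        cfg = self.config
        z_ae = z_igae = enc_outs = None
        if cfg.use_ae:
            z_ae = nets.ae_encode(params["ae"], self._x, cfg.activation)
        if cfg.use_igae:
            z_igae, enc_outs = nets.igae_encode(
                params["igae"], self._x, self._a, cfg.activation, return_all=True)
        if cfg.use_ae and cfg.use_igae:
            if cfg.fuse:
                alpha = (fu.alpha_from_raw(params["alpha_raw"])
                         if train_fusion else 0.5)
                beta = params["beta"] if train_fusion else 0.0
                _, _, _, z_tilde = fu.fuse(z_ae, z_igae, self._a, alpha, beta)
            else:
                z_tilde = 0.5 * (z_ae + z_igae)
        else:
            z_tilde = z_ae if cfg.use_ae else z_igae
        return z_ae, z_igae, enc_outs, z_tilde

    def _losses(self, params: dict, p_target, centers, decode_from: str,
                train_fusion: bool) -> dict:
        """All four loss components for the current parameters.

        decode_from: 'own' decodes each branch from its own latent
        (standalone pretraining); 'fused' decodes from the fused embedding.
        """
        cfg = self.config
        z_ae, z_igae, enc_outs, z_tilde = self._embed(params, train_fusion)
        l_ae = l_igae = l_kl = l_zinb = 0.0
        if cfg.use_ae:
            dec_in = z_ae if decode_from == "own" else z_tilde
            x_hat = nets.ae_decode(params["ae"], dec_in, cfg.activation)
            l_ae = nets.ae_loss(self._x, x_hat)
        if cfg.use_igae:
            dec_in = z_igae if decode_from == "own" else z_tilde
            z_hat, a_hat = nets.igae_decode(
                params["igae"], dec_in, self._a, cfg.activation,
                enc_outputs=enc_outs if cfg.adj_recon == "multilevel" else None)
            _, _, l_igae = nets.igae_loss(
                self._x, self._a, z_hat, a_hat, gamma=cfg.gamma_adj)
        if cfg.use_kl and p_target is not None:
            c = params.get("centers", centers)
            qs = [ss.soft_assign(z_tilde, c, cfg.student_dof)]
            if cfg.use_igae and z_igae is not z_tilde:
                qs.append(ss.soft_assign(z_igae, c, cfg.student_dof))
            if cfg.use_ae and z_ae is not z_tilde:
                qs.append(ss.soft_assign(z_ae, c, cfg.student_dof))
            mix = sum(qs) / len(qs)
            l_kl = ss.clu_loss(p_target, mix)
        if cfg.use_zinb:
            zp = zb.zinb_heads(params["zinb"], z_tilde, self._sf, cfg.activation)
            l_zinb = zb.zinb_nll(self._raw, zp)
        return {"l_ae": l_ae, "l_igae": l_igae, "l_kl": l_kl, "l_zinb": l_zinb,
                "z_tilde": z_tilde}

    # ---------------------------------------------------------------- training

    def _run_phase(self, params: dict, train_keys: list[str], loss_of,
                   epochs: int, lr: float, history: list[dict], phase: str,
                   epoch_hook=None) -> dict:
        """Adam-train the sub-dict of ``params`` named by ``train_keys``."""
        if epochs == 0:
            return params
        sub = {k: params[k] for k in train_keys}
        flat, unflatten = flatten(sub)
        fixed = {k: v for k, v in params.items() if k not in train_keys}

        def objective(flat_sub):
            merged = {**fixed, **unflatten(flat_sub)}
            return loss_of(merged)

        vag = value_and_grad(objective)
        opt = _Adam(flat.size, lr)
        for ep in range(epochs):
            val, grad = vag(flat)
            if not np.isfinite(val):
                raise NumericalError(f"{phase}: loss diverged at epoch {ep}")
            flat = opt.step(flat, grad)
            merged = {**fixed, **unflatten(flat)}
            stop = epoch_hook(merged, ep) if epoch_hook is not None else False
            comps = self._components(merged, phase)
            history.append({"phase": phase, **comps,
                            "label_change": self._last_label_change})
            if stop:
                break
        return {**fixed, **unflatten(flat)}

    def _components(self, params: dict, phase: str) -> dict:
        """Numeric loss components after an update, for the history log."""
        cfg = self.config
        decode_from = "own" if phase in ("pretrain_ae", "pretrain_igae") else "fused"
        train_fusion = phase == "finetune"
        p = self._p_target if (phase == "finetune" and cfg.use_kl) else None
        active = {
            "pretrain_ae": ("l_ae",),
            "pretrain_igae": ("l_igae",),
            "pretrain_joint": ("l_ae", "l_igae"),
            "finetune": ("l_ae", "l_igae", "l_kl", "l_zinb"),
        }[phase]
        ls = self._losses(params, p, self._centers, decode_from, train_fusion)
        comps = {k: (float(ls[k]) if k in active else 0.0)
                 for k in ("l_ae", "l_igae", "l_kl", "l_zinb")}
        comps["total"] = joint_loss(
            comps["l_ae"], comps["l_igae"], comps["l_kl"], comps["l_zinb"],
            self.config.gammas)
        return comps

    def pretrain(self, params: dict, history: list[dict]) -> dict:
        """Branch-wise pretraining followed by a short joint phase."""
        cfg = self.config
        g1, g2, _, _ = cfg.gammas
        if cfg.use_ae:
            params = self._run_phase(
                params, ["ae"],
                lambda p: g1 * self._losses(p, None, None, "own", False)["l_ae"],
                cfg.epochs_pretrain, cfg.lr_pretrain, history, "pretrain_ae")
        if cfg.use_igae:
            params = self._run_phase(
                params, ["igae"],
                lambda p: g2 * self._losses(p, None, None, "own", False)["l_igae"],
                cfg.epochs_pretrain, cfg.lr_pretrain, history, "pretrain_igae")
        if cfg.use_ae and cfg.use_igae:
            def joint(p):
                ls = self._losses(p, None, None, "fused", False)
                return g1 * ls["l_ae"] + g2 * ls["l_igae"]

            params = self._run_phase(
                params, ["ae", "igae"], joint,
                cfg.epochs_joint, cfg.lr_pretrain, history, "pretrain_joint")
        return params

    def fit(self, seed: int = 0) -> SCDFNResults:
        """Run the full two-phase training and return the results object.

        Deterministic on cpu for a given seed: all randomness (weight
        initialization, k-means) flows from named substreams of ``seed``.
        """
        cfg = self.config
        self._p_target = None
        self._centers = None
        self._last_label_change = float("nan")
        history: list[dict] = []
        params = self._init_params(seed)

        params = self.pretrain(params, history)

        # center initialization on the fused embedding
        z_tilde = self._numpy_embedding(params, train_fusion=False)
        centers = ss.init_centers(z_tilde, self.n_clusters, seed=self._kmeans_seed)
        params["centers"] = centers
        self._centers = centers

        q0 = ss.soft_assign(z_tilde, centers, cfg.student_dof)
        prev_labels = ss.hard_labels(q0)
        if cfg.use_kl:
            self._p_target = ss.target_distribution(q0)

        state = {"prev_labels": prev_labels, "converged": False}

        def finetune_loss(p):
            ls = self._losses(p, self._p_target, None, "fused", True)
            return joint_loss(ls["l_ae"], ls["l_igae"], ls["l_kl"],
                              ls["l_zinb"], cfg.gammas)

        def hook(p, ep):
            if (ep + 1) % cfg.p_update_interval:
                return False
            z = self._numpy_embedding(p, train_fusion=True)
            q = ss.soft_assign(z, p["centers"], cfg.student_dof)
            labels = ss.hard_labels(q)
            change = float(np.mean(labels != state["prev_labels"]))
            state["prev_labels"] = labels
            self._last_label_change = change
            if cfg.use_kl:
                self._p_target = ss.target_distribution(q)
            # full-batch steps move labels slowly; only trust the stability
            # signal after a minimum number of fine-tune epochs
            if ep + 1 >= cfg.min_epochs_finetune and change < cfg.label_change_tol:
                state["converged"] = True
                return True
            return False

        train_keys = [k for k in params if k != "centers"] + ["centers"]
        params = self._run_phase(
            params, train_keys, finetune_loss,
            cfg.epochs_finetune, cfg.lr_finetune, history, "finetune",
            epoch_hook=hook)

        z_tilde = self._numpy_embedding(params, train_fusion=True)
        q_fused = ss.soft_assign(z_tilde, params["centers"], cfg.student_dof)
        labels = ss.hard_labels(q_fused)
        alpha = (float(fu.alpha_from_raw(params["alpha_raw"]))
                 if "alpha_raw" in params else
                 (1.0 if not cfg.use_igae else 0.0 if not cfg.use_ae else 0.5))
        beta = float(params.get("beta", 0.0))
        hist = pd.DataFrame(history)
        hist.insert(0, "epoch", np.arange(len(hist)))
        self.params_ = params
        return SCDFNResults(
            labels=labels,
            embedding=np.asarray(z_tilde),
            q_fused=np.asarray(q_fused),
            centers=np.asarray(params["centers"]),
            loss_history=hist,
            alpha_final=alpha,
            beta_final=beta,
            converged=state["converged"],
            seed=seed,
            n_clusters=self.n_clusters,
            cell_ids=list(self.data.cell_ids),
            config=cfg,
            model=self,
        )

    def _numpy_embedding(self, params: dict, train_fusion: bool) -> np.ndarray:
        _, _, _, z_tilde = self._embed(params, train_fusion)
        return np.asarray(z_tilde)

    # ------------------------------------------------------------- checkpoints

    def save_weights(self, path: str) -> None:
        """Save all trained parameters to a single versioned .npz archive."""
        if not hasattr(self, "params_"):
            raise ConfigurationError("fit the model before saving weights")
        nets.save_weights(path, self.params_)

    def load_weights(self, path: str) -> "SCDFN":
        """Restore parameters saved by :meth:`save_weights`."""
        self.params_ = nets.load_weights(path)
        return self


def predict(result: SCDFNResults) -> np.ndarray:
    """Hard labels from a completed fit (functional alias of ``predict``)."""
    return result.predict()
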