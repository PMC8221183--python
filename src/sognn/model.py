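"""The self-organized graph neural network.

Three conv-pool blocks extract per-electrode time-frequency features (the
electrode axis is never mixed, so graph structure stays meaningful); after
each block the feature map is reshaped to electrodes x features and fed to a
branch that (i) learns a per-sample adjacency through a tanh bottleneck and
row softmax, (ii) sparsifies it to the k largest weights per row, and
(iii) applies a Chebyshev spectral graph convolution on the normalized
Laplacian.  The three branch outputs are flattened, concatenated and
classified by a fully-connected head with softmax output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["SOGNNConfig", "SOGNN", "sognn_loss", "save_checkpoint", "load_checkpoint"]


@dataclass
class SOGNNConfig:
    """Architecture hyperparameters and shape contract.

    Defaults follow the 62-electrode, 5-band, 265-frame configuration:
    conv kernels (5,5)/(1,5)/(1,5) with 32/64/128 maps, 1x4 pooling,
    bottleneck width 64, 32 graph-convolution output channels, top-10
    adjacency weights, order-2 Chebyshev filters, 3 classes.  The 4-class
    variant uses 64 frames and 1x2 pooling.
    """

    n_electrodes: int = 62
    n_bands: int = 5
    n_frames: int = 265
    conv_kernels: tuple = ((5, 5), (1, 5), (1, 5))
    conv_maps: tuple = (32, 64, 128)
    pool_sizes: tuple = ((1, 4), (1, 4), (1, 4))
    bottleneck: int = 64
    graph_out: int = 32
    k: int = 10
    cheb_order: int = 2
    n_classes: int = 3
    fc_hidden: int = 128
    dropout: float = 0.1
    loss_kind: str = "per-class-bce"  # or "categorical"
    seed: int = 0

    @classmethod
    def seed_preset(cls) -> "SOGNNConfig":
        return cls()

    @classmethod
    def seed4_preset(cls) -> "SOGNNConfig":
        return cls(n_frames=64, pool_sizes=((1, 2), (1, 2), (1, 2)), n_classes=4)

    @classmethod
    def tiny_preset(cls, n_classes: int = 3) -> "SOGNNConfig":
        """Reduced configuration for 16-electrode synthetic data."""
        return cls(
            n_electrodes=16,
            n_frames=40,
            conv_maps=(16, 32, 64),
            pool_sizes=((1, 2), (1, 2), (1, 2)),
            n_classes=n_classes,
        )

    def __post_init__(self):
        for name in ("conv_kernels", "conv_maps", "pool_sizes"):
            value = tuple(
                tuple(v) if isinstance(v, (list, tuple)) else v
                for v in getattr(self, name)
            )
            object.__setattr__(self, name, value)
            if len(value) != 3:
                raise ValueError(f"{name} must have length 3")
        self.propagate_shapes()  # fail fast on invalid geometry

    def propagate_shapes(self) -> dict:
        """Symbolic shape propagation through the three blocks.

        Returns per-block post-conv and post-pool (height, frames) plus each
        branch's node-feature width and the concatenated feature length.
        Raises at construction time if any stage underflows.
        """
        h, t = self.n_bands, self.n_frames
        info = {"blocks": [], "branch_features": []}
        for i, ((kh, kw), maps, (ph, pw)) in enumerate(
            zip(self.conv_kernels, self.conv_maps, self.pool_sizes)
        ):
            h_c, t_c = h - kh + 1, t - kw + 1
            if h_c < 1 or t_c < 1:
                raise ValueError(
                    f"block {i + 1}: conv kernel ({kh},{kw}) underflows input ({h},{t})"
                )
            h_p, t_p = h_c // ph, t_c // pw
            if h_p < 1 or t_p < 1:
                raise ValueError(
                    f"block {i + 1}: pool ({ph},{pw}) underflows conv output ({h_c},{t_c})"
                )
            info["blocks"].append(
                {"post_conv": (h_c, t_c), "post_pool": (h_p, t_p), "maps": maps}
            )
            info["branch_features"].append(maps * h_p * t_p)
            h, t = h_p, t_p
        if info["blocks"][0]["post_conv"][0] != 1:
            raise ValueError(
                "first conv kernel must consume the whole band axis "
                f"(got height {info['blocks'][0]['post_conv'][0]})"
            )
        info["concat_length"] = self.n_electrodes * self.graph_out * 3
        return info

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SOGNNConfig":
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class SOGNN:
    """Trainable network; parameters are a flat name -> Tensor mapping."""

    def __init__(self, config: SOGNNConfig, rng: np.random.Generator | None = None):
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.shapes = config.propagate_shapes()
        p: dict[str, Tensor] = {}
        c_in = 1
        for i, ((kh, kw), maps) in enumerate(zip(config.conv_kernels, config.conv_maps)):
            fan_in, fan_out = c_in * kh * kw, maps * kh * kw
            p[f"conv{i}_w"] = _glorot(rng, (maps, c_in, kh, kw), fan_in, fan_out)
            p[f"conv{i}_b"] = Tensor(np.zeros(maps), requires_grad=True)
            c_in = maps
        for i, F in enumerate(self.shapes["branch_features"]):
            p[f"bottleneck{i}_w"] = _glorot(rng, (F, config.bottleneck), F, config.bottleneck)
            p[f"cheb{i}"] = _glorot(
                rng,
                (config.cheb_order + 1, F, config.graph_out),
                F * (config.cheb_order + 1),
                config.graph_out,
            )
            p[f"cheb{i}_b"] = Tensor(np.zeros(config.graph_out), requires_grad=True)
        concat = self.shapes["concat_length"]
        p["fc_w"] = _glorot(rng, (concat, config.fc_hidden), concat, config.fc_hidden)
        p["fc_b"] = Tensor(np.zeros(config.fc_hidden), requires_grad=True)
        p["out_w"] = _glorot(
            rng, (config.fc_hidden, config.n_classes), config.fc_hidden, config.n_classes
        )
        p["out_b"] = Tensor(np.zeros(config.n_classes), requires_grad=True)
        self.params = p

    # -- forward ----------------------------------------------------------

    def _dropout(self, x: Tensor, train: bool, rng) -> Tensor:
        rate = self.config.dropout
        if not train or rate <= 0:
            return x
        keep = rng.random(x.shape) >= rate
        return x * Tensor(keep / (1.0 - rate))

    def conv_pool_block(self, x: Tensor, block_index: int) -> Tensor:
        """One per-electrode conv + ReLU + max-pool stage.

        ``x`` is (B*N, C, H, T); electrodes ride in the batch axis so they
        never mix.
        """
        w = self.params[f"conv{block_index}_w"]
        b = self.params[f"conv{block_index}_b"]
        y = ag.conv2d(x, w, b).relu()
        return ag.maxpool2d(y, self.config.pool_sizes[block_index])

    def branch(self, V: Tensor, branch_index: int) -> tuple[Tensor, dict]:
        """Self-organized graph + spectral convolution for one branch.

        V: (B, N, F) node features.  Returns (B, N, graph_out) and the
        dense/sparse adjacencies as diagnostics.
        """
        cfg = self.config
        W = self.params[f"bottleneck{branch_index}_w"]
        G = (V @ W).tanh()
        S = G @ G.swapaxes(-1, -2)
        A = ag.softmax(S, axis=-1)
        A_k = ag.topk_rows(A, cfg.k)
        # symmetrize for a real spectral decomposition; softmax rows keep
        # every node's degree strictly positive
        A_sym = (A_k + A_k.swapaxes(-1, -2)) * 0.5
        deg = A_sym.sum(axis=-1)
        d = deg ** (-0.5)
        n = cfg.n_electrodes
        B = V.shape[0]
        M = d.reshape(B, n, 1) * A_sym * d.reshape(B, 1, n)
        # rescaled Laplacian with lmax fixed at 2: Ltilde = L - I = -M
        theta = self.params[f"cheb{branch_index}"]
        T_prev = V
        out = T_prev @ _slice0(theta, 0)
        if cfg.cheb_order >= 1:
            T_cur = -(M @ V)
            out = out + T_cur @ _slice0(theta, 1)
            for k in range(2, cfg.cheb_order + 1):
                T_next = (M @ T_cur) * (-2.0) - T_prev
                out = out + T_next @ _slice0(theta, k)
                T_prev, T_cur = T_cur, T_next
        out = out + self.params[f"cheb{branch_index}_b"]
        out = out.relu()
        diag = {"dense": A.data.copy(), "sparse": A_k.data.copy()}
        return out, diag

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        return_adjacency: bool = False,
    ):
        """Class probabilities for a batch shaped (B, N, bands, frames)."""
        cfg = self.config
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        B, N, Hb, T = x.shape
        if (N, Hb, T) != (cfg.n_electrodes, cfg.n_bands, cfg.n_frames):
            raise ValueError(
                f"input shape {(N, Hb, T)} does not match config "
                f"{(cfg.n_electrodes, cfg.n_bands, cfg.n_frames)} at the input stage"
            )
        if train and rng is None:
            rng = np.random.default_rng()
        h = Tensor(x.reshape(B * N, 1, Hb, T))
        branch_outputs = []
        adjacency = []
        for i in range(3):
            h = self.conv_pool_block(h, i)
            h = self._dropout(h, train, rng)
            maps = cfg.conv_maps[i]
            hp, tp = self.shapes["blocks"][i]["post_pool"]
            V = h.reshape(B, N, maps * hp * tp)
            out, diag = self.branch(V, i)
            branch_outputs.append(out.reshape(B, N * cfg.graph_out))
            adjacency.append(diag)
        feat = ag.concat(branch_outputs, axis=-1)
        feat = self._dropout(feat, train, rng)
        hdn = (feat @ self.params["fc_w"] + self.params["fc_b"]).relu()
        logits = hdn @ self.params["out_w"] + self.params["out_b"]
        probs = ag.softmax(logits, axis=-1)
        if return_adjacency:
            return probs, adjacency
        return probs

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Eval-mode probabilities as a plain array (no dropout, no graph)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        chunks = [
            self.forward(x[i : i + batch_size]).data
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def trainable(self) -> dict[str, Tensor]:
        return self.params

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unexpected parameter {k!r}")
            if self.params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()


def _slice0(theta: Tensor, k: int) -> Tensor:
    """View of theta[k] that routes gradients back into the stacked tensor."""
    out = Tensor(theta.data[k], theta.requires_grad)

    def bw(g):
        if theta.requires_grad:
            if theta.grad is None:
                theta.grad = np.zeros_like(theta.data)
            theta.grad[k] += g

    out._backward, out._parents = bw, (theta,)
    return out


def reshape_to_nodes(block_output: np.ndarray, n_electrodes: int) -> np.ndarray:
    """(B*N, maps, 1, t) block output -> (B, N, maps*t) node features.

    Row i of a sample is the concatenation of electrode i's maps x frames
    values; the mapping is a bijection, so no information is lost.
    """
    bn, maps, h, t = block_output.shape
    if bn % n_electrodes:
        raise ValueError("batch axis is not a multiple of the electrode count")
    return np.asarray(block_output).reshape(bn // n_electrodes, n_electrodes, maps * h * t)


def sognn_loss(p: Tensor, y: np.ndarray, kind: str = "per-class-bce") -> Tensor:
    """Training loss on softmax outputs.

    Default: the sum over samples and classes of the per-class binary
    cross-entropy, -sum_i sum_c [y log p + (1-y) log(1-p)].  ``kind=
    "categorical"`` gives the plain categorical cross-entropy instead.
    Probabilities are clamped to [1e-7, 1 - 1e-7] to keep both logs finite.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"labels {y.shape} do not match probabilities {p.shape}")
    pc = p.clamp(1e-7, 1.0 - 1e-7)
    if kind == "per-class-bce":
        yt = Tensor(y)
        loss = -(yt * pc.log() + (1.0 - yt) * (1.0 - pc).log()).sum()
    elif kind == "categorical":
        loss = -(Tensor(y) * pc.log()).sum()
    else:
        raise ValueError(f"unknown loss kind {kind!r}")
    return loss


def save_checkpoint(path, model: SOGNN) -> None:
    """Single-file checkpoint: parameters plus embedded config JSON."""
    state = model.state_dict()
    np.savez(
        path,
        __config__=np.frombuffer(model.config.to_json().encode(), dtype=np.uint8),
        __hash__=np.frombuffer(model.config.config_hash().encode(), dtype=np.uint8),
        **state,
    )


def load_checkpoint(path) -> SOGNN:
    with np.load(path) as data:
        cfg_json = bytes(data["__config__"]).decode()
        stored_hash = bytes(data["__hash__"]).decode()
        config = SOGNNConfig.from_dict(json.loads(cfg_json))
        if config.config_hash() != stored_hash:
            raise ValueError("checkpoint config hash mismatch: file corrupted?")
        model = SOGNN(config)
        model.load_state_dict(
            {k: data[k] for k in data.files if not k.startswith("__")}
        )
    return model
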