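"""The alignment model: feature projection, stacked graph-convolution
blocks with within- and across-network attention message passing, and a
pairwise MLP prediction head.

Each block computes, for node i with embedding h_i,

    m_i      = sum_{j in N_in(i)}    alpha_ij * h_j     (PPI neighbours)
    mu_i^(r) = sum_{j in N_r_ac(i)}  beta_ij  * h_j     (type-r anchors)

where alpha (resp. beta) is the softmax over the neighbourhood of
gamma * h_j (resp. omega_r * h_j) with a learnable scalar inverse
temperature, applied per feature channel; the update is residual:

    h_i' = f(h_i + m_i) + sum_r f^(r)(h_i + mu_i^(r)) + h_i

with two-layer MLPs f, f^(r).  Pair normalisation and ReLU are applied
between adjacent blocks.  A two-layer MLP scores the concatenated final
embeddings of a cross-species pair; training uses binary cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .features import EmbeddingMatrix
from .network_io import JointGraph, ValidationError

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture + optimisation settings.

    The default depth is a seven-block stack over NetMF distance and
    Laplacian positional features; width, dropout and optimiser
    settings are free knobs of this implementation.
    """

    hidden_dim: int = 64           # d, must be even (split between features)
    n_blocks: int = 7              # L
    anchor_types: tuple = ("ortholog", "seqsim")
    mlp_head_layers: int = 2
    init_temperature: float = 1.0  # initial gamma / omega
    dropout: float = 0.0           # full-batch training; dropout off by default
    attention: str = "channel"     # per-channel softmax; "scalar" for ablation
    pos_dim: int = 16              # Laplacian eigenvector count per network
    pairnorm_scale: float = 1.0
    seed: int = 0
    lr: float = 1e-2
    max_epochs: int = 400
    patience: int = 60

    def __post_init__(self):
        if self.n_blocks < 1 or self.hidden_dim < 2:
            raise ValidationError("need n_blocks >= 1 and hidden_dim >= 2")
        if self.hidden_dim % 2:
            raise ValidationError("hidden_dim must be even")
        if not self.anchor_types:
            raise ValidationError("anchor_types must be non-empty")
        if self.attention not in ("channel", "scalar"):
            raise ValidationError("attention must be 'channel' or 'scalar'")


class GraphFeatures:
    """Constant per-joint-graph inputs: adjacencies + raw feature rows."""

    def __init__(self, jg: JointGraph, dist1: EmbeddingMatrix,
                 dist2: EmbeddingMatrix, pos1: EmbeddingMatrix,
                 pos2: EmbeddingMatrix):
        if dist1.node_order != jg.g1.node_order \
                or dist2.node_order != jg.g2.node_order \
                or pos1.node_order != jg.g1.node_order \
                or pos2.node_order != jg.g2.node_order:
            raise ValidationError("embedding node order does not match graph")
        if pos1.values.shape[1] != pos2.values.shape[1]:
            raise ValidationError("positional widths differ between species")
        self.jg = jg
        self.within_adj = jg.within_adjacency()
        self.anchor_adj = {t: jg.anchor_adjacency(t) for t in jg.anchor_types}
        self.dist1 = dist1.values
        self.dist2 = dist2.values
        self.pos1 = pos1.values
        self.pos2 = pos2.values

    @property
    def pos_dim(self) -> int:
        return self.pos1.shape[1]


# ---------------------------------------------------------------------------
# message passing primitives
# ---------------------------------------------------------------------------

def _neighbour_softmax_aggregate(h: Tensor, adj: sp.csr_matrix,
                                 temp: Tensor, mode: str) -> Tensor:
    """Attention-weighted neighbour sum shared by Eq.-style within- and
    across-network aggregation.

    The softmax logit of neighbour j is temp * h_j (per channel) or
    temp * sum_c h_j[c] (scalar mode); subtracting the global per-channel
    maximum leaves every neighbourhood softmax unchanged but keeps the
    exponentials in range.  Nodes with an empty neighbourhood get zero.
    """
    if mode == "channel":
        logits = h * temp
    else:
        logits = h.sum(axis=1, keepdims=True) * temp
    shift = logits.v.max(axis=0, keepdims=True)  # constant w.r.t. autodiff
    z = (logits - Tensor(shift)).exp()
    den = ad.spmm(adj, z)
    num = ad.spmm(adj, z * h)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    guard = Tensor((deg == 0).astype(float)[:, None])  # avoids 0/0 only
    return num / (den + guard)


def within_message(h: Tensor, adj: sp.csr_matrix, gamma: Tensor,
                   mode: str = "channel") -> Tensor:
    """Within-network attention aggregation over PPI neighbours."""
    return _neighbour_softmax_aggregate(h, adj, gamma, mode)


def across_message(h: Tensor, anchor_adj: sp.csr_matrix, omega: Tensor,
                   mode: str = "channel") -> Tensor:
    """Across-network attention aggregation over typed anchor links."""
    return _neighbour_softmax_aggregate(h, anchor_adj, omega, mode)


def attention_weights(h: np.ndarray, adj: sp.spmatrix, temp: float,
                      mode: str = "channel") -> np.ndarray:
    """Dense (n, n, d) attention coefficients implied by the aggregation.

    For inspection/testing on small graphs: weights[i, j, c] is the
    coefficient on h_j[c] in message m_i[c]; rows with an empty
    neighbourhood are all zero.
    """
    A = np.asarray(adj.todense())
    n, d = h.shape
    if mode == "channel":
        logits = temp * h
    else:
        logits = np.repeat(temp * h.sum(axis=1, keepdims=True), d, axis=1)
    E = np.exp(logits - logits.max(axis=0, keepdims=True))
    w = A[:, :, None] * E[None, :, :]
    den = w.sum(axis=1, keepdims=True)
    den[den == 0] = 1.0
    return w / den


def pair_norm(h: Tensor, scale: float = 1.0) -> Tensor:
    """Pair normalisation (basic centre-and-rescale variant): subtract
    the mean embedding over all nodes, then rescale so the root-mean-
    square row norm equals ``scale``; counteracts oversmoothing in deep
    graph convolutions."""
    centered = h - h.mean(axis=0, keepdims=True)
    msq = (centered * centered).sum(axis=1, keepdims=True).mean()
    return centered * (scale / (msq + 1e-12).sqrt())


def _mlp2(x: Tensor, W1: Tensor, b1: Tensor, W2: Tensor, b2: Tensor,
          drop: float = 0.0, rng=None) -> Tensor:
    hidden = (x @ W1 + b1).relu()
    if drop > 0.0 and rng is not None:
        hidden = ad.dropout(hidden, drop, rng)
    return hidden @ W2 + b2


def block_update(h: Tensor, m: Tensor, mus: dict[str, Tensor],
                 params: dict[str, Tensor], prefix: str,
                 drop: float = 0.0, rng=None) -> Tensor:
    """Residual heterogeneous update; with a single anchor type this is
    exactly the homogeneous form h + f(h+m) + f'(h+mu)."""
    out = h + _mlp2(h + m, params[f"{prefix}.within.W1"],
                    params[f"{prefix}.within.b1"],
                    params[f"{prefix}.within.W2"],
                    params[f"{prefix}.within.b2"], drop, rng)
    for r, mu in mus.items():
        out = out + _mlp2(h + mu, params[f"{prefix}.ac.{r}.W1"],
                          params[f"{prefix}.ac.{r}.b1"],
                          params[f"{prefix}.ac.{r}.W2"],
                          params[f"{prefix}.ac.{r}.b2"], drop, rng)
    return out


def bce_loss(scores: np.ndarray, labels: np.ndarray,
             clamp: float = 1e-12) -> float:
    """Mean binary cross-entropy on probability scores in [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValidationError("scores/labels length mismatch")
    if np.any((labels != 0) & (labels != 1)):
        raise ValidationError("labels must be 0/1")
    p = np.clip(scores, clamp, 1 - clamp)
    return float(-(labels * np.log(p) + (1 - labels) * np.log(1 - p)).mean())


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=(fan_in, fan_out))


class AlignerModel:
    """Trainable state: projections, L conv blocks, prediction head."""

    def __init__(self, config: ModelConfig, n1: int, n2: int,
                 pos_dim: int | None = None):
        self.config = config
        self.n1 = n1
        self.n2 = n2
        self.pos_dim = config.pos_dim if pos_dim is None else pos_dim
        self.params: dict[str, Tensor] = {}
        self._build(np.random.default_rng(config.seed))

    # --- construction --------------------------------------------------
    def _add(self, name: str, value: np.ndarray):
        self.params[name] = Tensor(value, requires_grad=True)

    def _build(self, rng: np.random.Generator):
        cfg = self.config
        d = cfg.hidden_dim
        dh = d // 2
        self._add("proj.dist1.W", _glorot(rng, self.n1, dh))
        self._add("proj.dist1.b", np.zeros(dh))
        self._add("proj.dist2.W", _glorot(rng, self.n2, dh))
        self._add("proj.dist2.b", np.zeros(dh))
        self._add("proj.pos.W", _glorot(rng, self.pos_dim, dh))
        self._add("proj.pos.b", np.zeros(dh))
        for l in range(cfg.n_blocks):
            p = f"block{l}"
            self._add(f"{p}.gamma", np.float64(cfg.init_temperature))
            self._add(f"{p}.within.W1", _glorot(rng, d, d))
            self._add(f"{p}.within.b1", np.zeros(d))
            self._add(f"{p}.within.W2", _glorot(rng, d, d))
            self._add(f"{p}.within.b2", np.zeros(d))
            for r in cfg.anchor_types:
                self._add(f"{p}.ac.{r}.omega", np.float64(cfg.init_temperature))
                self._add(f"{p}.ac.{r}.W1", _glorot(rng, d, d))
                self._add(f"{p}.ac.{r}.b1", np.zeros(d))
                self._add(f"{p}.ac.{r}.W2", _glorot(rng, d, d))
                self._add(f"{p}.ac.{r}.b2", np.zeros(d))
        widths = [2 * d] + [d] * (cfg.mlp_head_layers - 1) + [1]
        for i, (w_in, w_out) in enumerate(zip(widths[:-1], widths[1:])):
            self._add(f"head.W{i}", _glorot(rng, w_in, w_out))
            self._add(f"head.b{i}", np.zeros(w_out))

    def head_param_names(self) -> list[str]:
        return [k for k in self.params if k.startswith("head.")]

    # --- forward pass --------------------------------------------------
    def init_features(self, feats: GraphFeatures) -> Tensor:
        """Project raw distance rows (species-specific maps) and
        positional rows (shared map) to width d/2 each and concatenate."""
        if feats.dist1.shape[0] != self.n1 or feats.dist2.shape[0] != self.n2:
            raise ValidationError("feature row count mismatch with model")
        if feats.pos_dim != self.pos_dim:
            raise ValidationError("positional width mismatch with model")
        p = self.params
        h1 = ad.concat([Tensor(feats.dist1) @ p["proj.dist1.W"]
                        + p["proj.dist1.b"],
                        Tensor(feats.pos1) @ p["proj.pos.W"]
                        + p["proj.pos.b"]], axis=1)
        h2 = ad.concat([Tensor(feats.dist2) @ p["proj.dist2.W"]
                        + p["proj.dist2.b"],
                        Tensor(feats.pos2) @ p["proj.pos.W"]
                        + p["proj.pos.b"]], axis=1)
        return ad.concat([h1, h2], axis=0)

    def forward(self, feats: GraphFeatures, train: bool = False,
                rng: np.random.Generator | None = None,
                capture: list | None = None) -> Tensor:
        """Final node embeddings h^L for all |V1|+|V2| nodes.

        ``capture``, if given, collects the post-pair-norm embeddings
        between blocks (before ReLU) for inspection.
        """
        cfg = self.config
        drop = cfg.dropout if train else 0.0
        h = self.init_features(feats)
        for l in range(cfg.n_blocks):
            pfx = f"block{l}"
            m = within_message(h, feats.within_adj,
                               self.params[f"{pfx}.gamma"], cfg.attention)
            mus = {r: across_message(h, feats.anchor_adj[r],
                                     self.params[f"{pfx}.ac.{r}.omega"],
                                     cfg.attention)
                   for r in cfg.anchor_types}
            h = block_update(h, m, mus, self.params, pfx, drop, rng)
            if l < cfg.n_blocks - 1:
                h = pair_norm(h, cfg.pairnorm_scale)
                if capture is not None:
                    capture.append(h.v.copy())
                h = h.relu()
                if drop > 0.0 and rng is not None:
                    h = ad.dropout(h, drop, rng)
        return h

    # --- scoring -------------------------------------------------------
    def pair_indices(self, jg: JointGraph,
                     pairs) -> tuple[np.ndarray, np.ndarray]:
        i_idx, j_idx = [], []
        for u, v in pairs:
            if u not in jg.g1.index or v not in jg.g2.index:
                raise ValidationError(
                    f"pair ({u!r}, {v!r}) not in (species-1, species-2) order")
            i_idx.append(jg.idx1(u))
            j_idx.append(jg.idx2(v))
        return np.asarray(i_idx, dtype=np.intp), np.asarray(j_idx, dtype=np.intp)

    def pair_logits(self, h: Tensor, i_idx: np.ndarray, j_idx: np.ndarray,
                    train: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
        x = ad.concat([ad.rows(h, i_idx), ad.rows(h, j_idx)], axis=1)
        n_layers = self.config.mlp_head_layers
        drop = self.config.dropout if train else 0.0
        for i in range(n_layers):
            x = x @ self.params[f"head.W{i}"] + self.params[f"head.b{i}"]
            if i < n_layers - 1:
                x = x.relu()
                if drop > 0.0 and rng is not None:
                    x = ad.dropout(x, drop, rng)
        return x  # (m, 1) raw logits

    def score_pairs(self, feats: GraphFeatures, pairs,
                    h: Tensor | None = None) -> np.ndarray:
        """Probability in (0, 1) that each (g1-node, g2-node) pair is
        functionally related; batched scoring equals per-pair scoring."""
        if h is None:
            h = self.forward(feats, train=False)
        i_idx, j_idx = self.pair_indices(feats.jg, pairs)
        logits = self.pair_logits(h, i_idx, j_idx, train=False)
        return ad.sigmoid(logits).v.ravel()

    # --- serialization -------------------------------------------------
    def save(self, path) -> None:
        """Parameter container (.npz) plus JSON sidecar with the config
        and size manifest."""
        path = Path(path)
        np.savez(path, **{k: p.v for k, p in self.params.items()})
        cfg = asdict(self.config)
        cfg["anchor_types"] = list(cfg["anchor_types"])
        sidecar = {"config": cfg, "n1": self.n1, "n2": self.n2,
                   "pos_dim": self.pos_dim}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "AlignerModel":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_d = dict(sidecar["config"])
        cfg_d["anchor_types"] = tuple(cfg_d["anchor_types"])
        model = cls(ModelConfig(**cfg_d), sidecar["n1"], sidecar["n2"],
                    pos_dim=sidecar["pos_dim"])
        with np.load(path) as data:
            for k in model.params:
                model.params[k].v = np.asarray(data[k], dtype=np.float64)
        return model

    def copy(self) -> "AlignerModel":
        clone = AlignerModel(self.config, self.n1, self.n2, self.pos_dim)
        for k, p in self.params.items():
            clone.params[k].v = p.v.copy()
        return clone
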