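"""The two network heads over a shared residual EGCL trunk.

Both models consume a :class:`~carbsite.graph.ResidueGraph` whose edge
features are rigid-motion invariant, so their outputs are invariant under
any global rotation + translation of the input structure by construction.

* The residue head ("CAPSIF2"): 12 residual equivariant graph convolutional
  layers (EGCL) at embedding dimension 128 over a fixed 16-nearest-neighbor
  topology, followed by a two-layer dense decoder with a sigmoid per residue
  — the carbohydrate-binding likelihood of each residue.
* The protein head ("PiCAP"): the same 12-layer trunk but with a widening
  neighborhood schedule (k = 10 for layers 1–3, 20 for 4–6, 40 for 7–9, 60
  for 10–12), adaptive average pooling of the residue features to a fixed
  150-row map, then two convolutions and three dense layers to a single
  sigmoid — the probability that the protein binds carbohydrates at all.

Each EGCL computes messages ``m_ij = MLP_e([h_i, h_j, e_ij])`` over the k
neighbors, sums them, and applies a residual update
``h_i' = h_i + MLP_h([h_i, Σ_j m_ij])``.  Node coordinates are never
modified; only features propagate.

Hidden widths (MLP_e 156, MLP_h 144, decoder 33, conv channels 9→3, dense
55→31) were calibrated once so the default configurations reproduce the
reference trainable-parameter totals exactly: 1,600,387 for the residue
model and 1,798,895 for the protein model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import autograd.numpy as anp
import numpy as np

from .graph import DegenerateGraphError, ResidueGraph
from .nn import adaptive_pool, conv2d, count_parameters, init_weights, sigmoid, silu

__all__ = [
    "ModelConfig",
    "Capsif2",
    "PiCAP",
    "egcl_forward",
    "adaptive_pool",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

CAPSIF2_K = 16
PICAP_K_SCHEDULE = (10, 20, 40, 60)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters shared by both heads.

    The defaults are the full-size calibrated configuration; tests and toy
    training shrink ``n_layers``/``embed_dim`` (and the hidden widths) while
    keeping the same topology.
    """

    n_layers: int = 12
    embed_dim: int = 128
    input_dim: int = 1280
    edge_dim: int = 23              # 16 RBF + 3 direction + 4 quaternion
    msg_hidden: int = 156           # MLP_e hidden width
    upd_hidden: int = 144           # MLP_h hidden width
    capsif2_k: int = CAPSIF2_K
    picap_k_schedule: tuple[int, ...] = PICAP_K_SCHEDULE
    decoder_hidden: int = 33        # residue decoder hidden width
    pool_len: int = 150
    conv_channels: tuple[int, int] = (9, 3)
    conv_kernel: int = 3
    conv_stride: int = 2
    dense_widths: tuple[int, int] = (55, 31)
    pool_norm: str = "log"  # {log, standardize, none}: pooled-map squash
    init_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_layers % len(self.picap_k_schedule) != 0:
            raise ValueError("n_layers must be divisible by the k-schedule stages")
        if self.pool_len < 1:
            raise ValueError("pool_len must be >= 1")

    def layer_k(self, layer: int) -> int:
        """Neighborhood size of the protein head's trunk layer (0-based)."""
        stage = layer // (self.n_layers // len(self.picap_k_schedule))
        return self.picap_k_schedule[stage]


def _trunk_shapes(cfg: ModelConfig) -> dict[str, tuple]:
    D, E = cfg.embed_dim, cfg.edge_dim
    shapes: dict[str, tuple] = {
        "proj_W": (cfg.input_dim, D),
        "proj_b": (D,),
    }
    for l in range(cfg.n_layers):
        shapes[f"l{l}_msg1_W"] = (2 * D + E, cfg.msg_hidden)
        shapes[f"l{l}_msg1_b"] = (cfg.msg_hidden,)
        shapes[f"l{l}_msg2_W"] = (cfg.msg_hidden, D)
        shapes[f"l{l}_msg2_b"] = (D,)
        shapes[f"l{l}_upd1_W"] = (2 * D, cfg.upd_hidden)
        shapes[f"l{l}_upd1_b"] = (cfg.upd_hidden,)
        shapes[f"l{l}_upd2_W"] = (cfg.upd_hidden, D)
        shapes[f"l{l}_upd2_b"] = (D,)
    return shapes


def egcl_forward(h, neighbors: np.ndarray, edge_feats: np.ndarray, params: dict, layer: int):
    """One residual EGCL update; coordinates are untouched."""
    n, k = neighbors.shape
    h_j = h[neighbors]                                   # (N, k, D)
    h_i = anp.repeat(h[:, None, :], k, axis=1)           # (N, k, D)
    cat = anp.concatenate([h_i, h_j, edge_feats], axis=-1)
    m = silu(anp.dot(cat, params[f"l{layer}_msg1_W"]) + params[f"l{layer}_msg1_b"])
    m = silu(anp.dot(m, params[f"l{layer}_msg2_W"]) + params[f"l{layer}_msg2_b"])
    agg = anp.sum(m, axis=1)                             # (N, D)
    u = anp.concatenate([h, agg], axis=-1)
    u = silu(anp.dot(u, params[f"l{layer}_upd1_W"]) + params[f"l{layer}_upd1_b"])
    u = anp.dot(u, params[f"l{layer}_upd2_W"]) + params[f"l{layer}_upd2_b"]
    out = h + u
    return out


class _ModelBase:
    config: ModelConfig
    params: dict

    def count_parameters(self) -> int:
        return count_parameters(self.params)

    def _check_finite(self, h, layer: int):
        arr = h if isinstance(h, np.ndarray) else getattr(h, "_value", None)
        if arr is not None and not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite activations after trunk layer {layer}")


class Capsif2(_ModelBase):
    """Per-residue carbohydrate-binding-likelihood predictor."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int | None = None):
        self.config = config
        shapes = _trunk_shapes(config)
        D, w = config.embed_dim, config.decoder_hidden
        shapes["dec1_W"] = (D, w)
        shapes["dec1_b"] = (w,)
        shapes["dec2_W"] = (w, 1)
        shapes["dec2_b"] = (1,)
        self.shapes = shapes
        self.params = init_weights(
            shapes, config.seed if seed is None else seed, config.init_sigma
        )

    def required_k(self) -> tuple[int, ...]:
        return (self.config.capsif2_k,)

    def forward(self, graph: ResidueGraph, params: dict | None = None) -> np.ndarray:
        """Per-residue probabilities, shape (N,), strictly inside (0, 1)."""
        p = self.params if params is None else params
        cfg = self.config
        if graph.n_nodes < 2:
            raise DegenerateGraphError("need at least 2 residues")
        k = cfg.capsif2_k
        if k not in graph.neighbors:
            raise KeyError(f"graph lacks neighbor lists for k={k}")
        nbr, ef = graph.neighbors[k], graph.edge_feats[k]
        h = anp.dot(graph.node_feats, p["proj_W"]) + p["proj_b"]
        for l in range(cfg.n_layers):
            h = egcl_forward(h, nbr, ef, p, l)
            self._check_finite(h, l)
        d = silu(anp.dot(h, p["dec1_W"]) + p["dec1_b"])
        d = anp.dot(d, p["dec2_W"]) + p["dec2_b"]
        return sigmoid(d[:, 0])


class PiCAP(_ModelBase):
    """Whole-protein carbohydrate binder/nonbinder classifier."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int | None = None):
        self.config = config
        shapes = _trunk_shapes(config)
        shapes.update(self.head_shapes(config))
        self.shapes = shapes
        self.params = init_weights(
            shapes, config.seed if seed is None else seed, config.init_sigma
        )

    @staticmethod
    def head_shapes(cfg: ModelConfig) -> dict[str, tuple]:
        c1, c2 = cfg.conv_channels
        kk, s = cfg.conv_kernel, cfg.conv_stride
        pad = kk // 2
        h1 = (cfg.pool_len + 2 * pad - kk) // s + 1
        w1 = (cfg.embed_dim + 2 * pad - kk) // s + 1
        h2 = (h1 + 2 * pad - kk) // s + 1
        w2 = (w1 + 2 * pad - kk) // s + 1
        flat = h2 * w2 * c2
        d1, d2 = cfg.dense_widths
        return {
            "conv1_W": (kk, kk, 1, c1),
            "conv1_b": (c1,),
            "conv2_W": (kk, kk, c1, c2),
            "conv2_b": (c2,),
            "fc1_W": (flat, d1),
            "fc1_b": (d1,),
            "fc2_W": (d1, d2),
            "fc2_b": (d2,),
            "fc3_W": (d2, 1),
            "fc3_b": (1,),
        }

    def required_k(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.config.picap_k_schedule)))

    def trunk_pooled(self, graph: ResidueGraph, params: dict | None = None):
        """Trunk + adaptive pooling + squash: the fixed-size (pool_len, D) map."""
        p = self.params if params is None else params
        cfg = self.config
        if graph.n_nodes < 2:
            raise DegenerateGraphError("need at least 2 residues")
        for k in self.required_k():
            if k not in graph.neighbors:
                raise KeyError(f"graph lacks neighbor lists for stage k={k}")
        h = anp.dot(graph.node_feats, p["proj_W"]) + p["proj_b"]
        for l in range(cfg.n_layers):
            k = cfg.layer_k(l)
            h = egcl_forward(h, graph.neighbors[k], graph.edge_feats[k], p, l)
            self._check_finite(h, l)
        pooled = adaptive_pool(h, cfg.pool_len)            # (150, D)
        # parameter-free compression keeps the head's operating range sane
        # when the transplanted trunk produces large activations, without
        # erasing absolute magnitude (a binder-vs-flat cue)
        if cfg.pool_norm == "log":
            pooled = anp.sign(pooled) * anp.log1p(anp.abs(pooled))
        elif cfg.pool_norm == "standardize":
            pooled = (pooled - anp.mean(pooled)) / (anp.std(pooled) + 1e-8)
        return pooled

    def head_forward(self, pooled, params: dict | None = None) -> float:
        """Conv/dense classifier over a pooled map; scalar probability."""
        p = self.params if params is None else params
        cfg = self.config
        img = pooled[:, :, None]                           # 1-channel image
        pad = cfg.conv_kernel // 2
        x = silu(conv2d(img, p["conv1_W"], p["conv1_b"], stride=cfg.conv_stride, pad=pad))
        x = silu(conv2d(x, p["conv2_W"], p["conv2_b"], stride=cfg.conv_stride, pad=pad))
        x = anp.reshape(x, (-1,))
        x = silu(anp.dot(x, p["fc1_W"]) + p["fc1_b"])
        x = silu(anp.dot(x, p["fc2_W"]) + p["fc2_b"])
        x = anp.dot(x, p["fc3_W"]) + p["fc3_b"]
        return sigmoid(x[0])

    def forward(self, graph: ResidueGraph, params: dict | None = None) -> float:
        """Scalar probability that the protein binds carbohydrates."""
        return self.head_forward(self.trunk_pooled(graph, params), params)

    def head_view(self) -> "PiCAPHeadView":
        return PiCAPHeadView(self)

    def transplant_trunk(self, trunk_params: dict) -> None:
        """Copy trunk tensors from a trained residue model, where shapes match.

        Raises on a declared-trunk tensor whose shape disagrees (the heads
        must share the same trunk configuration to transfer).
        """
        mismatched = []
        for name in _trunk_shapes(self.config):
            if name not in trunk_params:
                mismatched.append(f"{name} (missing)")
            elif trunk_params[name].shape != self.params[name].shape:
                mismatched.append(
                    f"{name} {trunk_params[name].shape} != {self.params[name].shape}"
                )
        if mismatched:
            raise ValueError("trunk transplant incompatibility: " + ", ".join(mismatched))
        for name in _trunk_shapes(self.config):
            self.params[name] = trunk_params[name].copy()


class PiCAPHeadView:
    """Trainable view of a protein model's pooling head over cached trunk maps.

    ``forward`` consumes a precomputed pooled map (from
    :meth:`PiCAP.trunk_pooled`) instead of a graph, so a training loop over
    this view touches only head tensors — the trunk stays frozen and its
    forward pass is paid once per protein.  Call :meth:`commit` to write the
    trained head back into the underlying model.
    """

    def __init__(self, model: PiCAP):
        self._model = model
        head_keys = set(PiCAP.head_shapes(model.config))
        self.params = {k: model.params[k] for k in head_keys}

    def forward(self, pooled, params: dict | None = None) -> float:
        p = self.params if params is None else params
        merged = dict(self._model.params)
        merged.update(p)
        return self._model.head_forward(pooled, merged)

    def commit(self) -> PiCAP:
        self._model.params.update(self.params)
        return self._model


def save_checkpoint(model: _ModelBase, path: str | Path, history: dict | None = None) -> Path:
    """Write weights + config (+ optional training history) to an .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "model_class": type(model).__name__,
        "config": asdict(model.config),
        "history": history or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)
    return path


def load_checkpoint(path: str | Path):
    """Load a checkpoint; returns the reconstructed model (weights installed)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = meta["config"]
    for key in ("picap_k_schedule", "conv_channels", "dense_widths"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = ModelConfig(**cfg_dict)
    cls = {"Capsif2": Capsif2, "PiCAP": PiCAP}[meta["model_class"]]
    model = cls(cfg)
    for name in model.params:
        if name not in params:
            raise ValueError(f"checkpoint missing tensor {name}")
        if params[name].shape != model.params[name].shape:
            raise ValueError(f"checkpoint tensor {name} has wrong shape")
    model.params = params
    model.history = meta.get("history", {})
    return model
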