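"""The compact two-block CNN: temporal conv -> depthwise spatial conv ->
separable conv -> dense, with batch norm, ELU, average pooling and dropout.

Implemented directly in NumPy with analytic backprop; the input-gradient path
(gradient of the pre-softmax class score w.r.t. the 8 x 201 input) is the
contract the saliency module builds on and is validated against finite
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import layers as L
from .ops import elu, elu_grad, softmax


@dataclass(frozen=True)
class EEGNetConfig:
    n_channels: int = 8
    n_samples: int = 201
    temporal_filters: int = 8  # F1
    temporal_kernel: int = 64
    depth_multiplier: int = 2  # D -> F1*D = 16 depthwise outputs
    separable_filters: int = 16  # F2
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout_rate: float = 0.5
    n_classes: int = 2
    max_norm: float | None = None  # optional depthwise weight constraint

    def __post_init__(self) -> None:
        if self.pool1 < 1 or self.pool2 < 1:
            raise ValueError("pool sizes must be >= 1")
        if self.flatten_length == 0:
            raise ValueError("pooling produces a zero-length feature vector")

    @property
    def depthwise_outputs(self) -> int:
        return self.temporal_filters * self.depth_multiplier

    @property
    def pool1_length(self) -> int:
        return self.n_samples // self.pool1

    @property
    def pool2_length(self) -> int:
        return self.pool1_length // self.pool2

    @property
    def flatten_length(self) -> int:
        return self.separable_filters * self.pool2_length

    def layer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Per-layer output dimensions in the printed-table convention.

        The temporal-convolution row is reported as (filters, 1, time); the
        true tensor additionally retains the electrode axis until the
        depthwise stage (see ``tensor_shapes``).
        """
        c, t = self.n_channels, self.n_samples
        f1, fd, f2 = self.temporal_filters, self.depthwise_outputs, self.separable_filters
        t1, t2 = self.pool1_length, self.pool2_length
        return [
            ("input", (c, t)),
            ("reshape", (1, c, t)),
            ("conv_temporal", (f1, 1, t)),
            ("batchnorm1", (f1, 1, t)),
            ("depthwise", (fd, 1, t)),
            ("batchnorm2", (fd, 1, t)),
            ("elu1", (fd, 1, t)),
            ("avgpool1", (fd, 1, t1)),
            ("dropout1", (fd, 1, t1)),
            ("separable", (f2, 1, t1)),
            ("batchnorm3", (f2, 1, t1)),
            ("elu2", (f2, 1, t1)),
            ("avgpool2", (f2, 1, t2)),
            ("dropout2", (f2, 1, t2)),
            ("flatten", (self.flatten_length,)),
            ("dense", (self.n_classes,)),
        ]

    def tensor_shapes(self) -> dict[str, tuple[int, ...]]:
        """True per-sample tensor shapes (electrode axis retained where real)."""
        c, t = self.n_channels, self.n_samples
        return {
            "input": (c, t),
            "conv_temporal": (self.temporal_filters, c, t),
            "depthwise": (self.depthwise_outputs, t),
            "avgpool1": (self.depthwise_outputs, self.pool1_length),
            "separable": (self.separable_filters, self.pool1_length),
            "avgpool2": (self.separable_filters, self.pool2_length),
            "flatten": (self.flatten_length,),
            "dense": (self.n_classes,),
        }


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class EEGNet:
    """Trainable network instance holding parameters and batch-norm state."""

    def __init__(self, config: EEGNetConfig, seed: int = 0, dtype=np.float64):
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        cfg = config
        f1, k1 = cfg.temporal_filters, cfg.temporal_kernel
        d, c = cfg.depth_multiplier, cfg.n_channels
        f2, k2 = cfg.separable_filters, cfg.separable_kernel
        fd = cfg.depthwise_outputs
        self.params: dict[str, np.ndarray] = {
            "w_temp": _glorot(rng, (f1, k1), k1, f1 * k1),
            "bn1_gamma": np.ones(f1),
            "bn1_beta": np.zeros(f1),
            "w_depth": _glorot(rng, (f1, d, c), c, d * c),
            "bn2_gamma": np.ones(fd),
            "bn2_beta": np.zeros(fd),
            "w_sep_t": _glorot(rng, (fd, k2), k2, k2),
            "w_sep_p": _glorot(rng, (f2, fd), fd, f2),
            "bn3_gamma": np.ones(f2),
            "bn3_beta": np.zeros(f2),
            "w_dense": _glorot(rng, (cfg.flatten_length, cfg.n_classes), cfg.flatten_length, cfg.n_classes),
            "b_dense": np.zeros(cfg.n_classes),
        }
        self.params = {k: v.astype(self.dtype) for k, v in self.params.items()}
        self.bn_state = {
            name: {"mean": np.zeros(nc, self.dtype), "var": np.ones(nc, self.dtype)}
            for name, nc in (("bn1", f1), ("bn2", fd), ("bn3", f2))
        }

    # ------------------------------------------------------------- forward --
    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None):
        """Compute logits for a batch. x: (N, channels, samples).

        Returns (logits, caches); caches feed :meth:`backward`.
        """
        p, cfg = self.params, self.config
        x = np.asarray(x, dtype=self.dtype)
        caches: dict[str, object] = {}
        h, caches["conv"] = L.conv_temporal_forward(x, p["w_temp"])  # (N,F1,C,T)
        h, caches["bn1"] = L.batchnorm_forward(
            h, p["bn1_gamma"], p["bn1_beta"], self.bn_state["bn1"], training
        )
        h, caches["depth"] = L.depthwise_spatial_forward(h, p["w_depth"])  # (N,FD,T)
        h, caches["bn2"] = L.batchnorm_forward(
            h, p["bn2_gamma"], p["bn2_beta"], self.bn_state["bn2"], training
        )
        caches["elu1"] = h
        h = elu(h)
        h, caches["pool1"] = L.avgpool_forward(h, cfg.pool1)
        h, caches["drop1"] = L.dropout_forward(h, cfg.dropout_rate, training, rng)
        h, caches["sep"] = L.separable_forward(h, p["w_sep_t"], p["w_sep_p"])
        h, caches["bn3"] = L.batchnorm_forward(
            h, p["bn3_gamma"], p["bn3_beta"], self.bn_state["bn3"], training
        )
        caches["elu2"] = h
        h = elu(h)
        h, caches["pool2"] = L.avgpool_forward(h, cfg.pool2)
        h, caches["drop2"] = L.dropout_forward(h, cfg.dropout_rate, training, rng)
        caches["flat_shape"] = h.shape
        flat = h.reshape(len(h), -1)
        logits, caches["dense"] = L.dense_forward(flat, p["w_dense"], p["b_dense"])
        return logits, caches

    # ------------------------------------------------------------ backward --
    def backward(self, dlogits: np.ndarray, caches: dict) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Backprop from dL/dlogits; returns (parameter grads, dL/dinput)."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        dflat, grads["w_dense"], grads["b_dense"] = L.dense_backward(
            dlogits, caches["dense"], p["w_dense"]
        )
        dh = dflat.reshape(caches["flat_shape"])
        dh = L.dropout_backward(dh, caches["drop2"])
        dh = L.avgpool_backward(dh, caches["pool2"])
        dh = dh * elu_grad(caches["elu2"])
        dh, grads["bn3_gamma"], grads["bn3_beta"] = L.batchnorm_backward(dh, caches["bn3"])
        dh, grads["w_sep_t"], grads["w_sep_p"] = L.separable_backward(dh, caches["sep"])
        dh = L.dropout_backward(dh, caches["drop1"])
        dh = L.avgpool_backward(dh, caches["pool1"])
        dh = dh * elu_grad(caches["elu1"])
        dh, grads["bn2_gamma"], grads["bn2_beta"] = L.batchnorm_backward(dh, caches["bn2"])
        dh, grads["w_depth"] = L.depthwise_spatial_backward(dh, caches["depth"])
        dh, grads["bn1_gamma"], grads["bn1_beta"] = L.batchnorm_backward(dh, caches["bn1"])
        dx, grads["w_temp"] = L.conv_temporal_backward(dh, caches["conv"])
        return grads, dx

    # ----------------------------------------------------------- inference --
    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities (N, 2) in eval mode (running BN stats, no dropout)."""
        x = np.atleast_3d(np.asarray(x, dtype=float))
        out = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size], training=False)
            out.append(softmax(logits, axis=1))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def class_score(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """Pre-softmax score h_c for each epoch in the batch."""
        logits, _ = self.forward(np.atleast_3d(x), training=False)
        return logits[:, class_index]

    def input_gradient(self, x: np.ndarray, class_index: int, batch_size: int = 256) -> np.ndarray:
        """d h_c / d input, per epoch, in eval mode. x: (N, C, T) or (C, T)."""
        if not 0 <= class_index < self.config.n_classes:
            raise IndexError(f"class index {class_index} out of range")
        x = np.asarray(x, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        grads = []
        for i in range(0, len(x), batch_size):
            xb = x[i : i + batch_size]
            logits, caches = self.forward(xb, training=False)
            dlogits = np.zeros_like(logits)
            dlogits[:, class_index] = 1.0
            _, dx = self.backward(dlogits, caches)
            grads.append(dx)
        dx = np.concatenate(grads, axis=0)
        return dx[0] if single else dx

    def layer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        return self.config.layer_shapes()

    # -------------------------------------------------------- serialization --
    def state_dict(self) -> dict:
        state = {f"param/{k}": v for k, v in self.params.items()}
        for bn, st in self.bn_state.items():
            state[f"bn/{bn}/mean"] = st["mean"]
            state[f"bn/{bn}/var"] = st["var"]
        return state

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.array(state[f"param/{k}"])
        for bn, st in self.bn_state.items():
            st["mean"] = np.array(state[f"bn/{bn}/mean"])
            st["var"] = np.array(state[f"bn/{bn}/var"])

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, config: EEGNetConfig | None = None) -> "EEGNet":
        model = cls(config or EEGNetConfig())
        with np.load(path) as z:
            model.load_state_dict(dict(z))
        return model

    def apply_max_norm(self) -> None:
        """Optional max-norm constraint on the depthwise spatial filters."""
        mn = self.config.max_norm
        if mn is None:
            return
        w = self.params["w_depth"]
        norms = np.linalg.norm(w, axis=2, keepdims=True)
        self.params["w_depth"] = w * np.minimum(1.0, mn / np.maximum(norms, 1e-12))


def build_model(config: EEGNetConfig | None = None, seed: int = 0, dtype=np.float64) -> EEGNet:
    """Construct an initialized (untrained) network.

    ``dtype=np.float32`` roughly halves training cost; float64 (default) is
    required for tight finite-difference gradient checks.
    """
    return EEGNet(config or EEGNetConfig(), seed=seed, dtype=dtype)
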