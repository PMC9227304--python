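"""Capsule network with dynamic (agreement) routing, in pure NumPy.

Architecture, for a 28x28 single-channel input:

* ``Conv1``: valid 9x9 convolution, stride 1, ReLU -> ``conv1_channels`` x 20 x 20.
* Primary capsules: a second valid 9x9 convolution with stride 2 ->
  ``primary_channels`` x 6 x 6, reshaped into 8-D capsule vectors (32
  capsule types on the 6x6 grid at the default width gives 1152 primary
  capsules), each squashed.
* Class capsules: one capsule per class.  Each primary capsule ``i``
  predicts every class capsule ``j`` through a learned matrix ``W_ij``
  (``u_hat_{j|i} = W_ij u_i``); agreement routing iteratively re-weights
  these predictions with coupling coefficients ``c_ij`` (softmax over
  classes of log-priors ``b_ij``), sums them (``s_j``), squashes
  (``v_j``), and reinforces couplings by the dot-product agreement
  ``a_ij = v_j . u_hat_{j|i}``.  Routing is full-link: every primary
  capsule routes to every class capsule.

The length of ``v_j`` encodes the probability that class ``j`` is
present; training minimizes a separation margin loss on those lengths.
Gradients are hand-written and checked against finite differences in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._conv import conv2d_backward, conv2d_forward, conv_output_size
from .imaging import SampleImage

__all__ = [
    "CapsNetConfig",
    "CapsNetParams",
    "RoutingState",
    "squash",
    "predict_uhat",
    "dynamic_routing",
    "forward",
    "margin_loss",
    "init_params",
    "AdamState",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class CapsNetConfig:
    """Architecture and loss hyperparameters.

    Defaults reproduce the full-width network (1152 primary capsules);
    narrower ``conv1_channels`` / ``primary_channels`` give the same
    topology at lower cost.
    """

    image_side: int = 28
    conv1_channels: int = 256
    conv1_kernel: int = 9
    conv1_stride: int = 1
    primary_channels: int = 256
    primary_kernel: int = 9
    primary_stride: int = 2
    primary_caps_dim: int = 8
    n_classes: int = 3
    class_caps_dim: int = 16
    routing_iterations: int = 3
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_: float = 0.5
    w_init_std: float = 0.1

    def __post_init__(self) -> None:
        if self.primary_channels % self.primary_caps_dim != 0:
            raise ValueError("primary_channels must be a multiple of primary_caps_dim")
        if self.routing_iterations < 1:
            raise ValueError("routing_iterations must be >= 1")
        if min(self.conv1_channels, self.primary_channels, self.n_classes) < 1:
            raise ValueError("channel and class counts must be positive")

    @property
    def conv1_grid(self) -> int:
        """Spatial side after Conv1 (20 for a 28x28 input)."""
        return conv_output_size(self.image_side, self.conv1_kernel, self.conv1_stride)

    @property
    def primary_grid(self) -> int:
        """Spatial side of the primary-capsule grid (6 for a 28x28 input)."""
        return conv_output_size(self.conv1_grid, self.primary_kernel, self.primary_stride)

    @property
    def primary_caps_types(self) -> int:
        """Number of capsule types per grid cell (32 at default width)."""
        return self.primary_channels // self.primary_caps_dim

    @property
    def n_primary(self) -> int:
        """Total primary capsules (1152 at default width)."""
        return self.primary_grid**2 * self.primary_caps_types


@dataclass
class CapsNetParams:
    """All learnable tensors."""

    conv1_w: np.ndarray  # (C1, 1, k, k)
    conv1_b: np.ndarray  # (C1,)
    conv2_w: np.ndarray  # (C2, C1, k, k)
    conv2_b: np.ndarray  # (C2,)
    W: np.ndarray  # (n_primary, n_classes, class_caps_dim, primary_caps_dim)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "conv1_w": self.conv1_w,
            "conv1_b": self.conv1_b,
            "conv2_w": self.conv2_w,
            "conv2_b": self.conv2_b,
            "W": self.W,
        }

    def copy(self) -> "CapsNetParams":
        return CapsNetParams(**{k: v.copy() for k, v in self.as_dict().items()})

    def validate(self, cfg: CapsNetConfig) -> None:
        expected = _param_shapes(cfg)
        for name, arr in self.as_dict().items():
            if arr.shape != expected[name]:
                raise ValueError(
                    f"parameter {name} has shape {arr.shape}, expected {expected[name]}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"parameter {name} contains non-finite values")


@dataclass
class RoutingState:
    """Per-forward routing quantities from the final iteration.

    ``b`` holds the log-prior couplings as they stood when the final
    class-capsule outputs ``v`` were computed (the post-final agreement
    update is never applied).
    """

    b: np.ndarray  # (B, I, J) log priors
    c: np.ndarray  # (B, I, J) coupling coefficients
    u_hat: np.ndarray  # (B, I, J, D) prediction vectors
    s: np.ndarray  # (B, J, D) pre-squash class inputs
    v: np.ndarray  # (B, J, D) class capsule outputs
    a: np.ndarray  # (B, I, J) agreements from the final iteration


def _param_shapes(cfg: CapsNetConfig) -> dict[str, tuple[int, ...]]:
    return {
        "conv1_w": (cfg.conv1_channels, 1, cfg.conv1_kernel, cfg.conv1_kernel),
        "conv1_b": (cfg.conv1_channels,),
        "conv2_w": (cfg.primary_channels, cfg.conv1_channels, cfg.primary_kernel, cfg.primary_kernel),
        "conv2_b": (cfg.primary_channels,),
        "W": (cfg.n_primary, cfg.n_classes, cfg.class_caps_dim, cfg.primary_caps_dim),
    }


def init_params(cfg: CapsNetConfig, seed: int) -> CapsNetParams:
    """He-initialized conv weights, zero biases, Gaussian ``W_ij``.

    Fully determined by ``seed``; the same seed yields bit-identical
    parameters.
    """
    rng = np.random.default_rng(seed)
    k1, k2 = cfg.conv1_kernel, cfg.primary_kernel
    fan1 = 1 * k1 * k1
    fan2 = cfg.conv1_channels * k2 * k2
    conv1_w = rng.normal(0.0, np.sqrt(2.0 / fan1), size=_param_shapes(cfg)["conv1_w"])
    conv2_w = rng.normal(0.0, np.sqrt(2.0 / fan2), size=_param_shapes(cfg)["conv2_w"])
    W = rng.normal(0.0, cfg.w_init_std, size=_param_shapes(cfg)["W"])
    return CapsNetParams(
        conv1_w=conv1_w,
        conv1_b=np.zeros(cfg.conv1_channels),
        conv2_w=conv2_w,
        conv2_b=np.zeros(cfg.primary_channels),
        W=W,
    )


# ---------------------------------------------------------------- squashing


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Nonlinear squashing ``v = (|s|^2 / (1 + |s|^2)) (s / |s|)``.

    Written as ``s * |s| / (1 + |s|^2)`` so the zero vector maps to zero
    by continuity without any division guard.  Output norms lie in
    ``[0, 1)``, strictly increasing in ``|s|``, direction preserved.
    """
    s = np.asarray(s, dtype=float)
    r = np.linalg.norm(s, axis=axis, keepdims=True)
    return s * (r / (1.0 + r**2))


def _squash_backward(dv: np.ndarray, s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vector-Jacobian product of :func:`squash` at ``s``."""
    r = np.linalg.norm(s, axis=axis, keepdims=True)
    g = r / (1.0 + r**2)
    gprime = (1.0 - r**2) / (1.0 + r**2) ** 2
    r_safe = np.where(r > 0, r, 1.0)
    dot = np.sum(s * dv, axis=axis, keepdims=True)
    return g * dv + (gprime / r_safe) * dot * s


# ------------------------------------------------------------------ routing


def predict_uhat(u: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Prediction vectors ``u_hat_{j|i} = W_ij u_i``.

    ``u``: (B, I, K) or (I, K); ``W``: (I, J, D, K).
    Returns (B, I, J, D) (or (I, J, D) for unbatched input).
    """
    u = np.asarray(u, dtype=float)
    W = np.asarray(W, dtype=float)
    unbatched = u.ndim == 2
    if unbatched:
        u = u[None]
    if u.shape[1] != W.shape[0] or u.shape[2] != W.shape[3]:
        raise ValueError(
            f"shape mismatch: u {u.shape} vs W {W.shape} "
            "(expected u (B, I, K) with W (I, J, D, K))"
        )
    u_hat = np.einsum("ijdk,bik->bijd", W, u, optimize=True)
    return u_hat[0] if unbatched else u_hat


def _routing_forward(u_hat: np.ndarray, iterations: int) -> tuple[RoutingState, dict]:
    """Batched routing keeping per-iteration intermediates for backprop."""
    bsz, n_i, n_j, _ = u_hat.shape
    b = np.zeros((bsz, n_i, n_j))
    cs, ss, vs = [], [], []
    a = None
    for it in range(iterations):
        bmax = b.max(axis=2, keepdims=True)
        e = np.exp(b - bmax)
        c = e / e.sum(axis=2, keepdims=True)
        s = np.einsum("bij,bijd->bjd", c, u_hat, optimize=True)
        v = squash(s, axis=-1)
        a = np.einsum("bjd,bijd->bij", v, u_hat, optimize=True)
        cs.append(c)
        ss.append(s)
        vs.append(v)
        if it < iterations - 1:
            b = b + a
    state = RoutingState(b=b, c=cs[-1], u_hat=u_hat, s=ss[-1], v=vs[-1], a=a)
    return state, {"c": cs, "s": ss, "v": vs}


def _routing_backward(
    dv_last: np.ndarray, u_hat: np.ndarray, cache: dict
) -> np.ndarray:
    """Gradient of the routed output w.r.t. ``u_hat``, exact through every
    iteration (softmax couplings and agreement updates included)."""
    iterations = len(cache["c"])
    du_hat = np.zeros_like(u_hat)
    dv = dv_last
    db_acc = None
    for t in reversed(range(iterations)):
        c, s = cache["c"][t], cache["s"][t]
        ds = _squash_backward(dv, s)
        du_hat += np.einsum("bij,bjd->bijd", c, ds, optimize=True)
        dc = np.einsum("bijd,bjd->bij", u_hat, ds, optimize=True)
        db = c * (dc - np.sum(c * dc, axis=2, keepdims=True))
        db_acc = db if db_acc is None else db_acc + db
        if t > 0:
            # b_t = b_{t-1} + a_{t-1} with a_{t-1} = v_{t-1} . u_hat
            da = db_acc
            v_prev = cache["v"][t - 1]
            dv = np.einsum("bij,bijd->bjd", da, u_hat, optimize=True)
            du_hat += np.einsum("bij,bjd->bijd", da, v_prev, optimize=True)
    return du_hat


def dynamic_routing(u_hat: np.ndarray, iterations: int = 3) -> RoutingState:
    """Agreement routing between primary and class capsules.

    Log priors ``b`` start at zero, so the first coupling coefficients
    are uniform over classes.  Each iteration computes ``c`` (softmax of
    ``b`` over classes), ``s_j = sum_i c_ij u_hat_{j|i}``,
    ``v_j = squash(s_j)`` and the agreement ``a_ij = v_j . u_hat_{j|i}``;
    ``b`` is reinforced by ``a`` between iterations but not after the
    last one.  Routing is full-link: every primary capsule routes to
    every class capsule.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not np.all(np.isfinite(u_hat)):
        raise ValueError("u_hat contains non-finite values")
    unbatched = u_hat.ndim == 3
    if unbatched:
        u_hat = u_hat[None]
    state, _ = _routing_forward(u_hat, iterations)
    if unbatched:
        state = RoutingState(
            b=state.b[0], c=state.c[0], u_hat=state.u_hat[0],
            s=state.s[0], v=state.v[0], a=state.a[0],
        )
    return state


# ------------------------------------------------------------------ forward


def _as_batch(images) -> np.ndarray:
    """Coerce SampleImage / (H,W) / (B,H,W) / (B,1,H,W) to (B,1,H,W)."""
    if isinstance(images, SampleImage):
        x = images.pixels[None]
    elif isinstance(images, (list, tuple)) and images and isinstance(images[0], SampleImage):
        x = np.stack([im.pixels for im in images])
    else:
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4:
        raise ValueError(f"cannot interpret input of shape {np.shape(images)} as images")
    return np.ascontiguousarray(x, dtype=float)


def _forward_full(x: np.ndarray, params: CapsNetParams, cfg: CapsNetConfig) -> dict:
    """Forward pass keeping every intermediate needed for backprop."""
    if x.shape[2] != cfg.image_side or x.shape[3] != cfg.image_side:
        raise ValueError(
            f"expected {cfg.image_side}x{cfg.image_side} images, got {x.shape[2:]}"
        )
    z1, cols1 = conv2d_forward(x, params.conv1_w, params.conv1_b, cfg.conv1_stride)
    h1 = np.maximum(z1, 0.0)
    z2, cols2 = conv2d_forward(h1, params.conv2_w, params.conv2_b, cfg.primary_stride)
    bsz = x.shape[0]
    g = cfg.primary_grid
    # (B, C2, g, g) -> (B, types, dim, g, g) -> (B, types, g, g, dim) -> (B, I, dim)
    u_raw = (
        z2.reshape(bsz, cfg.primary_caps_types, cfg.primary_caps_dim, g, g)
        .transpose(0, 1, 3, 4, 2)
        .reshape(bsz, cfg.n_primary, cfg.primary_caps_dim)
    )
    u = squash(u_raw, axis=-1)
    u_hat = predict_uhat(u, params.W)
    if not np.all(np.isfinite(u_hat)):
        raise FloatingPointError("u_hat contains non-finite values")
    state, routing_cache = _routing_forward(u_hat, cfg.routing_iterations)
    lengths = np.linalg.norm(state.v, axis=-1)
    return {
        "x": x,
        "z1": z1,
        "cols1": cols1,
        "h1": h1,
        "z2": z2,
        "cols2": cols2,
        "u_raw": u_raw,
        "u": u,
        "state": state,
        "routing_cache": routing_cache,
        "lengths": lengths,
    }


def forward(
    images, params: CapsNetParams, cfg: CapsNetConfig = CapsNetConfig()
) -> tuple[np.ndarray, RoutingState]:
    """Class-capsule lengths (one per class, each in [0, 1)) and the
    routing state for the given image(s)."""
    single = isinstance(images, SampleImage) or (
        not isinstance(images, (list, tuple)) and np.asarray(images).ndim == 2
    )
    cache = _forward_full(_as_batch(images), params, cfg)
    lengths, state = cache["lengths"], cache["state"]
    if single:
        lengths = lengths[0]
        state = RoutingState(
            b=state.b[0], c=state.c[0], u_hat=state.u_hat[0],
            s=state.s[0], v=state.v[0], a=state.a[0],
        )
    return lengths, state


# --------------------------------------------------------------------- loss


def margin_loss(lengths: np.ndarray, label: int, cfg: CapsNetConfig = CapsNetConfig()) -> float:
    """Separation margin loss for one sample.

    ``sum_j [T_j max(0, m+ - |v_j|)^2 + lambda (1 - T_j) max(0, |v_j| - m-)^2]``
    with ``T_j = 1`` iff ``j == label``.  Zero exactly when the true
    class's length reaches ``m+`` and every other length is at most ``m-``.
    """
    lengths = np.asarray(lengths, dtype=float)
    if not (0 <= int(label) < cfg.n_classes) or int(label) != label:
        raise ValueError(f"label must be an integer in [0, {cfg.n_classes}), got {label}")
    t = np.zeros(cfg.n_classes)
    t[int(label)] = 1.0
    pos = np.maximum(0.0, cfg.m_plus - lengths) ** 2
    neg = np.maximum(0.0, lengths - cfg.m_minus) ** 2
    return float(np.sum(t * pos + cfg.lambda_ * (1.0 - t) * neg))


def _margin_loss_batch(
    lengths: np.ndarray, labels: np.ndarray, cfg: CapsNetConfig
) -> tuple[float, np.ndarray]:
    """Mean margin loss over a batch and its gradient w.r.t. lengths."""
    bsz = lengths.shape[0]
    t = np.zeros_like(lengths)
    t[np.arange(bsz), labels] = 1.0
    pos_gap = np.maximum(0.0, cfg.m_plus - lengths)
    neg_gap = np.maximum(0.0, lengths - cfg.m_minus)
    loss = np.sum(t * pos_gap**2 + cfg.lambda_ * (1.0 - t) * neg_gap**2) / bsz
    dlengths = (-2.0 * t * pos_gap + 2.0 * cfg.lambda_ * (1.0 - t) * neg_gap) / bsz
    return float(loss), dlengths


# ----------------------------------------------------------------- backward


def loss_and_grads(
    x: np.ndarray, labels: np.ndarray, params: CapsNetParams, cfg: CapsNetConfig
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Mean margin loss, parameter gradients and class lengths for a batch.

    Gradients are exact: the backward pass differentiates through every
    routing iteration (softmax couplings and agreement updates included).
    """
    cache = _forward_full(x, params, cfg)
    state: RoutingState = cache["state"]
    lengths = cache["lengths"]
    labels = np.asarray(labels, dtype=int)
    loss, dlengths = _margin_loss_batch(lengths, labels, cfg)

    v, u_hat = state.v, state.u_hat
    lsafe = np.where(lengths > 0, lengths, 1.0)
    dv = (dlengths / lsafe)[..., None] * v
    du_hat = _routing_backward(dv, u_hat, cache["routing_cache"])
    dW = np.einsum("bijd,bik->ijdk", du_hat, cache["u"], optimize=True)
    du = np.einsum("ijdk,bijd->bik", params.W, du_hat, optimize=True)
    du_raw = _squash_backward(du, cache["u_raw"])

    bsz = x.shape[0]
    g = cfg.primary_grid
    dz2 = (
        du_raw.reshape(bsz, cfg.primary_caps_types, g, g, cfg.primary_caps_dim)
        .transpose(0, 1, 4, 2, 3)
        .reshape(bsz, cfg.primary_channels, g, g)
    )
    dh1, dconv2_w, dconv2_b = conv2d_backward(
        dz2, cache["cols2"], cache["h1"].shape, params.conv2_w, cfg.primary_stride
    )
    dz1 = dh1 * (cache["z1"] > 0)
    _, dconv1_w, dconv1_b = conv2d_backward(
        dz1, cache["cols1"], x.shape, params.conv1_w, cfg.conv1_stride, need_dx=False
    )
    grads = {
        "conv1_w": dconv1_w,
        "conv1_b": dconv1_b,
        "conv2_w": dconv2_w,
        "conv2_b": dconv2_b,
        "W": dW,
    }
    return loss, grads, lengths


# ---------------------------------------------------------------- optimizer


class AdamState:
    """Adaptive-moment gradient descent over a parameter dictionary."""

    def __init__(self, params: CapsNetParams, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.as_dict().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.as_dict().items()}

    def step(self, params: CapsNetParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, p in params.as_dict().items():
            gr = grads[key]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * gr
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * gr**2
            p -= self.lr * (self.m[key] / b1t) / (np.sqrt(self.v[key] / b2t) + self.eps)


# -------------------------------------------------------------- checkpoints


def save_checkpoint(path, params: CapsNetParams, cfg: CapsNetConfig, seed: int) -> None:
    """Single-archive checkpoint: tensors keyed by layer name plus config
    and the init seed."""
    meta = json.dumps({"config": asdict(cfg), "seed": int(seed)})
    np.savez(path, __meta__=np.array(meta), **params.as_dict())


def load_checkpoint(path) -> tuple[CapsNetParams, CapsNetConfig, int]:
    """Load a checkpoint, rejecting shape-mismatched tensors."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        cfg = CapsNetConfig(**meta["config"])
        params = CapsNetParams(
            conv1_w=npz["conv1_w"], conv1_b=npz["conv1_b"],
            conv2_w=npz["conv2_w"], conv2_b=npz["conv2_b"], W=npz["W"],
        )
    params.validate(cfg)
    return params, cfg, meta["seed"]
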