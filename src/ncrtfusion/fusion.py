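"""Z-score standardization and the attention-based feature-fusion layer.

Each standardized scalar feature z_i is lifted to a value vector
v_i = z_i * e_i + b_i with learnable embedding e_i and offset b_i; scaled
dot-product attention between a learnable query q and per-feature keys k_i
yields softmax weights w_i = softmax(q . k_i / sqrt(d_k)), and the fused
representation is the weighted sum of the value vectors (embed-sum mode) or
the weighted scalars themselves (weighted-scalar mode).

The attention parameters are trained by minimizing the L2-regularized
logistic loss of a linear head on the fused vector with full-batch gradient
descent (step halving on any loss increase, so the recorded loss is
non-increasing); the head is then discarded and a downstream SVM is fit on
the frozen fused features. The trainer is vectorized over an arbitrary batch
of training sets so that leave-one-out folds train in one pass; the public
single-set entry point is the batch-of-one case of the same core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODES = ("embed-sum", "weighted-scalar")


class NotFittedError(ValueError):
    """Fusion parameters were not produced by training/initialization."""


@dataclass
class StandardizationParams:
    """Per-feature mean and standard deviation fitted on training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.mean)


def standardize_fit(values) -> StandardizationParams:
    """Fit per-feature mean and sample SD (ddof=1) on the supplied rows."""
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardize_fit needs a 2-D matrix with >= 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("standardize_fit: non-finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise ValueError(f"zero-variance feature column(s) {zero.tolist()}")
    return StandardizationParams(mean=mean, sd=sd)


def standardize_apply(params: StandardizationParams, values) -> np.ndarray:
    """z = (x - mean) / sd elementwise; never refits on the supplied rows."""
    X = np.asarray(values, dtype=float)
    if X.shape[-1] != params.n_features:
        raise ValueError(
            f"feature-set mismatch: params fitted on {params.n_features} features, "
            f"got {X.shape[-1]}"
        )
    return (X - params.mean) / params.sd


@dataclass
class FusionConfig:
    """Hyperparameters of the fusion layer and its surrogate training."""

    d_k: int = 8
    mode: str = "embed-sum"
    epochs: int = 200
    learning_rate: float = 0.01
    l2: float = 1e-3
    init_scale: float = 0.1
    convergence_tol: float = 1e-7  # relative improvement below which a fold stops
    monotone_tol: float = 1e-8    # accepted loss may exceed the previous by this

    def validate(self) -> None:
        if self.d_k < 1:
            raise ValueError("d_k must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.epochs < 1 or self.learning_rate <= 0 or self.l2 < 0:
            raise ValueError("epochs >= 1, learning_rate > 0 and l2 >= 0 required")


@dataclass
class FusionParams:
    """Learned fusion parameters for one training set.

    ``query`` (d_k,), ``keys``/``embeds``/``offsets`` (m, d_k). In
    weighted-scalar mode embeds/offsets are unused and stay at their
    initialization. ``head_w``/``head_b`` are the training-time logistic head
    (kept for inspection; downstream classification uses the SVM instead).
    """

    d_k: int
    mode: str
    query: np.ndarray
    keys: np.ndarray
    embeds: np.ndarray
    offsets: np.ndarray
    head_w: np.ndarray | None = None
    head_b: float = 0.0
    loss_history: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_features(self) -> int:
        return self.keys.shape[0]


def attention_weights(params: FusionParams, active=None) -> np.ndarray:
    """Softmax attention weights over the active feature subset.

    ``active`` holds positions into the params' feature axis (default: all).
    Weights are nonnegative and sum to one over the subset.
    """
    if params.query is None or params.keys is None:
        raise NotFittedError("fusion parameters are not initialized")
    m = params.n_features
    idx = np.arange(m) if active is None else np.asarray(list(active), dtype=int)
    if idx.size == 0:
        raise ValueError("active feature subset must be nonempty")
    if (idx < 0).any() or (idx >= m).any():
        raise ValueError(f"active positions must be in 0..{m - 1}")
    scores = params.keys[idx] @ params.query / np.sqrt(params.d_k)
    scores = scores - scores.max()  # shift invariance / overflow guard
    w = np.exp(scores)
    return w / w.sum()


def fuse(params: FusionParams, z, active=None) -> np.ndarray:
    """Fused representation of standardized row(s) ``z``.

    embed-sum: sum_i w_i (z_i e_i + b_i) in R^{d_k}; weighted-scalar:
    (w_i z_i) over the active subset. Accepts a single row or a matrix.
    """
    if params.embeds is None and params.mode == "embed-sum":
        raise NotFittedError("fusion parameters are not initialized")
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    Z = np.atleast_2d(z)
    m = params.n_features
    idx = np.arange(m) if active is None else np.asarray(list(active), dtype=int)
    if Z.shape[1] != idx.size:
        raise ValueError(f"z has {Z.shape[1]} columns but {idx.size} active features")
    w = attention_weights(params, idx)
    if params.mode == "weighted-scalar":
        out = Z * w
    else:
        out = (Z * w) @ params.embeds[idx] + w @ params.offsets[idx]
    return out[0] if single else out


def _init_params(m: int, cfg: FusionConfig, seed) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    head_dim = cfg.d_k if cfg.mode == "embed-sum" else m
    return {
        "query": cfg.init_scale * rng.standard_normal(cfg.d_k),
        "keys": cfg.init_scale * rng.standard_normal((m, cfg.d_k)),
        "embeds": cfg.init_scale * rng.standard_normal((m, cfg.d_k)),
        "offsets": cfg.init_scale * rng.standard_normal((m, cfg.d_k)),
        "head_w": cfg.init_scale * rng.standard_normal(head_dim),
        "head_b": np.zeros(()),
    }


def _forward_backward(P: dict[str, np.ndarray], Z: np.ndarray, Y: np.ndarray,
                      cfg: FusionConfig):
    """Loss and gradients for a batch of training sets.

    ``Z`` is (F, N, m) standardized features, ``Y`` is (F, N) binary labels;
    parameter arrays carry a leading fold axis F. Returns (loss (F,), grads).
    """
    lam = cfg.l2
    rd = 1.0 / np.sqrt(cfg.d_k)
    q, K, E, B = P["query"], P["keys"], P["embeds"], P["offsets"]
    theta, c = P["head_w"], P["head_b"]
    F, N, m = Z.shape

    s = (K @ q[:, :, None])[:, :, 0] * rd
    s = s - s.max(axis=1, keepdims=True)
    w = np.exp(s)
    w /= w.sum(axis=1, keepdims=True)

    Zw = Z * w[:, None, :]
    if cfg.mode == "embed-sum":
        fused = Zw @ E + (w[:, None, :] @ B)
    else:
        fused = Zw
    u = (fused @ theta[:, :, None])[:, :, 0] + c[:, None]
    # numerically stable binary cross-entropy
    bce = (np.logaddexp(0.0, u) - Y * u).mean(axis=1)
    reg = lam * (
        (q ** 2).sum(axis=-1)
        + (K ** 2).sum(axis=(-2, -1))
        + (theta ** 2).sum(axis=-1)
        + ((E ** 2).sum(axis=(-2, -1)) + (B ** 2).sum(axis=(-2, -1))
           if cfg.mode == "embed-sum" else 0.0)
    )
    loss = bce + reg

    g = (1.0 / (1.0 + np.exp(-u)) - Y) / N  # (F, N)
    d_theta = (g[:, None, :] @ fused)[:, 0, :] + 2 * lam * theta
    d_c = g.sum(axis=1)
    dF = g[:, :, None] * theta[:, None, :]  # (F, N, head_dim)
    grads = {"head_w": d_theta, "head_b": d_c}
    if cfg.mode == "embed-sum":
        M = Z.swapaxes(1, 2) @ dF  # (F, m, d_k)
        S0 = dF.sum(axis=1)
        grads["embeds"] = w[:, :, None] * M + 2 * lam * E
        grads["offsets"] = w[:, :, None] * S0[:, None, :] + 2 * lam * B
        dw = (M * E).sum(axis=-1) + (B @ S0[:, :, None])[:, :, 0]
    else:
        grads["embeds"] = np.zeros_like(E)  # unused in this mode
        grads["offsets"] = np.zeros_like(B)
        dw = (dF * Z).sum(axis=1)
    ds = w * (dw - (w * dw).sum(axis=1, keepdims=True))
    grads["query"] = (ds[:, None, :] @ K)[:, 0, :] * rd + 2 * lam * q
    grads["keys"] = ds[:, :, None] * q[:, None, :] * rd + 2 * lam * K
    return loss, grads


def _train_batch(Z: np.ndarray, Y: np.ndarray, cfg: FusionConfig, seeds):
    """Train fusion parameters for F training sets at once.

    Returns (params dict with leading fold axis, loss history (F, epochs+1)).
    Deterministic for fixed (Z, Y, cfg, seeds); the accepted per-fold loss
    sequence is non-increasing up to ``monotone_tol``.
    """
    cfg.validate()
    F, N, m = Z.shape
    if Y.shape != (F, N):
        raise ValueError("label array shape mismatch")
    for f in range(F):
        if len(np.unique(Y[f])) < 2:
            raise ValueError(f"training set {f} contains a single class")
    inits = [_init_params(m, cfg, seed) for seed in seeds]
    P = {k: np.stack([init[k] for init in inits]) for k in inits[0]}

    loss, grads = _forward_backward(P, Z, Y, cfg)
    history = [loss.copy()]
    lr = np.full(F, cfg.learning_rate)
    stalled = np.zeros(F, dtype=bool)
    for _ in range(cfg.epochs):
        if stalled.all():
            break
        cand = {}
        for k in P:
            shape = (F,) + (1,) * (P[k].ndim - 1)
            cand[k] = P[k] - lr.reshape(shape) * grads[k]
        cand_loss, cand_grads = _forward_backward(cand, Z, Y, cfg)
        accept = cand_loss <= loss + cfg.monotone_tol
        improvement = np.where(accept, loss - cand_loss, 0.0)
        for k in P:
            mask = accept.reshape((F,) + (1,) * (P[k].ndim - 1))
            P[k] = np.where(mask, cand[k], P[k])
            grads[k] = np.where(mask, cand_grads[k], grads[k])
        loss = np.where(accept, cand_loss, loss)
        lr = np.where(accept, lr, lr * 0.5)
        history.append(loss.copy())
        stalled = (accept & (improvement < cfg.convergence_tol * (1.0 + np.abs(loss)))) | (
            lr < 1e-12
        )
    return P, np.stack(history, axis=1)


def _params_from_batch(P: dict[str, np.ndarray], history: np.ndarray, f: int,
                       cfg: FusionConfig) -> FusionParams:
    return FusionParams(
        d_k=cfg.d_k,
        mode=cfg.mode,
        query=P["query"][f],
        keys=P["keys"][f],
        embeds=P["embeds"][f],
        offsets=P["offsets"][f],
        head_w=P["head_w"][f],
        head_b=float(P["head_b"][f]),
        loss_history=history[f],
    )


def train_fusion(z, labels, cfg: FusionConfig | None = None, seed: int = 0) -> FusionParams:
    """Train the fusion layer on one standardized training set.

    Deterministic for a fixed seed. Raises on single-class labels. The
    returned ``loss_history`` is the accepted (non-increasing) loss sequence.
    """
    cfg = cfg or FusionConfig()
    Z = np.asarray(z, dtype=float)
    Y = np.asarray(labels, dtype=float)
    if Z.ndim != 2:
        raise ValueError("z must be a 2-D matrix")
    if Y.shape != (Z.shape[0],):
        raise ValueError("labels must match the number of rows")
    classes, counts = np.unique(Y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need >= 2 patients per class")
    P, history = _train_batch(Z[None], Y[None], cfg, [seed])
    return _params_from_batch(P, history, 0, cfg)
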