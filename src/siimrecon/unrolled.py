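"""Unrolled variable-splitting reconstruction and self-supervised training.

The model alternates a learned residual-CNN regularizer with conjugate-
gradient data-consistency solves of ``(A^H A + mu I) x = A^H y + mu z`` for
a fixed number of unrolls; the regularizer weights are shared across
unrolls and ``mu`` is a single trainable softplus-parameterized scalar.

Training is self-supervised: the acquired k-space points are split into a
data-consistency subset (Theta) and a loss subset (Lambda); several such
splits per scan are drawn ("multi-mask"), and the normalized l1-l2 loss is
evaluated on Lambda only.  Gradients flow through the DF solves via the
implicit-function theorem (one extra CG solve per unroll), so they are
exact at DF convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classic import cg_least_squares
from .datamodel import ValidationError
from .encoding import EncodingOperator, SamplingPattern
from .network import (
    ResNetWeights,
    resnet_regularizer,
    resnet_regularizer_backward,
)

__all__ = [
    "UnrolledModel",
    "SSDUSplit",
    "TrainConfig",
    "ssdu_partition",
    "ssdu_loss",
    "unrolled_forward",
    "train_model",
    "reconstruct_with_model",
    "restore_intensity",
    "enumerate_training_frames",
    "build_training_samples",
]


def _softplus(x: float) -> float:
    return float(np.log1p(np.exp(-abs(x))) + max(x, 0.0))


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


@dataclass
class UnrolledModel:
    """Weights + trainable penalty for one operator kind."""

    weights: ResNetWeights
    mu_raw: float = -2.25  # softplus(-2.25) ~= 0.1
    n_unrolls: int = 10
    cg_iters: int = 10
    operator_kind: str = "conventional"

    @property
    def mu(self) -> float:
        return _softplus(self.mu_raw)

    @classmethod
    def init(
        cls,
        operator_kind: str = "conventional",
        n_unrolls: int = 10,
        cg_iters: int = 10,
        n_blocks: int = 15,
        n_channels: int = 64,
        seed: int = 0,
        identity: bool = False,
    ) -> "UnrolledModel":
        w = ResNetWeights.init(n_blocks, n_channels, seed=seed, identity=identity)
        return cls(weights=w, n_unrolls=n_unrolls, cg_iters=cg_iters, operator_kind=operator_kind)


@dataclass
class SSDUSplit:
    """K disjoint (Theta, Lambda) partitions of the sampling mask."""

    theta: np.ndarray  # (K, nx, ny) bool
    lam: np.ndarray  # (K, nx, ny) bool
    rho: float
    seed: int

    @property
    def n_masks(self) -> int:
        return self.theta.shape[0]


def ssdu_partition(
    pattern: SamplingPattern,
    rho: float = 0.4,
    n_masks: int = 6,
    seed: int = 0,
    center_protect: int = 3,
    sigma_frac: float = 0.5,
) -> SSDUSplit:
    """Split the sampled points into Theta (data consistency) and Lambda
    (loss) subsets, K times.

    Lambda points are drawn without replacement with a Gaussian density
    centered on DC; a ``(2*center_protect+1)^2`` central block is protected
    and stays in every Theta.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    if n_masks < 1:
        raise ValueError("need at least one mask")
    mask = pattern.mask
    nx, ny = mask.shape
    n_omega = int(mask.sum())
    n_lambda = int(round(rho * n_omega))
    if n_lambda < 1:
        raise ValueError(f"rho * |Omega| = {rho * n_omega:.2f} < 1: nothing to hold out")
    cx, cy = nx // 2, ny // 2
    protect = np.zeros_like(mask)
    protect[
        max(cx - center_protect, 0) : cx + center_protect + 1,
        max(cy - center_protect, 0) : cy + center_protect + 1,
    ] = True
    cand = np.flatnonzero(mask & ~protect)
    if n_lambda > cand.size:
        raise ValueError("rho too large for the unprotected sampled points")
    xs, ys = np.unravel_index(cand, mask.shape)
    sigma = sigma_frac * max(nx, ny)
    w = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    theta = np.empty((n_masks,) + mask.shape, dtype=bool)
    lam = np.empty_like(theta)
    for k in range(n_masks):
        pick = rng.choice(cand, size=n_lambda, replace=False, p=w)
        lk = np.zeros_like(mask)
        lk.flat[pick] = True
        lam[k] = lk
        theta[k] = mask & ~lk
    return SSDUSplit(theta=theta, lam=lam, rho=rho, seed=seed)


def ssdu_loss(
    y_pred: np.ndarray, y_meas: np.ndarray, lam_mask: np.ndarray | None = None
) -> float:
    """Normalized l1-l2 loss ||e||2/||y||2 + ||e||1/||y||1 on the loss mask."""
    if lam_mask is not None:
        y_pred = y_pred[..., lam_mask]
        y_meas = y_meas[..., lam_mask]
    if y_meas.size == 0:
        raise ValueError("empty loss mask")
    e = y_meas - y_pred
    n2 = np.linalg.norm(y_meas)
    n1 = np.abs(y_meas).sum()
    if n2 == 0:
        raise ValueError("all-zero measured k-space on the loss mask")
    return float(np.linalg.norm(e) / n2 + np.abs(e).sum() / n1)


def _ssdu_loss_grad(y_pred: np.ndarray, y_meas: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and packed complex gradient w.r.t. ``y_pred`` (full-grid arrays)."""
    e = y_meas - y_pred
    n2 = np.linalg.norm(y_meas)
    n1 = np.abs(y_meas).sum()
    e2 = np.linalg.norm(e)
    loss = float(e2 / n2 + np.abs(e).sum() / n1)
    g_e = np.zeros_like(e)
    if e2 > 0:
        g_e += e / (e2 * n2)
    mag = np.abs(e)
    g_e += np.where(mag > 0, e / np.where(mag > 0, mag, 1.0), 0.0) / n1
    return loss, -g_e


# ---------------------------------------------------------------------------
# unrolled forward / backward
# ---------------------------------------------------------------------------


def unrolled_forward(
    y: np.ndarray,
    op: EncodingOperator,
    model: UnrolledModel,
    want_cache: bool = False,
    cg_tol: float = 1e-30,
    cg_iters: int | None = None,
):
    """x0 = A^H y; then T times: z = net(x); x = argmin ||Ax-y||^2 + mu||x-z||^2."""
    mu = model.mu
    iters = model.cg_iters if cg_iters is None else cg_iters
    x = op.adjoint(y)
    steps = []
    for _ in range(model.n_unrolls):
        z, net_cache = resnet_regularizer(x, model.weights, want_cache=True)
        x_prev = x
        # warm start at the previous iterate: the DF solution moves little
        # between unrolls, which matters for the ill-conditioned siim system
        x, rep = cg_least_squares(
            op, y, tol=cg_tol, max_iter=iters, mu=mu, z=z, x0=x_prev
        )
        steps.append({"x_prev": x_prev, "z": z, "x": x, "net_cache": net_cache, "report": rep})
    if want_cache:
        return x, steps
    return x


def _unrolled_backward(
    g_x: np.ndarray,
    y: np.ndarray,
    op: EncodingOperator,
    model: UnrolledModel,
    steps: list,
    cg_tol: float = 1e-30,
    cg_iters: int | None = None,
) -> tuple[list, float]:
    """Backprop through the unrolled chain via implicit gradients.

    Returns (weight gradients, d loss / d mu_raw).
    """
    mu = model.mu
    iters = model.cg_iters if cg_iters is None else cg_iters
    w_grads = model.weights.zeros_like()
    g_mu = 0.0

    def solve(v):
        u, _ = cg_least_squares(
            _AdjointSystem(op), v, tol=cg_tol, max_iter=iters, mu=mu,
            z=np.zeros_like(v),
        )
        return u

    for t in range(len(steps) - 1, -1, -1):
        st = steps[t]
        u = solve(g_x)
        g_mu += float(np.real(np.vdot(u, st["z"] - st["x"])))
        g_z = mu * u
        g_x, grads = resnet_regularizer_backward(g_z, model.weights, st["net_cache"])
        for acc, g in zip(w_grads, grads):
            acc += g
    return w_grads, g_mu * _sigmoid(model.mu_raw)


class _AdjointSystem:
    """Wraps an operator so cg_least_squares solves M u = v with the same
    normal matrix but right-hand side v supplied directly in image space."""

    def __init__(self, op: EncodingOperator):
        self._op = op
        self.x_shape = op.x_shape

    def normal(self, x):
        return self._op.normal(x)

    def adjoint(self, v):  # rhs passthrough: b = v (+ mu * 0)
        return v


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    n_unrolls: int = 10
    cg_iters: int = 10
    n_blocks: int = 15
    n_channels: int = 64
    rho: float = 0.4
    n_masks: int = 6
    lr: float = 5e-4
    n_steps: int = 200
    n_last_frames: int = 35
    center_protect: int = 3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


def enumerate_training_frames(n_frames: int, n_last: int) -> range:
    """The frame-selection rule: keep the last ``n_last`` of ``n_frames``."""
    return range(max(0, n_frames - n_last), n_frames)


def build_training_samples(
    subjects: list[dict], operator_kind: str, n_last_frames: int = 35
) -> list[dict]:
    """Enumerate (subject, group, frame) training samples.

    Each subject dict needs: ``protocol``, ``kspace`` (frame, group, coil,
    kx, ky), ``maps`` (slice, coil, x, y), ``pattern``, ``caipi``, and —
    when ``operator_kind == "siim"`` — ``intensity`` (an IntensityMap).
    """
    samples = []
    for si, sub in enumerate(subjects):
        protocol = sub["protocol"]
        if operator_kind == "siim" and sub.get("intensity") is None:
            raise ValueError(f"subject {si}: siim training requires intensity maps")
        sms = protocol.sms_factor
        for g in range(protocol.n_groups):
            maps_g = sub["maps"][protocol.group_slices(g)]
            for t in enumerate_training_frames(protocol.n_frames, n_last_frames):
                intensity = None
                if operator_kind == "siim":
                    intensity = sub["intensity"].frame(t, protocol.group_slices(g))
                op = EncodingOperator(maps_g, sub["pattern"], sub["caipi"], intensity)
                samples.append(
                    {
                        "op": op,
                        "y": sub["kspace"][t, g],
                        "pattern": sub["pattern"],
                        "subject": si,
                        "group": g,
                        "frame": t,
                    }
                )
    return samples


class _Adam:
    def __init__(self, shapes, lr, b1, b2, eps):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def train_model(
    samples: list[dict],
    operator_kind: str,
    config: TrainConfig,
    seed: int = 0,
) -> tuple[UnrolledModel, list]:
    """Self-supervised training loop over (sample, split) pairs.

    Per step: draw a sample and one of its K Theta/Lambda splits, run the
    unrolled network with data consistency restricted to Theta, predict
    k-space on Lambda with the full forward model, and take an Adam step on
    the normalized l1-l2 loss.  Deterministic given ``seed``.
    """
    if not samples:
        raise ValueError("empty training set")
    model = UnrolledModel.init(
        operator_kind=operator_kind,
        n_unrolls=config.n_unrolls,
        cg_iters=config.cg_iters,
        n_blocks=config.n_blocks,
        n_channels=config.n_channels,
        seed=seed,
    )
    splits = [
        ssdu_partition(
            s["pattern"],
            rho=config.rho,
            n_masks=config.n_masks,
            seed=seed + 1000 * i,
            center_protect=config.center_protect,
        )
        for i, s in enumerate(samples)
    ]
    opt = _Adam(
        [t.shape for t in model.weights.tensors] + [()],
        config.lr,
        config.adam_beta1,
        config.adam_beta2,
        config.adam_eps,
    )
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(config.n_steps):
        i = int(rng.integers(len(samples)))
        k = int(rng.integers(splits[i].n_masks))
        loss, w_grads, g_mu = _training_step(samples[i], splits[i], k, model)
        new = opt.step(
            model.weights.tensors + [np.asarray(model.mu_raw)],
            w_grads + [np.asarray(g_mu)],
        )
        model.weights.tensors = new[:-1]
        model.mu_raw = float(new[-1])
        trace.append(loss)
    return model, trace


def _training_step(sample: dict, split: SSDUSplit, k: int, model: UnrolledModel):
    op = sample["op"]
    y = sample["y"]
    theta_op = op.with_mask(split.theta[k])
    lam_mask = split.lam[k]
    lam_op = op.with_mask(lam_mask)
    y_theta = y * split.theta[k]
    x, steps = unrolled_forward(y_theta, theta_op, model, want_cache=True)
    y_pred = lam_op.forward(x)
    y_lam = y * lam_mask
    loss, g_pred = _ssdu_loss_grad(y_pred[:, lam_mask], y_lam[:, lam_mask])
    g_full = np.zeros_like(y_pred)
    g_full[:, lam_mask] = g_pred
    g_x = lam_op.adjoint(g_full)
    w_grads, g_mu = _unrolled_backward(g_x, y_theta, theta_op, model, steps)
    return loss, w_grads, g_mu


def reconstruct_with_model(
    y: np.ndarray, op: EncodingOperator, model: UnrolledModel
) -> np.ndarray:
    """Inference: unrolled forward with the full sampling mask in DF."""
    if model.operator_kind != op.kind:
        raise ValidationError(
            f"model trained for {model.operator_kind!r} operators, got {op.kind!r}"
        )
    return unrolled_forward(y, op, model)


def restore_intensity(x_siim: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    """Pixelwise multiplication with the (floored) intensity map."""
    intensity = np.asarray(intensity)
    if intensity.shape != np.shape(x_siim):
        raise ValidationError("intensity map shape does not match image")
    if np.any(intensity <= 0):
        raise ValidationError("intensity map must be floored strictly positive")
    return intensity * x_siim
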