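"""Training objectives and schedules for the harmonization models.

Three models are trained in this package: a supervised segmentation U-Net, a
latent-space adversarial variant whose decoder features are pushed to be
domain-indistinguishable, and an image-space adversarial variant in which a
generator translates source volumes into target-like volumes.  This module
holds every scalar objective they use:

* the generalized Dice loss, with per-class weights ``w_l = 1 / (sum_n t_ln)^2``
  so small structures count as much as large ones;
* the binary cross-entropy domain-classifier loss for latent adaptation and
  the least-squares GAN losses for image adaptation;
* global normalized cross-correlation (NCC), used to constrain the generator
  to preserve anatomy;
* the combined objectives ``L_seg - alpha * L_adv`` (latent) and
  ``L_seg + L_adv + lambda * (1 - NCC)`` (image);
* the adversarial-weight ramp ``alpha(epoch)`` and the two learning-rate
  schedules (decaying-triangular cyclical, and linear decay).

All loss functions accept numpy arrays or autograd Tensors and return a
scalar Tensor (float() gives the value), so the same code path serves both
unit tests and training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "AlphaSchedule",
    "GanLabels",
    "LRScheduleSpec",
    "generalized_dice_loss",
    "alpha",
    "domain_classifier_loss",
    "lsgan_discriminator_loss",
    "lsgan_generator_adv_loss",
    "ncc",
    "method2_segmenter_loss",
    "method3_gen_seg_loss",
    "learning_rate",
]


# ---------------------------------------------------------------------------
# schedule / label specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlphaSchedule:
    """Linear ramp for the latent adversarial weight.

    alpha is 0 before `start_epoch`, rises linearly to `max_value` at
    `plateau_epoch`, and stays there.
    """

    start_epoch: int = 20
    plateau_epoch: int = 50
    max_value: float = 0.05

    def __post_init__(self):
        if not (0 <= self.start_epoch < self.plateau_epoch):
            raise ValueError("require 0 <= start_epoch < plateau_epoch")
        if self.max_value <= 0:
            raise ValueError("max_value must be positive")


@dataclass(frozen=True)
class GanLabels:
    """LSGAN targets: `a` for synthesized volumes, `b` for real ones."""

    a: float = 0.0
    b: float = 1.0

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("GAN labels a and b must differ")


@dataclass(frozen=True)
class LRScheduleSpec:
    """Learning-rate schedule.

    kind="cyclical_decaying": triangular wave between base_lr and a per-cycle
    maximum that halves every cycle (Smith's triangular2), floored at base_lr.
    kind="linear_decay": linear from start_lr to 0 over total_epochs.
    """

    kind: str = "cyclical_decaying"
    base_lr: float = 2e-6
    max_lr: float = 2e-3
    cycle_len_epochs: int = 10
    start_lr: float = 2e-3
    total_epochs: int = 100

    def __post_init__(self):
        if self.kind not in ("cyclical_decaying", "linear_decay"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "cyclical_decaying" and not (0 < self.base_lr < self.max_lr):
            raise ValueError("cyclical schedule requires 0 < base_lr < max_lr")
        if self.start_lr <= 0 or self.total_epochs <= 0:
            raise ValueError("start_lr and total_epochs must be positive")


def alpha(epoch: int, sched: AlphaSchedule = AlphaSchedule()) -> float:
    """Adversarial weight at a given epoch (non-decreasing, piecewise linear)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if epoch <= sched.start_epoch:
        return 0.0
    if epoch >= sched.plateau_epoch:
        return sched.max_value
    frac = (epoch - sched.start_epoch) / (sched.plateau_epoch - sched.start_epoch)
    return frac * sched.max_value


def learning_rate(epoch: float, spec: LRScheduleSpec) -> float:
    """Learning rate at an epoch (fractional epochs allowed for per-step use)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if spec.kind == "linear_decay":
        return spec.start_lr * max(0.0, 1.0 - epoch / spec.total_epochs)
    # triangular2: amplitude halves each cycle, floored at base_lr
    cycle = int(epoch // spec.cycle_len_epochs)
    pos = (epoch % spec.cycle_len_epochs) / spec.cycle_len_epochs  # in [0, 1)
    tri = 1.0 - abs(2.0 * pos - 1.0)  # 0 -> 1 -> 0 over the cycle
    amp = (spec.max_lr - spec.base_lr) * 0.5**cycle
    return spec.base_lr + amp * tri


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def generalized_dice_loss(pred, target) -> Tensor:
    """Generalized Dice loss over per-class probability maps.

    pred, target: (C, ...) or (N, C, ...) arrays; channel axis holds the
    classes.  target must be one-hot.  ``L = 1 - 2 * sum_l w_l sum_n p t /
    sum_l w_l sum_n (p + t)`` with ``w_l = 1/(sum_n t_ln)^2``.  Classes with no
    voxels in the target are excluded from both sums (their weight is
    undefined); this keeps the loss in [0, 1].
    """
    pred = _as_tensor(pred)
    target = _as_tensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    tdata = target.data
    if not np.all((tdata == 0) | (tdata == 1)):
        raise ValueError("target must be one-hot (0/1)")
    # flatten to (C, V); for batched (N, C, ...) input, samples pool into V
    def flat(t: Tensor) -> Tensor:
        if t.ndim >= 4:  # (N, C, spatial...)
            n, c = t.shape[0], t.shape[1]
            v = int(np.prod(t.shape[2:]))
            return t.reshape(n, c, v).transpose((1, 0, 2)).reshape(c, n * v)
        return t.reshape(t.shape[0], -1)

    p2 = flat(pred)
    t2 = flat(target)
    tsum = t2.data.sum(axis=1)
    present = tsum > 0
    if not np.any(present):
        raise ValueError("target contains no foreground in any class")
    w = np.zeros_like(tsum)
    w[present] = 1.0 / tsum[present] ** 2
    wt = Tensor(w[:, None])
    inter = (p2 * t2 * wt).sum()
    denom = ((p2 + t2) * wt).sum()
    return 1.0 - 2.0 * inter / denom


def domain_classifier_loss(logits, domain_label: float) -> Tensor:
    """Mean binary cross-entropy of patch logits against a constant label.

    Numerically stable form: ``max(z, 0) - z*y + log(1 + exp(-|z|))``.
    """
    z = _as_tensor(logits)
    y = float(domain_label)
    mask = Tensor((z.data > 0).astype(z.data.dtype))
    absz = z * (mask * 2.0 - 1.0)
    softplus = ((-absz).exp() + 1.0).log()
    return (z * mask - z * y + softplus).mean()


def lsgan_discriminator_loss(d_real, d_fake, labels: GanLabels = GanLabels()) -> Tensor:
    """LSGAN discriminator loss: E[(D(real)-b)^2] + E[(D(fake)-a)^2]."""
    dr = _as_tensor(d_real)
    df = _as_tensor(d_fake)
    return ((dr - labels.b) ** 2.0).mean() + ((df - labels.a) ** 2.0).mean()


def lsgan_generator_adv_loss(d_fake, labels: GanLabels = GanLabels()) -> Tensor:
    """LSGAN generator adversarial loss: E[(D(G(x))-b)^2]."""
    df = _as_tensor(d_fake)
    return ((df - labels.b) ** 2.0).mean()


def ncc(x, y) -> Tensor:
    """Global normalized cross-correlation (Pearson) of two volumes, in [-1, 1]."""
    xt = _as_tensor(x)
    yt = _as_tensor(y)
    if xt.shape != yt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {yt.shape}")
    if float(np.var(xt.data)) == 0.0 or float(np.var(yt.data)) == 0.0:
        raise ValueError("ncc undefined for zero-variance input")
    xc = xt - xt.mean()
    yc = yt - yt.mean()
    num = (xc * yc).mean()
    den = ((xc**2.0).mean() * (yc**2.0).mean()) ** 0.5
    return num / den


def method2_segmenter_loss(l_seg, l_adv, epoch: int,
                           sched: AlphaSchedule = AlphaSchedule()):
    """Latent-adaptation segmenter objective: L_seg - alpha(epoch) * L_adv."""
    a = alpha(epoch, sched)
    if isinstance(l_seg, Tensor) or isinstance(l_adv, Tensor):
        return _as_tensor(l_seg) - a * _as_tensor(l_adv)
    return float(l_seg) - a * float(l_adv)


def method3_gen_seg_loss(l_seg, l_adv, l_ncc_term, lambda_ncc: float = 1.0):
    """Image-adaptation generator+segmenter objective.

    ``L_seg + L_adv + lambda_ncc * (1 - NCC)``; `l_ncc_term` is the already
    formed ``1 - NCC`` penalty.
    """
    if lambda_ncc < 0:
        raise ValueError("lambda_ncc must be >= 0")
    if any(isinstance(v, Tensor) for v in (l_seg, l_adv, l_ncc_term)):
        return _as_tensor(l_seg) + _as_tensor(l_adv) + lambda_ncc * _as_tensor(l_ncc_term)
    return float(l_seg) + float(l_adv) + lambda_ncc * float(l_ncc_term)
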