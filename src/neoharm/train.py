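"""Training orchestration for the three harmonization regimes.

* ``baseline``: supervised segmentation U-Net on labeled source volumes,
  generalized Dice loss, Adam (default betas) with the decaying-cyclical
  learning rate.
* ``latent_da``: the same segmenter plus a PatchGAN domain classifier fed
  with the stacked decoder features of both domains.  The discriminator
  minimizes domain cross-entropy (Adam beta1=0.5, linearly decaying LR);
  the segmenter minimizes ``L_seg - alpha(epoch) * L_adv`` on alternating
  updates, which drives its features toward domain-invariance.  Target
  labels are never read.
* ``image_da``: a generator U-Net translates source volumes into target-like
  volumes; an LSGAN discriminator judges real target vs synthesized volumes;
  the segmenter trains on both real source and synthesized volumes against
  the source labels; an NCC penalty ties each synthesized volume to its
  source anatomy.  Target labels are never read.
* ``parcellation``: a U-Net from binary cGM masks to angular parcels
  (n_parcels + 1 softmax channels), affine-only augmentation.

Training data for the target domain is wrapped in a `GuardedSubject` whose
label accessors raise; the guard is how the "unsupervised in the target
domain" contract is enforced rather than merely promised.

Model selection keeps the epoch with the best validation mean Dice.  A
non-finite loss aborts with a diagnostic rather than silently restarting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import losses as L
from .augment import AugmentPlan, augment_pair
from .nets import (
    DiscSpec,
    PatchDiscriminator,
    UNet3d,
    UNetSpec,
    build_discriminator,
    build_generator,
    build_segmenter,
    collect_decoder_features,
)
from .nn import Adam, Tensor
from .phantom import ParcelMap, TissueLabelMap, Volume3D

__all__ = [
    "TrainPlan",
    "TrainHistory",
    "Subject",
    "GuardedSubject",
    "LabelAccessError",
    "guard_targets",
    "train_baseline",
    "train_latent_da",
    "train_image_da",
    "train_parcellation",
    "predict",
    "dice_scores",
]


class LabelAccessError(RuntimeError):
    """Raised when training code touches labels of an unsupervised domain."""


@dataclass
class Subject:
    """One training sample: an image and (optionally) its label map."""

    image: Volume3D
    labels: TissueLabelMap | None = None
    parcels: ParcelMap | None = None
    id: str = ""


class GuardedSubject:
    """Wraps a Subject; any label access raises LabelAccessError."""

    def __init__(self, subject: Subject):
        self._subject = subject

    @property
    def image(self) -> Volume3D:
        return self._subject.image

    @property
    def id(self) -> str:
        return self._subject.id

    @property
    def labels(self):
        raise LabelAccessError(
            "target-domain labels are not available to unsupervised training"
        )

    parcels = labels


def guard_targets(subjects: Sequence[Subject]) -> list[GuardedSubject]:
    return [GuardedSubject(s) for s in subjects]


@dataclass(frozen=True)
class TrainPlan:
    """Hyperparameters of one training run."""

    regime: str = "baseline"
    epochs: int = 100
    unet: UNetSpec = field(default_factory=UNetSpec)
    disc: DiscSpec = field(default_factory=DiscSpec)
    seg_lr: L.LRScheduleSpec = field(default_factory=lambda: L.LRScheduleSpec(
        kind="cyclical_decaying"))
    adv_lr: L.LRScheduleSpec = field(default_factory=lambda: L.LRScheduleSpec(
        kind="linear_decay"))
    alpha_sched: L.AlphaSchedule = field(default_factory=L.AlphaSchedule)
    gan_labels: L.GanLabels = field(default_factory=L.GanLabels)
    lambda_ncc: float = 1.0
    augment: AugmentPlan | None = None
    seed: int = 0
    val_every: int = 1

    def __post_init__(self):
        if self.regime not in ("baseline", "latent_da", "image_da", "parcellation"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class TrainHistory:
    """One record per completed epoch, exportable as a tidy DataFrame."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice: float = -np.inf

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((1, n_classes) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[0, c] = labels == c
    return out


def _as_input(img: Volume3D) -> Tensor:
    return Tensor(img.data.astype(np.float32)[None, None])


def dice_scores(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class Dice of two integer label grids (NaN where both empty)."""
    out = np.full(n_classes, np.nan)
    for c in range(n_classes):
        p = pred == c
        t = truth == c
        denom = p.sum() + t.sum()
        if denom:
            out[c] = 2.0 * (p & t).sum() / denom
    return out


def _mean_val_dice(model: UNet3d, subjects: Sequence[Subject],
                   n_classes: int, label_attr: str = "labels") -> float:
    vals = []
    for s in subjects:
        lab = getattr(s, label_attr)
        pred = predict(model, s.image)[1]
        d = dice_scores(pred.labels, lab.labels, n_classes)
        vals.append(np.nanmean(d[1:]))  # non-background classes
    return float(np.mean(vals)) if vals else float("nan")


def _check_finite(value: float, what: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite {what} at epoch {epoch}; aborting (check learning "
            "rates / data scaling)"
        )


def _maybe_augment(subject: Subject, plan: TrainPlan, rng: np.random.Generator,
                   label_attr: str = "labels"):
    img = subject.image
    lab = getattr(subject, label_attr)
    if plan.augment is not None:
        img, lab = augment_pair(img, lab, plan.augment, seed=int(rng.integers(2**31)))
    return img, lab


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def train_baseline(source_train: Sequence[Subject], source_val: Sequence[Subject],
                   plan: TrainPlan) -> tuple[UNet3d, TrainHistory]:
    """Supervised segmentation on the source domain only."""
    if not source_train:
        raise ValueError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    n_classes = plan.unet.out_channels
    model = build_segmenter(plan.unet, seed=plan.seed)
    opt = Adam(model.parameters())
    history = TrainHistory()
    best_state = model.state_dict()
    n = len(source_train)
    for epoch in range(plan.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for j, idx in enumerate(order):
            img, lab = _maybe_augment(source_train[idx], plan, rng)
            lr = L.learning_rate(epoch + j / n, plan.seg_lr)
            pred = model(_as_input(img))
            loss = L.generalized_dice_loss(pred, one_hot(lab.labels, n_classes))
            _check_finite(float(loss), "segmentation loss", epoch)
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            ep_loss += float(loss)
        val_dice = (_mean_val_dice(model, source_val, n_classes)
                    if (epoch % plan.val_every == 0) else float("nan"))
        history.append(epoch=epoch, seg_loss=ep_loss / n, val_dice=val_dice,
                       lr=L.learning_rate(epoch, plan.seg_lr))
        if np.isfinite(val_dice) and val_dice > history.best_val_dice:
            history.best_val_dice = val_dice
            history.best_epoch = epoch
            best_state = model.state_dict()
    if history.best_epoch >= 0:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# latent-space domain adaptation
# ---------------------------------------------------------------------------

def train_latent_da(source_train: Sequence[Subject],
                    target_train: Sequence[GuardedSubject],
                    source_val: Sequence[Subject],
                    target_val: Sequence[Subject],
                    plan: TrainPlan) -> tuple[UNet3d, PatchDiscriminator, TrainHistory]:
    """Adversarial feature alignment: source supervision, domain classifier.

    Target images flow through the segmenter; its decoder features feed a
    domain classifier.  Alternating updates: the discriminator minimizes
    domain cross-entropy; the segmenter minimizes
    ``L_seg - alpha(epoch) * L_adv``.  Target labels are never read (the
    GuardedSubject wrapper raises if they were).
    """
    if not source_train or not target_train:
        raise ValueError("both domains need training images")
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    n_classes = plan.unet.out_channels
    model = build_segmenter(plan.unet, seed=plan.seed)
    feat_channels = sum(model.spec.scaled_channels())
    grid = source_train[0].image.data.shape
    feat_shape = tuple(g // 2 ** (plan.unet.levels - 2) for g in grid)
    disc = build_discriminator(plan.disc, in_channels=feat_channels,
                               input_shape=feat_shape, seed=plan.seed + 1)
    seg_opt = Adam(model.parameters())
    disc_opt = Adam(disc.parameters(), betas=(0.5, 0.999))
    history = TrainHistory()
    best_state = model.state_dict()
    n = len(source_train)
    for epoch in range(plan.epochs):
        a = L.alpha(epoch, plan.alpha_sched)
        order = rng.permutation(n)
        ep = {"seg_loss": 0.0, "adv_loss": 0.0, "disc_loss": 0.0}
        for j, idx in enumerate(order):
            src = source_train[idx]
            tgt = target_train[int(rng.integers(len(target_train)))]
            img_s, lab_s = _maybe_augment(src, plan, rng)
            xs, xt = _as_input(img_s), _as_input(tgt.image)

            # discriminator update on detached features (source=0, target=1)
            fs = collect_decoder_features(model, xs).detach()
            ft = collect_decoder_features(model, xt).detach()
            d_loss = (L.domain_classifier_loss(disc(fs), 0.0)
                      + L.domain_classifier_loss(disc(ft), 1.0)) * 0.5
            _check_finite(float(d_loss), "discriminator loss", epoch)
            disc_opt.zero_grad()
            d_loss.backward()
            disc_opt.step(lr=L.learning_rate(epoch + j / n, plan.adv_lr))

            # segmenter update: source Dice minus the scaled adversarial term
            pred, feats = model.forward(xs, return_features=True)
            seg_loss = L.generalized_dice_loss(pred, one_hot(lab_s.labels, n_classes))
            ref_shape = feats[1].shape[2:]
            from .nn import concat

            fs_live = concat([f if f.shape[2:] == ref_shape
                              else f.resize_trilinear(ref_shape) for f in feats], 1)
            ft_live = collect_decoder_features(model, xt)
            adv_loss = (L.domain_classifier_loss(disc(fs_live), 0.0)
                        + L.domain_classifier_loss(disc(ft_live), 1.0)) * 0.5
            total = L.method2_segmenter_loss(seg_loss, adv_loss, epoch,
                                             plan.alpha_sched)
            _check_finite(float(total), "segmenter loss", epoch)
            seg_opt.zero_grad()
            disc.zero_grad()
            total.backward()
            seg_opt.step(lr=L.learning_rate(epoch + j / n, plan.seg_lr))
            disc.zero_grad()  # adversarial gradients must not leak into D

            ep["seg_loss"] += float(seg_loss)
            ep["adv_loss"] += float(adv_loss)
            ep["disc_loss"] += float(d_loss)
        val_s = _mean_val_dice(model, source_val, n_classes)
        val_t = _mean_val_dice(model, target_val, n_classes)
        history.append(epoch=epoch, alpha=a,
                       val_dice_source=val_s, val_dice_target=val_t,
                       **{k: v / n for k, v in ep.items()})
        if np.isfinite(val_s) and val_s > history.best_val_dice:
            history.best_val_dice = val_s
            history.best_epoch = epoch
            best_state = model.state_dict()
    if history.best_epoch >= 0:
        model.load_state_dict(best_state)
    return model, disc, history


# ---------------------------------------------------------------------------
# image-space domain adaptation
# ---------------------------------------------------------------------------

def train_image_da(source_train: Sequence[Subject],
                   target_train: Sequence[GuardedSubject],
                   source_val: Sequence[Subject],
                   target_val: Sequence[Subject],
                   plan: TrainPlan,
                   ) -> tuple[UNet3d, UNet3d, PatchDiscriminator, TrainHistory]:
    """Image translation + segmentation with an LSGAN discriminator.

    Per step: the discriminator takes one LSGAN update on (real target,
    synthesized); the generator and segmenter then share one combined update
    of ``L_seg(real) + L_seg(synth) + L_adv + lambda * (1 - NCC)``.
    Returns (generator, segmenter, discriminator, history).
    """
    if not source_train or not target_train:
        raise ValueError("both domains need training images")
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    n_classes = plan.unet.out_channels
    gen = build_generator(UNetSpec(**{**plan.unet.__dict__,
                                      "out_channels": 1, "head": "tanh"}),
                          seed=plan.seed + 2)
    model = build_segmenter(plan.unet, seed=plan.seed)
    grid = source_train[0].image.data.shape
    disc = build_discriminator(plan.disc, in_channels=1, input_shape=grid,
                               seed=plan.seed + 1)
    seg_opt = Adam(model.parameters())
    gen_opt = Adam(gen.parameters(), betas=(0.5, 0.999))
    disc_opt = Adam(disc.parameters(), betas=(0.5, 0.999))
    history = TrainHistory()
    best_state = (gen.state_dict(), model.state_dict())
    n = len(source_train)
    gl = plan.gan_labels
    for epoch in range(plan.epochs):
        order = rng.permutation(n)
        ep = {"seg_loss": 0.0, "adv_loss": 0.0, "disc_loss": 0.0, "ncc": 0.0}
        for j, idx in enumerate(order):
            src = source_train[idx]
            tgt = target_train[int(rng.integers(len(target_train)))]
            img_s, lab_s = _maybe_augment(src, plan, rng)
            xs, xt = _as_input(img_s), _as_input(tgt.image)
            lr_adv = L.learning_rate(epoch + j / n, plan.adv_lr)

            fake = gen(xs)
            # discriminator update
            d_loss = L.lsgan_discriminator_loss(disc(xt), disc(fake.detach()), gl)
            _check_finite(float(d_loss), "discriminator loss", epoch)
            disc_opt.zero_grad()
            d_loss.backward()
            disc_opt.step(lr=lr_adv)

            # generator + segmenter joint update
            target_onehot = one_hot(lab_s.labels, n_classes)
            seg_loss = (L.generalized_dice_loss(model(xs), target_onehot)
                        + L.generalized_dice_loss(model(fake), target_onehot)) * 0.5
            adv_loss = L.lsgan_generator_adv_loss(disc(fake), gl)
            ncc_val = L.ncc(xs, fake)
            total = L.method3_gen_seg_loss(seg_loss, adv_loss, 1.0 - ncc_val,
                                           plan.lambda_ncc)
            _check_finite(float(total), "generator/segmenter loss", epoch)
            seg_opt.zero_grad()
            gen_opt.zero_grad()
            disc.zero_grad()
            total.backward()
            seg_opt.step(lr=L.learning_rate(epoch + j / n, plan.seg_lr))
            gen_opt.step(lr=lr_adv)
            disc.zero_grad()  # generator gradients must not leak into D

            ep["seg_loss"] += float(seg_loss)
            ep["adv_loss"] += float(adv_loss)
            ep["disc_loss"] += float(d_loss)
            ep["ncc"] += float(ncc_val)
        val_s = _mean_val_dice(model, source_val, n_classes)
        val_t = _mean_val_dice(model, target_val, n_classes)
        history.append(epoch=epoch, val_dice_source=val_s, val_dice_target=val_t,
                       **{k: v / n for k, v in ep.items()})
        score = val_s
        if np.isfinite(score) and score > history.best_val_dice:
            history.best_val_dice = score
            history.best_epoch = epoch
            best_state = (gen.state_dict(), model.state_dict())
    if history.best_epoch >= 0:
        gen.load_state_dict(best_state[0])
        model.load_state_dict(best_state[1])
    return gen, model, disc, history


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------

def train_parcellation(masks: Sequence[Volume3D], parcel_maps: Sequence[ParcelMap],
                       plan: TrainPlan,
                       val_fraction: float = 0.25) -> tuple[UNet3d, TrainHistory]:
    """Binary cGM masks -> angular parcels (n_parcels + 1 softmax channels)."""
    if len(masks) != len(parcel_maps) or not masks:
        raise ValueError("need matching non-empty mask/parcel lists")
    for m in masks:
        vals = np.unique(m.data)
        if not np.all(np.isin(vals, [0.0, 1.0])):
            raise ValueError("parcellation inputs must be binary cGM masks")
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    n_classes = plan.unet.out_channels
    aug = plan.augment
    if aug is not None:
        aug = AugmentPlan(**{**aug.__dict__, "affine_only": True})
    eff_plan = TrainPlan(**{**plan.__dict__, "augment": aug})
    n_val = max(1, int(len(masks) * val_fraction)) if len(masks) > 1 else 0
    subjects = [Subject(image=m, labels=None, parcels=p, id=f"parc{i}")
                for i, (m, p) in enumerate(zip(masks, parcel_maps))]
    train_set = subjects[: len(subjects) - n_val]
    val_set = subjects[len(subjects) - n_val:]

    model = build_segmenter(plan.unet, seed=plan.seed)
    opt = Adam(model.parameters())
    history = TrainHistory()
    best_state = model.state_dict()
    n = len(train_set)
    for epoch in range(plan.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for j, idx in enumerate(order):
            img, lab = _maybe_augment(train_set[idx], eff_plan, rng,
                                      label_attr="parcels")
            pred = model(_as_input(img))
            loss = L.generalized_dice_loss(pred, one_hot(lab.labels, n_classes))
            _check_finite(float(loss), "parcellation loss", epoch)
            opt.zero_grad()
            loss.backward()
            opt.step(lr=L.learning_rate(epoch + j / n, plan.seg_lr))
            ep_loss += float(loss)
        val_dice = _mean_val_dice(model, val_set, n_classes, label_attr="parcels")
        history.append(epoch=epoch, seg_loss=ep_loss / n, val_dice=val_dice)
        if np.isfinite(val_dice) and val_dice > history.best_val_dice:
            history.best_val_dice = val_dice
            history.best_epoch = epoch
            best_state = model.state_dict()
    if history.best_epoch >= 0:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict(model: UNet3d, image: Volume3D):
    """Probability maps + argmax labels; pads and crops to the grid contract.

    Returns (probs, TissueLabelMap) for 7-class tissue models and
    (probs, ParcelMap) for parcellation models.
    """
    div = 2 ** (model.spec.levels - 1)
    shape = image.data.shape
    pads = [(0, (-s) % div) for s in shape]
    x = image.data
    if any(p[1] for p in pads):
        x = np.pad(x, pads, mode="edge")
    probs = model(Tensor(x.astype(np.float32)[None, None])).data[0]
    probs = probs[:, : shape[0], : shape[1], : shape[2]]
    labels = probs.argmax(axis=0).astype(np.int16)
    if model.spec.out_channels == 7:
        return probs, TissueLabelMap(labels, image.spacing_mm)
    return probs, ParcelMap(labels, image.spacing_mm,
                            n_parcels=model.spec.out_channels - 1)
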