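"""Loss and schedule oracles.

Each objective is checked against an independent brute-force evaluation of
its defining formula on toy inputs (generalized Dice, LSGAN terms, NCC and
the domain cross-entropy to 1e-10), plus the schedule fixed points: the
adversarial weight ramp and the two learning-rate schedules.
"""

import numpy as np
import pytest

from neoharm import losses as L
from neoharm.nn import Tensor


# ---------------------------------------------------------------------------
# generalized Dice
# ---------------------------------------------------------------------------

def brute_force_gdl(pred, target):
    """Direct evaluation of the weighted-overlap formula."""
    pred = pred.reshape(pred.shape[0], -1)
    target = target.reshape(target.shape[0], -1)
    num = den = 0.0
    for l in range(pred.shape[0]):
        n_l = target[l].sum()
        if n_l == 0:
            continue
        w = 1.0 / n_l**2
        num += w * (pred[l] * target[l]).sum()
        den += w * (pred[l] + target[l]).sum()
    return 1.0 - 2.0 * num / den


def test_gdl_perfect_overlap_is_zero():
    t = np.zeros((2, 4))
    t[0, :2] = 1
    t[1, 2:] = 1
    assert float(L.generalized_dice_loss(t, t)) == pytest.approx(0.0, abs=1e-12)


def test_gdl_disjoint_is_one():
    t = np.zeros((2, 4))
    t[0, :2] = 1
    t[1, 2:] = 1
    assert float(L.generalized_dice_loss(t[::-1].copy(), t)) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_gdl_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    logits = rng.standard_normal((3, 40))
    pred = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
    target = np.zeros((3, 40))
    target[rng.integers(0, 3, 40), np.arange(40)] = 1
    assert float(L.generalized_dice_loss(pred, target)) == pytest.approx(
        brute_force_gdl(pred, target), abs=1e-10)


def test_gdl_uniform_prediction_half():
    # 1D toy from first principles: 4 voxels, 2 classes, p = 0.5 everywhere
    t = np.array([[1.0, 1, 0, 0], [0, 0, 1, 1]])
    p = np.full((2, 4), 0.5)
    assert float(L.generalized_dice_loss(p, t)) == pytest.approx(
        brute_force_gdl(p, t), abs=1e-12)
    assert float(L.generalized_dice_loss(p, t)) == pytest.approx(0.5)


def test_gdl_absent_class_excluded():
    t = np.zeros((3, 4))
    t[0, :] = 1  # class 1 and 2 absent
    p = np.full((3, 4), 1 / 3)
    val = float(L.generalized_dice_loss(p, t))
    assert 0.0 <= val <= 1.0 and np.isfinite(val)


def test_gdl_decreases_toward_target():
    rng = np.random.default_rng(3)
    t = np.zeros((2, 30))
    t[0, :15] = 1
    t[1, 15:] = 1
    p0 = np.full((2, 30), 0.5)
    prev = 1.0
    for lam in (0.0, 0.3, 0.6, 0.9):
        p = (1 - lam) * p0 + lam * t
        val = float(L.generalized_dice_loss(p, t))
        assert val <= prev + 1e-12
        prev = val


def test_gdl_rejects_bad_inputs():
    t = np.zeros((2, 4))
    t[0] = 1
    with pytest.raises(ValueError):
        L.generalized_dice_loss(np.zeros((2, 5)), t)
    with pytest.raises(ValueError):
        L.generalized_dice_loss(t, t * 0.5)


# ---------------------------------------------------------------------------
# alpha ramp
# ---------------------------------------------------------------------------

def test_alpha_fixed_points():
    s = L.AlphaSchedule()
    assert L.alpha(10, s) == 0.0
    assert L.alpha(20, s) == 0.0
    assert L.alpha(35, s) == pytest.approx(0.025)
    assert L.alpha(50, s) == pytest.approx(0.05)
    assert L.alpha(75, s) == pytest.approx(0.05)


def test_alpha_monotone_piecewise_linear():
    s = L.AlphaSchedule()
    vals = [L.alpha(e, s) for e in range(100)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    ramp = np.diff(vals[21:50])
    assert np.allclose(ramp, ramp[0])


def test_alpha_schedule_validation():
    with pytest.raises(ValueError):
        L.AlphaSchedule(start_epoch=50, plateau_epoch=20)
    with pytest.raises(ValueError):
        L.alpha(-1)


# ---------------------------------------------------------------------------
# GAN losses
# ---------------------------------------------------------------------------

def test_domain_cross_entropy_closed_forms():
    assert float(L.domain_classifier_loss(np.zeros((2, 2, 2)), 1.0)) == \
        pytest.approx(np.log(2), abs=1e-12)
    assert float(L.domain_classifier_loss(np.full((3,), 50.0), 1.0)) == \
        pytest.approx(0.0, abs=1e-10)


def test_domain_cross_entropy_matches_hand_oracle():
    z = np.array([0.7, -1.3])
    for y in (0.0, 1.0):
        p = 1 / (1 + np.exp(-z))
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert float(L.domain_classifier_loss(z, y)) == pytest.approx(
            expected, abs=1e-10)


def test_lsgan_discriminator_closed_forms():
    gl = L.GanLabels()
    b = np.full((2, 2), 1.0)
    a = np.zeros((2, 2))
    assert float(L.lsgan_discriminator_loss(b, a, gl)) == 0.0
    assert float(L.lsgan_discriminator_loss(a, b, gl)) == pytest.approx(2.0)


def test_lsgan_matches_elementwise_oracle():
    rng = np.random.default_rng(0)
    d_real = rng.standard_normal((2, 3))
    d_fake = rng.standard_normal((2, 3))
    gl = L.GanLabels(a=0.1, b=0.9)
    expected = ((d_real - 0.9) ** 2).mean() + ((d_fake - 0.1) ** 2).mean()
    assert float(L.lsgan_discriminator_loss(d_real, d_fake, gl)) == \
        pytest.approx(expected, abs=1e-10)
    expected_g = ((d_fake - 0.9) ** 2).mean()
    assert float(L.lsgan_generator_adv_loss(d_fake, gl)) == \
        pytest.approx(expected_g, abs=1e-10)


def test_gan_labels_must_differ():
    with pytest.raises(ValueError):
        L.GanLabels(a=1.0, b=1.0)


# ---------------------------------------------------------------------------
# NCC
# ---------------------------------------------------------------------------

def test_ncc_self_and_affine_invariance():
    x = np.random.default_rng(0).standard_normal(64)
    assert float(L.ncc(x, x)) == pytest.approx(1.0)
    assert float(L.ncc(x, 3.0 * x + 2.0)) == pytest.approx(1.0)
    assert float(L.ncc(x, -2.0 * x)) == pytest.approx(-1.0)


def test_ncc_matches_pearson_oracle():
    x = np.array([1.0, 2.0, 4.0, 3.0])
    y = np.array([0.5, 1.5, 1.0, 2.5])
    expected = np.corrcoef(x, y)[0, 1]
    assert float(L.ncc(x, y)) == pytest.approx(expected, abs=1e-10)


def test_ncc_zero_variance_rejected():
    with pytest.raises(ValueError):
        L.ncc(np.ones(8), np.arange(8.0))


# ---------------------------------------------------------------------------
# combined objectives
# ---------------------------------------------------------------------------

def test_method2_combination():
    assert L.method2_segmenter_loss(0.4, 0.6, 75) == pytest.approx(0.37)
    assert L.method2_segmenter_loss(0.4, 0.6, 5) == pytest.approx(0.4)
    assert L.method2_segmenter_loss(0.4, 0.0, 99) == pytest.approx(0.4)


def test_method3_combination():
    assert L.method3_gen_seg_loss(0.3, 0.2, 0.1, 1.0) == pytest.approx(0.6)
    assert L.method3_gen_seg_loss(0.3, 0.2, 0.9, 0.0) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        L.method3_gen_seg_loss(0.1, 0.1, 0.1, -1.0)


def test_method3_gradient_flows_through_tensor_terms():
    x = Tensor(np.array([0.2, 0.8]), requires_grad=True)
    total = L.method3_gen_seg_loss((x**2.0).sum(), (x**2.0).mean(), 0.0, 1.0)
    total.backward()
    assert x.grad is not None


# ---------------------------------------------------------------------------
# learning-rate schedules
# ---------------------------------------------------------------------------

def test_cyclical_schedule_endpoints():
    s = L.LRScheduleSpec(kind="cyclical_decaying")
    assert L.learning_rate(0, s) == pytest.approx(2e-6)
    assert L.learning_rate(5, s) == pytest.approx(2e-3)  # mid-first-cycle peak
    assert L.learning_rate(10, s) == pytest.approx(2e-6)
    # second cycle amplitude halves (triangular2)
    assert L.learning_rate(15, s) == pytest.approx(2e-6 + (2e-3 - 2e-6) / 2)


def test_linear_decay_schedule():
    s = L.LRScheduleSpec(kind="linear_decay", start_lr=2e-3, total_epochs=100)
    assert L.learning_rate(0, s) == pytest.approx(2e-3)
    assert L.learning_rate(50, s) == pytest.approx(1e-3)
    assert L.learning_rate(100, s) == 0.0
    assert L.learning_rate(150, s) == 0.0


def test_schedule_validation():
    with pytest.raises(ValueError):
        L.LRScheduleSpec(kind="nope")
    with pytest.raises(ValueError):
        L.LRScheduleSpec(kind="cyclical_decaying", base_lr=1.0, max_lr=0.5)


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=2, max_value=4),
           st.integers(min_value=4, max_value=24))
    def test_gdl_bounded_and_monotone_toward_target(seed, n_classes, n_vox):
        """For any probabilistic prediction and one-hot target, the loss lies
        in [0, 1] and decreases along the convex path toward the target."""
        rng = np.random.default_rng(seed)
        logits = rng.standard_normal((n_classes, n_vox))
        pred = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
        target = np.zeros((n_classes, n_vox))
        target[rng.integers(0, n_classes, n_vox), np.arange(n_vox)] = 1
        vals = [float(L.generalized_dice_loss((1 - lam) * pred + lam * target,
                                              target))
                for lam in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in vals)
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.floats(min_value=0.1, max_value=5.0),
           st.floats(min_value=-3.0, max_value=3.0))
    def test_ncc_positive_affine_invariance_property(seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(32)
        y = rng.standard_normal(32)
        base = float(L.ncc(x, y))
        assert float(L.ncc(scale * x + shift, y)) == pytest.approx(base, abs=1e-8)
        assert -1.0 - 1e-12 <= base <= 1.0 + 1e-12
except ImportError:  # hypothesis is an optional test dependency
    pass
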