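"""Loss identities, confusion/metric arithmetic, and the paired t-test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from odseg.losses_metrics import (
    ConfusionCounts,
    MetricsReport,
    bce_loss,
    confusion,
    dice_loss,
    dsc,
    paired_t_test,
    sen,
    total_loss,
    write_metrics_csv,
)
from odseg.nn.tensor import Tensor


RNG = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# Dice loss


def test_dice_loss_identities_in_smooth_zero_limit():
    m = np.zeros((4, 4))
    m[1:3, 1:3] = 1.0
    assert dice_loss(m, m, smooth=0.0).item() == pytest.approx(0.0, abs=1e-12)
    disjoint = 1.0 - m
    assert dice_loss(m, disjoint, smooth=0.0).item() == pytest.approx(1.0, abs=1e-12)


def test_dice_loss_half_overlap():
    x = np.zeros(8)
    y = np.zeros(8)
    x[:4] = 1.0  # 4 foreground, overlap 2
    y[2:6] = 1.0
    assert dice_loss(x, y, smooth=0.0).item() == pytest.approx(0.5)


def test_dice_loss_differentiable_and_bounded():
    x = Tensor(RNG.uniform(0, 1, (8, 8)), requires_grad=True)
    y = (RNG.uniform(0, 1, (8, 8)) > 0.8).astype(float)
    loss = dice_loss(x, y)
    assert 0.0 <= loss.item() < 1.0
    loss.backward()
    assert x.grad is not None and np.all(np.isfinite(x.grad))


# ---------------------------------------------------------------------------
# BCE loss


def test_bce_at_half_is_log_two():
    y = (RNG.uniform(0, 1, (5, 5)) > 0.5).astype(float)
    assert bce_loss(np.full((5, 5), 0.5), y).item() == pytest.approx(np.log(2.0), abs=1e-12)


def test_bce_perfect_prediction_near_zero():
    y = (RNG.uniform(0, 1, (6, 6)) > 0.7).astype(float)
    assert bce_loss(y, y).item() <= 1e-6


def test_bce_matches_per_pixel_loop():
    x = RNG.uniform(0.05, 0.95, (4, 4))
    y = (RNG.uniform(0, 1, (4, 4)) > 0.5).astype(float)
    acc = 0.0
    for i in range(4):
        for j in range(4):
            acc += -(y[i, j] * np.log(x[i, j]) + (1 - y[i, j]) * np.log(1 - x[i, j]))
    assert bce_loss(x, y).item() == pytest.approx(acc / 16.0, abs=1e-8)
    assert bce_loss(x, y, reduction="sum").item() == pytest.approx(acc, abs=1e-8)


def test_total_loss_is_exact_component_sum():
    x = RNG.uniform(0, 1, (8, 8))
    y = (RNG.uniform(0, 1, (8, 8)) > 0.9).astype(float)
    assert total_loss(x, y).item() == dice_loss(x, y).item() + bce_loss(x, y).item()
    # half-probability prediction on a half-foreground mask: BCE part is log 2
    y_half = np.zeros((4, 4))
    y_half[:2] = 1.0
    x_half = np.full((4, 4), 0.5)
    expected = dice_loss(x_half, y_half).item() + np.log(2.0)
    assert total_loss(x_half, y_half).item() == pytest.approx(expected, abs=1e-12)


def test_loss_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shape"):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValueError, match="shape"):
        bce_loss(np.zeros((2, 2)), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# confusion + metrics


@pytest.mark.parametrize(
    "pred,truth,expected",
    [
        (np.ones((4, 4)), np.ones((4, 4)), ConfusionCounts(16, 0, 0, 0)),
        (1 - np.eye(3), np.eye(3), ConfusionCounts(0, 6, 3, 0)),
    ],
)
def test_confusion_known_cases(pred, truth, expected):
    assert confusion(pred, truth) == expected


def test_confusion_matches_double_loop_and_sums_to_total():
    p = (RNG.uniform(0, 1, (9, 7)) > 0.5).astype(int)
    t = (RNG.uniform(0, 1, (9, 7)) > 0.5).astype(int)
    c = confusion(p, t)
    tp = fp = fn = tn = 0
    for i in range(9):
        for j in range(7):
            if p[i, j] and t[i, j]:
                tp += 1
            elif p[i, j]:
                fp += 1
            elif t[i, j]:
                fn += 1
            else:
                tn += 1
    assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
    assert c.total == 63


def test_confusion_rejects_nonbinary():
    with pytest.raises(ValueError, match="0/1"):
        confusion(np.array([0.5]), np.array([1.0]))


@pytest.mark.parametrize(
    "counts,expected",
    [
        (ConfusionCounts(50, 10, 10, 0), 100 / 120),
        (ConfusionCounts(7, 0, 0, 9), 1.0),
        (ConfusionCounts(0, 3, 2, 5), 0.0),
        (ConfusionCounts(0, 0, 0, 16), 1.0),  # both-empty convention
    ],
)
def test_dsc_values(counts, expected):
    assert dsc(counts) == pytest.approx(expected)


@pytest.mark.parametrize(
    "counts,expected",
    [
        (ConfusionCounts(8, 0, 2, 0), 0.8),
        (ConfusionCounts(5, 2, 0, 3), 1.0),
        (ConfusionCounts(0, 1, 4, 5), 0.0),
    ],
)
def test_sen_values(counts, expected):
    assert sen(counts) == pytest.approx(expected)


def test_sen_undefined_on_empty_truth():
    with pytest.raises(ValueError, match="empty"):
        sen(ConfusionCounts(0, 3, 0, 13))


def test_dice_loss_complements_dsc_on_binary_masks():
    """1 - dice_loss (eps->0) equals dsc(confusion) on 0/1 masks."""
    for seed in range(5):
        rng = np.random.default_rng(seed)
        p = (rng.uniform(0, 1, (16, 16)) > 0.7).astype(float)
        t = (rng.uniform(0, 1, (16, 16)) > 0.7).astype(float)
        soft = 1.0 - dice_loss(p, t, smooth=0.0).item()
        hard = dsc(confusion(p, t))
        assert abs(soft - hard) < 1e-9


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    pred=hnp.arrays(np.int8, (6, 6), elements=st.integers(0, 1)),
    truth=hnp.arrays(np.int8, (6, 6), elements=st.integers(0, 1)),
)
def test_confusion_partitions_pixels_and_dice_identity(pred, truth):
    """For any binary pair: counts partition the image, and the soft Dice
    loss at eps->0 complements the hard coefficient (away from 0/0)."""
    c = confusion(pred, truth)
    assert c.total == pred.size
    assert min(c.tp, c.fp, c.fn, c.tn) >= 0
    if 2 * c.tp + c.fp + c.fn > 0:
        soft = 1.0 - dice_loss(pred.astype(float), truth.astype(float), smooth=0.0).item()
        assert abs(soft - dsc(c)) < 1e-9


def test_dsc_symmetric_sen_directional():
    rng = np.random.default_rng(11)
    p = (rng.uniform(0, 1, (12, 12)) > 0.6).astype(int)
    t = (rng.uniform(0, 1, (12, 12)) > 0.6).astype(int)
    assert dsc(confusion(p, t)) == pytest.approx(dsc(confusion(t, p)))
    assert sen(confusion(p, t)) != pytest.approx(sen(confusion(t, p)))


# ---------------------------------------------------------------------------
# paired t-test


def test_paired_t_detects_constant_shift():
    rng = np.random.default_rng(3)
    b = 0.85 + 0.001 * rng.standard_normal(5)
    a = b + 0.1 + 0.001 * rng.standard_normal(5)
    t, p = paired_t_test(a, b)
    assert p < 0.05 and t > 0


def test_paired_t_identical_scores_convention():
    a = [0.9, 0.8, 0.7, 0.95]
    assert paired_t_test(a, a) == (0.0, 1.0)


def test_paired_t_matches_textbook_formula():
    rng = np.random.default_rng(8)
    a, b = rng.uniform(0.7, 1.0, 10), rng.uniform(0.7, 1.0, 10)
    t, p = paired_t_test(a, b)
    d = a - b
    t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert t == pytest.approx(t_ref, abs=1e-12)


def test_paired_t_type_one_error_rate():
    """Under the null (same distribution), rejections at 0.05 stay near 5%."""
    rng = np.random.default_rng(123)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        a = rng.normal(0.9, 0.02, 30)
        b = rng.normal(0.9, 0.02, 30)
        _, p = paired_t_test(a, b)
        rejections += p < 0.05
    assert 0.03 <= rejections / n_rep <= 0.08


def test_paired_t_input_validation():
    with pytest.raises(ValueError, match="equal"):
        paired_t_test([1, 2, 3], [1, 2])
    with pytest.raises(ValueError, match="at least 3"):
        paired_t_test([1, 2], [3, 4])


# ---------------------------------------------------------------------------
# report


def test_metrics_report_means_and_csv(tmp_path):
    truth = np.zeros((8, 8), int)
    truth[2:5, 2:5] = 1
    pred_perfect = truth.copy()
    pred_half = truth.copy()
    pred_half[2:5, 2:3] = 0  # drop one column: TP=6, FN=3
    report = MetricsReport.from_masks(
        [("a", pred_perfect, truth), ("b", pred_half, truth)]
    )
    d_b = dsc(confusion(pred_half, truth))
    assert report.mean_dsc == pytest.approx((1.0 + d_b) / 2)
    assert report.mean_sen == pytest.approx((1.0 + 6 / 9) / 2)
    out = tmp_path / "metrics.csv"
    write_metrics_csv(report, out)
    lines = out.read_text().strip().splitlines()
    assert lines[0].startswith("image_id,")
    assert len(lines) == 4  # header + 2 images + mean row
    assert lines[-1].startswith("mean,")


def test_metrics_report_excludes_empty_truth_from_sen():
    empty = np.zeros((4, 4), int)
    ball = np.zeros((4, 4), int)
    ball[1:3, 1:3] = 1
    report = MetricsReport.from_masks([("x", ball, ball), ("y", empty, empty)])
    assert report.n_sen_excluded == 1
    assert report.mean_sen == pytest.approx(1.0)
    assert report.mean_dsc == pytest.approx(1.0)  # empty-vs-empty convention
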