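"""Student/Teacher pair: weight sharing, EMA exactness, training semantics."""

import copy

import numpy as np
import pytest

from radiofusion import nn
from radiofusion.autograd import Tensor
from radiofusion.genes import select_genes
from radiofusion.mean_teacher import (CheckpointError, ClassifierConfig,
                                      SemiTrainConfig, StudentModel,
                                      build_student, consistency_weight,
                                      ema_update, make_pair, predict,
                                      train_semisupervised)
from radiofusion.segnet import SegModel

TINY_CLS = ClassifierConfig(cls_channels=8, gene_hidden=16, gene_embed=8)


def _student(tiny_backbone, seed=0, gene_k=50):
    nn.manual_seed(seed)
    seg = SegModel(tiny_backbone)
    nn.manual_seed(seed + 1)
    return build_student(seg.state_dict(), tiny_backbone, TINY_CLS, gene_k=gene_k), seg


def _screen(cohort, k=50):
    lab = cohort.split["train_labeled"]
    return select_genes(cohort.expression_matrix()[lab],
                        cohort.labels(lab).astype(int), k=k)


def test_student_body_weights_bit_equal_checkpoint(tiny_backbone):
    student, seg = _student(tiny_backbone)
    seg_state = seg.state_dict()
    body_state = student.body.state_dict()
    assert set(seg_state) == set(body_state)
    for k in seg_state:
        np.testing.assert_array_equal(seg_state[k], body_state[k])


def test_incompatible_checkpoint_is_reported(tiny_backbone):
    nn.manual_seed(0)
    seg = SegModel(tiny_backbone)
    state = seg.state_dict()
    state.pop(sorted(state)[0])
    with pytest.raises(CheckpointError, match="incompatible"):
        build_student(state, tiny_backbone, TINY_CLS, gene_k=10)


def test_build_is_deterministic_given_seed(tiny_backbone):
    s1, _ = _student(tiny_backbone, seed=5)
    s2, _ = _student(tiny_backbone, seed=5)
    a, b = s1.state_dict(), s2.state_dict()
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_forward_probability_in_unit_interval(tiny_backbone, small_cohort):
    student, _ = _student(tiny_backbone)
    screen = _screen(small_cohort)
    idx = small_cohort.split["test"][:4]
    p = predict(student, small_cohort.images(idx),
                screen.transform(small_cohort.genes(idx)))
    assert p.shape == (4,)
    assert ((p > 0) & (p < 1)).all()


def test_predict_batch_and_single_sample_agree(tiny_backbone, small_cohort):
    student, _ = _student(tiny_backbone)
    screen = _screen(small_cohort)
    idx = small_cohort.split["test"][:5]
    imgs = small_cohort.images(idx)
    g = screen.transform(small_cohort.genes(idx))
    batch = predict(student, imgs, g)
    singles = np.array([predict(student, imgs[i:i + 1], g[i:i + 1])[0]
                        for i in range(5)])
    np.testing.assert_allclose(batch, singles, atol=1e-6)
    np.testing.assert_array_equal(batch, predict(student, imgs, g))
    with pytest.raises(ValueError, match="does not match"):
        predict(student, imgs, g[:, :10])


@pytest.mark.parametrize("alpha", [0.0, 0.5, 0.9, 1.0])
def test_ema_exactness_on_every_tensor(tiny_backbone, alpha):
    student, _ = _student(tiny_backbone, seed=2, gene_k=10)
    pair = make_pair(student, alpha=alpha)
    rng = np.random.default_rng(0)
    for p in student.parameters():
        p.data = rng.normal(size=p.data.shape).astype(np.float32)
    old_teacher = {k: v.copy() for k, v in pair.teacher.state_dict().items()}
    ema_update(pair)
    new_teacher = pair.teacher.state_dict()
    s_state = student.state_dict()
    for k in s_state:
        expected = alpha * old_teacher[k] + (1 - alpha) * s_state[k]
        np.testing.assert_allclose(new_teacher[k], expected, atol=1e-6)
    if alpha == 1.0:
        for k in s_state:
            np.testing.assert_array_equal(new_teacher[k], old_teacher[k])
    if alpha == 0.0:
        for k in s_state:
            np.testing.assert_allclose(new_teacher[k], s_state[k], atol=0)


def test_ema_scalar_arithmetic_example():
    """w_t=1.0, w_s=2.0, alpha=0.9 -> 1.1"""
    assert 0.9 * 1.0 + (1 - 0.9) * 2.0 == pytest.approx(1.1)


def test_consistency_ramp_endpoints():
    cfg = SemiTrainConfig(consistency_weight_max=2.5, rampup_epochs=4, epochs=8)
    assert consistency_weight(0, cfg) == pytest.approx(2.5 * np.exp(-5.0))
    assert consistency_weight(4, cfg) == pytest.approx(2.5)   # exp(0) = 1
    assert consistency_weight(7, cfg) == pytest.approx(2.5)
    assert consistency_weight(3, SemiTrainConfig(consistency_weight_max=0.0)) == 0.0


def test_teacher_accumulates_no_gradients(tiny_backbone, small_cohort):
    student, _ = _student(tiny_backbone)
    pair = make_pair(student)
    screen = _screen(small_cohort)
    cfg = SemiTrainConfig(epochs=1, batch_size=16, rampup_epochs=0,
                          consistency_weight_max=1.0, seed=0)
    train_semisupervised(pair, small_cohort, screen, cfg)
    for p in pair.teacher.parameters():
        assert p.grad is None
        assert not p.requires_grad


def test_zero_consistency_matches_supervised_trajectory(tiny_backbone, small_cohort):
    screen = _screen(small_cohort)
    results = []
    for _ in range(2):
        student, _ = _student(tiny_backbone, seed=3)
        pair = make_pair(student)
        cfg = SemiTrainConfig(epochs=2, batch_size=16, consistency_weight_max=0.0,
                              rampup_epochs=0, seed=4)
        trained, hist = train_semisupervised(pair, small_cohort, screen, cfg)
        results.append((trained.state_dict(), hist))
    for k in results[0][0]:
        np.testing.assert_array_equal(results[0][0][k], results[1][0][k])
    assert results[0][1]["sup_loss"] == results[1][1]["sup_loss"]
    assert all(w == 0.0 for w in results[0][1]["weight"])


def test_teacher_student_gap_shrinks_during_training(tiny_backbone, small_cohort):
    student, _ = _student(tiny_backbone, seed=6)
    pair = make_pair(student, alpha=0.9)
    screen = _screen(small_cohort)
    probe = small_cohort.split["test"][:8]
    imgs = small_cohort.images(probe)
    g = screen.transform(small_cohort.genes(probe))

    def gap():
        ps = predict(pair.student, imgs, g)
        pt = predict(pair.teacher, imgs, g)
        return np.abs(ps - pt).mean()

    cfg = SemiTrainConfig(epochs=1, batch_size=16, consistency_weight_max=1.0,
                          rampup_epochs=0, seed=6)
    train_semisupervised(pair, small_cohort, screen, cfg)
    g1 = gap()
    for _ in range(3):
        train_semisupervised(pair, small_cohort, screen, cfg)
    assert gap() <= g1 + 0.02


def test_no_unlabeled_data_degrades_to_supervised(tiny_backbone, small_cohort):
    student, _ = _student(tiny_backbone)
    pair = make_pair(student)
    screen = _screen(small_cohort)
    cohort = copy.deepcopy(small_cohort)
    cohort.split["train_unlabeled"] = np.array([], dtype=int)
    with pytest.warns(UserWarning, match="no unlabeled"):
        _, hist = train_semisupervised(pair, cohort, screen,
                                       SemiTrainConfig(epochs=1, rampup_epochs=0, seed=0))
    assert hist["cons_loss"][0] == 0.0


def test_freeze_shared_keeps_body_weights_fixed(tiny_backbone, small_cohort):
    student, seg = _student(tiny_backbone, seed=8)
    before = {k: v.copy() for k, v in student.body.state_dict().items()}
    pair = make_pair(student)
    screen = _screen(small_cohort)
    cfg = SemiTrainConfig(epochs=1, batch_size=16, freeze_shared=True,
                          consistency_weight_max=0.0, rampup_epochs=0, seed=8)
    train_semisupervised(pair, small_cohort, screen, cfg)
    after = student.body.state_dict()
    for k in before:
        if "running" in k:   # BN statistics still update in train mode
            continue
        np.testing.assert_array_equal(before[k], after[k])
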