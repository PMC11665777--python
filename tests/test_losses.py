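"""Closed-form loss cases, metric arithmetic and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plutonet as p
from plutonet.losses import MetricReport


# -- dice-form losses --------------------------------------------------------

def test_dice_loss_closed_forms():
    ones4 = np.ones((1, 4), np.float32)
    zeros4 = np.zeros((1, 4), np.float32)
    assert p.dice_loss(ones4, ones4).item() == pytest.approx(0.0, abs=1e-6)
    assert p.dice_loss(zeros4, ones4).item() == pytest.approx(1.0, abs=1e-6)
    pred = np.array([[1, 1, 0, 0]], np.float32)
    truth = np.array([[0, 1, 1, 0]], np.float32)
    assert p.dice_loss(pred, truth).item() == pytest.approx(0.5, abs=1e-6)


def test_consistency_loss_agreement_and_uniform_maps():
    pm = np.full((1, 10, 10, 1), 0.5, np.float32)
    assert p.consistency_loss(pm, pm).item() == pytest.approx(0.0, abs=1e-4)
    q = np.random.default_rng(0).random((1, 8, 8, 1)).astype(np.float32)
    assert p.consistency_loss(q, q).item() == pytest.approx(0.0, abs=1e-4)


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_consistency_loss_symmetric_and_bounded(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((1, 6, 6, 1)).astype(np.float32)
    b = rng.random((1, 6, 6, 1)).astype(np.float32)
    lab = p.consistency_loss(a, b).item()
    lba = p.consistency_loss(b, a).item()
    assert lab == pytest.approx(lba, abs=1e-6)
    assert 0.0 <= lab <= 1.0


def test_total_loss_arithmetic():
    assert p.total_loss(0.3, 0.1, 1.0) == pytest.approx(0.4)
    assert p.total_loss(0.7, 0.9, 0.0) == pytest.approx(0.7)   # ablation arm
    assert p.total_loss(0.0, 0.0, 1.0) == 0.0


def test_losses_reject_bad_arguments():
    a = np.ones((1, 4), np.float32)
    with pytest.raises(ValueError):
        p.dice_loss(a, np.ones((1, 5), np.float32))
    with pytest.raises(ValueError):
        p.dice_loss(a, a, epsilon=0.0)
    with pytest.raises(ValueError):
        p.total_loss(0.1, 0.1, alpha=-1.0)


# -- evaluation metrics ------------------------------------------------------

def test_perfect_prediction_metrics():
    t = (np.random.default_rng(1).random((16, 16)) > 0.5).astype(np.float64)
    rep = p.evaluate(t, t)
    assert (rep.dice, rep.iou, rep.precision, rep.recall) == (1, 1, 1, 1)


def test_confusion_arithmetic_on_two_by_two_case():
    rep = p.evaluate(np.array([1, 1, 0, 0.0]), np.array([0, 1, 1, 0.0]))
    assert rep.dice == pytest.approx(0.5)
    assert rep.iou == pytest.approx(1 / 3)
    assert rep.precision == pytest.approx(0.5)
    assert rep.recall == pytest.approx(0.5)


def test_auc_of_perfectly_ranked_scores():
    rep = p.evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0.0]))
    assert rep.auc == pytest.approx(1.0)


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_dice_iou_functional_relation(seed):
    rng = np.random.default_rng(seed)
    pred = rng.random((12, 12))
    truth = (rng.random((12, 12)) > 0.4).astype(np.float64)
    rep = p.evaluate(pred, truth)
    if 0 < rep.iou < 1:
        assert rep.dice == pytest.approx(2 * rep.iou / (1 + rep.iou), abs=1e-9)
    assert rep.iou <= rep.dice + 1e-12


def test_degenerate_cells_follow_documented_convention():
    empty = np.zeros((4, 4))
    rep = p.evaluate(empty, empty)
    assert rep.precision == 1.0 and rep.recall == 1.0 and rep.dice == 1.0
    rep2 = p.evaluate(empty, np.ones((4, 4)))
    assert rep2.precision == 0.0 and rep2.recall == 0.0
    with pytest.raises(ValueError):
        p.evaluate(np.zeros((0,)), np.zeros((0,)))


def test_gradient_step_decreases_loss_on_fixed_batch(tiny_model):
    from plutonet.nn import Adam
    rng = np.random.default_rng(5)
    size = tiny_model.encoder_config.input_size
    x = rng.random((1, size, size, 3)).astype(np.float32)
    t = (rng.random((1, size, size, 1)) > 0.8).astype(np.float32)
    params = tiny_model.trainable_parameters(True)
    state = [q.data.copy() for q in params]
    opt = Adam(params, lr=1e-4)
    try:
        pm, pa = tiny_model.forward(x, training=True)
        l0 = p.total_loss(p.dice_loss(pm, t), p.consistency_loss(pm, pa), 1.0)
        opt.zero_grad()
        l0.backward()
        opt.step()
        pm, pa = tiny_model.forward(x, training=True)
        l1 = p.total_loss(p.dice_loss(pm, t), p.consistency_loss(pm, pa), 1.0)
        assert l1.item() < l0.item()
    finally:
        for q, s in zip(params, state):
            q.data = s
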