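"""Triple-task network: losses vs brute-force oracles, gradients, training."""

import math

import numpy as np
import pytest

from cusdvt import net, nn, synth
from cusdvt.net import LossWeights

TINY_ARCH = {"levels": 1, "base_width": 2, "resolution": 8}
SMALL_ARCH = {"levels": 2, "base_width": 4, "resolution": 24}


# ---------------------------------------------------------------------------
# Losses against hand-rolled oracles
# ---------------------------------------------------------------------------

def _bce_loop(p, y):
    """Scalar-by-scalar clipped binary cross-entropy, the slow way."""
    total = 0.0
    for pi, yi in zip(np.ravel(p), np.ravel(y)):
        pc = min(max(pi, 1e-7), 1 - 1e-7)
        total += -(yi * math.log(pc) + (1 - yi) * math.log(1 - pc))
    return total


def test_seg_loss_perfect_and_single_pixel():
    target = np.zeros((2, 2, 3))
    target[..., 0] = 1
    assert net.seg_loss(target, target) <= 1e-6
    assert net.seg_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(
        0.6931, abs=1e-4)


def test_seg_loss_matches_pixel_loop(rng):
    for _ in range(5):
        p = rng.random((4, 4, 3))
        y = (rng.random((4, 4, 3)) > 0.5).astype(float)
        assert net.seg_loss(p, y) == pytest.approx(_bce_loop(p, y) / p.size,
                                                   abs=1e-6)


def test_seg_loss_shape_mismatch():
    with pytest.raises(ValueError):
        net.seg_loss(np.zeros((2, 2, 3)), np.zeros((2, 3, 3)))


def test_landmark_loss_closed_forms(rng):
    one_hot = np.array([1.0, 0, 0, 0])
    sharp = np.array([1 - 1e-9, 1e-9, 1e-9, 1e-9])
    assert net.landmark_loss(sharp, one_hot) <= 1e-6
    uniform = np.full(4, 0.25)
    expected = -math.log(0.25) - 3 * math.log(0.75)
    assert net.landmark_loss(uniform, one_hot) == pytest.approx(expected, abs=1e-4)
    assert expected == pytest.approx(2.2493, abs=1e-4)
    for _ in range(5):
        p = rng.dirichlet(np.ones(6))
        y = np.zeros(6)
        y[rng.integers(6)] = 1
        assert net.landmark_loss(p, y) == pytest.approx(_bce_loop(p, y), abs=1e-6)
    with pytest.raises(ValueError):
        net.landmark_loss(np.ones(3) / 3, np.array([1.0, 0.0]))


@pytest.mark.parametrize("p,y,expected", [
    (0.5, 1, 0.6931), (1.0 - 1e-9, 1, 0.0), (0.9, 0, 2.3026),
])
def test_compression_loss_values(p, y, expected):
    assert net.compression_loss(p, y) == pytest.approx(expected, abs=1e-4)


def test_compression_loss_validation():
    with pytest.raises(ValueError):
        net.compression_loss(0.5, 2)
    with pytest.raises(ValueError):
        net.compression_loss(1.5, 1)


def test_total_loss_weighted_sum():
    assert net.total_loss(0.01, 0.2, 0.3) == pytest.approx(1.5)
    assert net.total_loss(0, 0, 0) == 0.0
    assert net.total_loss(0.4, 0.5, 0.7, LossWeights(0, 0, 1)) == 0.7
    # decomposition identity at the published defaults
    ls, ll, lo = 0.013, 0.8, 0.25
    assert net.total_loss(ls, ll, lo) == 100 * ls + ll + lo


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def test_sliding_window_stream():
    frames = np.arange(20, dtype=float)[:, None, None] * np.ones((1, 4, 4))
    windows = list(net.sliding_windows(frames))
    assert len(windows) == 20
    assert windows[0].frames[0, 0, 0] == 0 and windows[0].index_of_last == 0
    # first 8 windows replicate the first frame on the left
    assert np.all(windows[3].frames[:5, 0, 0] == 0)
    # window 9 holds frames 1..9 in order (0-based 0..8)
    assert list(windows[8].frames[:, 0, 0]) == list(range(9))
    # consecutive windows share 8 frames
    assert np.array_equal(windows[10].frames[1:], windows[11].frames[:-1])


def test_sliding_window_single_frame_and_empty():
    one = np.ones((1, 4, 4))
    w = list(net.sliding_windows(one))
    assert len(w) == 1 and np.all(w[0].frames == 1)
    with pytest.raises(ValueError):
        list(net.sliding_windows(np.ones((0, 4, 4))))


# ---------------------------------------------------------------------------
# Model contract
# ---------------------------------------------------------------------------

def test_build_model_output_contract(rng):
    for region, n_classes in (("groin_thigh", 7), ("knee", 4)):
        m = net.build_model(region, SMALL_ARCH, seed=1)
        assert m.n_parameters() > 0
        x = rng.random((2, 9, 24, 24)).astype(np.float32)
        seg, lm, oc = m.forward(x)
        assert seg.data.shape == (2, 3, 24, 24)
        assert np.allclose(seg.data.sum(axis=1), 1.0, atol=1e-5)
        assert lm.data.shape == (2, n_classes)
        assert np.allclose(lm.data.sum(axis=1), 1.0, atol=1e-5)
        assert np.all((oc.data >= 0) & (oc.data <= 1))
    with pytest.raises(ValueError, match="unknown region"):
        net.build_model("ankle")


def test_predict_is_deterministic_and_normalised(healthy_knee_sequence):
    m = net.build_model("knee", SMALL_ARCH, seed=0)
    window = next(net.sliding_windows(healthy_knee_sequence))
    seg1, lm1, oc1 = net.predict(m, window)
    seg2, lm2, oc2 = net.predict(m, window)
    assert np.array_equal(seg1, seg2) and np.array_equal(lm1, lm2) and oc1 == oc2
    assert seg1.shape == (150, 150, 3)
    assert np.allclose(seg1.sum(axis=-1), 1.0, atol=1e-5)
    assert lm1.shape == (4,)


def test_checkpoint_round_trip(tmp_path, healthy_knee_sequence):
    m = net.build_model("knee", SMALL_ARCH, seed=5)
    path = str(tmp_path / "ckpt")
    m.save(path, extra={"epochs": 0})
    again = net.TriptychModel.load(path)
    w = next(net.sliding_windows(healthy_knee_sequence))
    a = net.predict(m, w)
    b = net.predict(again, w)
    assert np.array_equal(a[0], b[0]) and a[2] == b[2]


# ---------------------------------------------------------------------------
# Gradient sanity
# ---------------------------------------------------------------------------

def test_total_loss_gradients_match_finite_differences(rng):
    """Central finite differences vs backpropagation on a toy model."""
    m = net.build_model("knee", TINY_ARCH, seed=0)
    for p in m.parameters():
        p.data = p.data.astype(np.float64)
    x = rng.random((2, 9, 8, 8))
    ymask = np.zeros((2, 3, 8, 8))
    ymask[:, 0] = 1
    ymask[0, 0, 2:5, 2:5] = 0
    ymask[0, 2, 2:5, 2:5] = 1
    ylm = np.zeros((2, 4))
    ylm[:, 1] = 1
    yoc = np.array([[0.0], [1.0]])

    def loss():
        seg, lm, oc = m.forward(x)
        return nn.weighted_sum([
            (100.0, nn.bce(seg, ymask, 1.0 / seg.data.size)),
            (1.0, nn.bce(lm, ylm, 0.5)),
            (1.0, nn.bce(oc, yoc, 0.5)),
        ])

    total = loss()
    for p in m.parameters():
        p.zero_grad()
    total.backward()
    eps = 1e-6
    for name in ("stem.w", "down0.w", "lm.w", "seg.w", "oc_d1.w", "oc_d2.b"):
        p = m.params[name]
        idx = tuple(rng.integers(0, s) for s in p.data.shape)
        old = p.data[idx]
        p.data[idx] = old + eps
        up = float(loss().data)
        p.data[idx] = old - eps
        down = float(loss().data)
        p.data[idx] = old
        fd = (up - down) / (2 * eps)
        grad = p.grad[idx]
        denom = max(abs(fd), abs(grad), 1e-8)
        assert abs(fd - grad) / denom < 1e-3, name


# ---------------------------------------------------------------------------
# Training behaviour
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_training(tiny_manifest):
    seqs = [synth.realize(r) for r in tiny_manifest.records]
    return tiny_manifest, seqs


def _small_optim(**overrides):
    cfg = {"epochs": 3, "lr": 2e-3, "batch_size": 8, "seed": 5,
           "windows_per_sequence": 4, "augment": False}
    cfg.update(overrides)
    return cfg


def test_training_reduces_total_loss(tiny_training):
    manifest, seqs = tiny_training
    m = net.build_model("knee", SMALL_ARCH, seed=5)
    history = net.train(m, manifest, _small_optim(), sequences=seqs)
    assert len(history) == 3
    assert history[-1]["total"] < history[0]["total"]


def test_training_is_seed_deterministic(tiny_training):
    manifest, seqs = tiny_training
    h1 = net.train(net.build_model("knee", SMALL_ARCH, seed=5), manifest,
                   _small_optim(epochs=1), sequences=seqs)
    h2 = net.train(net.build_model("knee", SMALL_ARCH, seed=5), manifest,
                   _small_optim(epochs=1), sequences=seqs)
    assert h1[0]["total"] == h2[0]["total"]


def test_zero_seg_weight_leaves_segmentation_untrained(tiny_training):
    """With only the landmark loss active the segmentation head cannot move,
    while the landmark branch still learns."""
    manifest, seqs = tiny_training
    m = net.build_model("knee", SMALL_ARCH, seed=5)
    seg_before = {k: p.data.copy() for k, p in m.params.items()
                  if k.startswith(("seg", "dec"))}
    history = net.train(m, manifest,
                        _small_optim(loss_weights=LossWeights(0.0, 1.0, 0.0)),
                        sequences=seqs)
    assert history[-1]["landmark"] < history[0]["landmark"]
    for k, before in seg_before.items():
        assert np.array_equal(m.params[k].data, before), k


def test_train_rejects_empty_region(tiny_manifest):
    m = net.build_model("groin_thigh", SMALL_ARCH, seed=0)
    with pytest.raises(ValueError, match="no training sequences"):
        net.train(m, tiny_manifest, _small_optim())


# ---------------------------------------------------------------------------
# Naive black-box baseline
# ---------------------------------------------------------------------------

def test_baseline_blackbox_learns_separable_set():
    from cusdvt.metrics import roc_auc
    rng = np.random.default_rng(17)
    seqs, labels = [], []
    for i in range(16):
        pathology = i % 2 == 1
        scene = synth.make_scene("LM8", pathology, seed=100 + i)
        n = 12 if i % 3 else 15       # deliberately unequal lengths
        prof = synth.ramp_profile(2, 4, 3, n - 9)
        seqs.append(synth.render_sequence(scene, prof, seed=i, speckle=False))
        labels.append(int(pathology))
    scores = net.baseline_blackbox(seqs[:12], labels[:12], seqs[12:],
                                   seed=3, res=32, time_len=16,
                                   encoder_epochs=2, classifier_epochs=20)
    assert scores.shape == (4,)
    assert np.all((scores >= 0) & (scores <= 1))
    auc = roc_auc(scores, np.array(labels[12:])).auc
    assert auc > 0.5


def test_baseline_requires_both_classes(healthy_knee_sequence):
    with pytest.raises(ValueError, match="both healthy and pathological"):
        net.baseline_blackbox([healthy_knee_sequence] * 4, [0, 0, 0, 0],
                              [healthy_knee_sequence])
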