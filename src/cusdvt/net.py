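"""Triple-task network for compression-ultrasound interpretation.

A U-Net-style encoder/decoder segments artery and vein in the last frame of
a 9-frame sliding window; a landmark-classification branch reads the
bottleneck representation; a vein open/closed branch reads the output
segmentation probability map (keeping the whole graph differentiable end
to end).
Two region models with identical architecture are trained, one for the
groin/thigh landmarks and one for the knee landmarks.

Losses follow the published composite: per-pixel binary cross-entropy over
the one-hot segmentation (mean over pixels and classes), a BCE-over-classes
landmark term (summed over classes, averaged per sample), a scalar BCE for
the open/closed head, combined as ``α·L_seg + β·L_lm + γ·L_oc`` with
defaults α=100, β=γ=1.  Probabilities are clipped at 1e-7 before logs.

The network runs at a configurable internal resolution (inputs are resized
bilinearly on the way in, segmentation probabilities resized back out), so
desk-scale models can train quickly on CPU while the window contract stays
150×150.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .synth import (FRAME_SIZE, DatasetManifest, RenderedSequence,
                    augment, realize)

__all__ = [
    "FrameWindow",
    "LossWeights",
    "ModelRegion",
    "GROIN_THIGH",
    "KNEE",
    "TriptychModel",
    "build_model",
    "seg_loss",
    "landmark_loss",
    "compression_loss",
    "total_loss",
    "sliding_windows",
    "train",
    "predict",
    "predict_sequence",
    "baseline_blackbox",
]

WINDOW_LEN = 9
N_SEG_CLASSES = 3          # background, artery, vein
VEIN_CHANNEL = 2


@dataclass(frozen=True)
class FrameWindow:
    """Nine consecutive grayscale frames; the unit of network input."""

    frames: np.ndarray          # (9, H, W) in [0, 1]
    index_of_last: int

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] != WINDOW_LEN:
            raise ValueError(f"a window holds exactly {WINDOW_LEN} frames")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite loss: α (segmentation), β (landmark), γ (open/closed)."""

    alpha: float = 100.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class ModelRegion:
    """A regional model's landmark class set (plus background)."""

    region: str
    landmarks: tuple[str, ...]

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.landmarks + ("background",)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


GROIN_THIGH = ModelRegion("groin_thigh", tuple(f"LM{i}" for i in range(6)))
KNEE = ModelRegion("knee", ("LM8", "LM9", "LM10"))
_REGIONS = {r.region: r for r in (GROIN_THIGH, KNEE)}


# ---------------------------------------------------------------------------
# Loss functions (array API, shared with the training graph)
# ---------------------------------------------------------------------------

def seg_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean clipped BCE over pixels and classes of a one-hot segmentation."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, target {target.shape}")
    return float(nn.bce_elements(pred, target).mean())


def landmark_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """BCE summed over landmark classes for a one-hot target."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape or pred.ndim != 1:
        raise ValueError(f"posterior/target length mismatch: {pred.shape} vs {target.shape}")
    return float(nn.bce_elements(pred, target).sum())


def compression_loss(pred: float, target: int) -> float:
    """Scalar clipped BCE for the vein open(0)/closed(1) head."""
    if target not in (0, 1):
        raise ValueError(f"target must be 0 or 1, got {target!r}")
    if not 0.0 <= pred <= 1.0:
        raise ValueError(f"predicted probability must be in [0, 1], got {pred}")
    return float(nn.bce_elements(np.asarray(pred, dtype=float),
                                 np.asarray(target, dtype=float)))


def total_loss(l_seg: float, l_lm: float, l_oc: float,
               weights: LossWeights = LossWeights()) -> float:
    """α·L_seg + β·L_lm + γ·L_oc."""
    if min(l_seg, l_lm, l_oc) < 0:
        raise ValueError("component losses must be non-negative")
    return weights.alpha * l_seg + weights.beta * l_lm + weights.gamma * l_oc


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def sliding_windows(sequence: "RenderedSequence | np.ndarray") -> Iterator[FrameWindow]:
    """One 9-frame window per frame, advancing by one frame.

    The first eight windows are left-padded by replicating the first frame,
    so every frame of the sequence is the last-most frame of exactly one
    window.
    """
    frames = sequence.frames if isinstance(sequence, RenderedSequence) else np.asarray(sequence)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("sequence must be a non-empty (n, H, W) stack")
    n = frames.shape[0]
    pad = np.repeat(frames[:1], WINDOW_LEN - 1, axis=0)
    padded = np.concatenate([pad, frames], axis=0)
    for t in range(n):
        yield FrameWindow(frames=padded[t:t + WINDOW_LEN], index_of_last=t)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _resize_stack(frames: np.ndarray, size: int) -> np.ndarray:
    if frames.shape[-1] == size and frames.shape[-2] == size:
        return np.asarray(frames, dtype=np.float32)
    # anti-alias when downsizing so few-pixel vessels survive the resample
    aa = size < frames.shape[-1]
    out = np.empty(frames.shape[:-2] + (size, size), dtype=np.float32)
    flat = frames.reshape(-1, frames.shape[-2], frames.shape[-1])
    for i, f in enumerate(flat):
        out.reshape(-1, size, size)[i] = _sk_resize(
            f, (size, size), order=1, preserve_range=True, anti_aliasing=aa)
    return out


def default_arch_config() -> dict[str, int]:
    return {"levels": 4, "base_width": 32, "resolution": 144}


class TriptychModel:
    """The triple-task model handle: parameters, forward pass, checkpoints."""

    LM_GRID = 2       # landmark head reads a coarse spatial grid of the bottleneck
    OC_GRID = 4       # open/closed head reads block-wise vein-area fractions
    OC_AREA_SCALE = 20.0

    def __init__(self, region: ModelRegion, arch_config: Mapping[str, int] | None = None,
                 seed: int = 0):
        cfg = default_arch_config()
        if arch_config:
            cfg.update(arch_config)
        self.region = region
        self.config = cfg
        self.seed = seed
        levels, base, res = cfg["levels"], cfg["base_width"], cfg["resolution"]
        if res % (2 ** levels) != 0:
            raise ValueError(
                f"resolution {res} must be divisible by 2^levels = {2 ** levels}")
        rng = np.random.default_rng(seed)
        P: dict[str, nn.Tensor] = {}

        def conv_p(name: str, o: int, c: int, k: int = 3) -> None:
            P[f"{name}.w"] = nn.parameter(nn.he_conv(rng, o, c, k))
            P[f"{name}.b"] = nn.parameter(np.zeros(o))

        def dense_p(name: str, d: int, m: int) -> None:
            P[f"{name}.w"] = nn.parameter(nn.he_dense(rng, d, m))
            P[f"{name}.b"] = nn.parameter(np.zeros(m))

        conv_p("stem", base, WINDOW_LEN)
        width = base
        for lvl in range(levels):
            conv_p(f"down{lvl}", width * 2, width)
            conv_p(f"enc{lvl}", width * 2, width * 2)
            width *= 2
        self._bottleneck_width = width
        dense_p("lm", width * self.LM_GRID ** 2, region.n_classes)
        for lvl in reversed(range(levels)):
            skip = width // 2
            conv_p(f"dec{lvl}", skip, width + skip)
            width = skip
        conv_p("seg", N_SEG_CLASSES, width, k=1)
        dense_p("oc_d1", 2 * N_SEG_CLASSES * self.OC_GRID ** 2, 16)
        dense_p("oc_d2", 16, 1)
        self.params = P

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
        """Batched forward pass: x (N, 9, R, R) -> (seg probs, landmark, oc).

        Returns graph nodes so training can backpropagate; ``predict`` wraps
        this for plain-array inference.
        """
        P = self.params
        levels = self.config["levels"]
        t = nn.Tensor(x)
        h = nn.relu(nn.conv2d(t, P["stem.w"], P["stem.b"]))
        skips = []
        for lvl in range(levels):
            skips.append(h)
            h = nn.relu(nn.conv2d(h, P[f"down{lvl}.w"], P[f"down{lvl}.b"], stride=2))
            h = nn.relu(nn.conv2d(h, P[f"enc{lvl}.w"], P[f"enc{lvl}.b"]))
        lm = nn.softmax(nn.dense(nn.grid_pool(h, self.LM_GRID), P["lm.w"], P["lm.b"]),
                        axis=1)
        for lvl in reversed(range(levels)):
            h = nn.upsample2(h)
            h = nn.concat_channels(h, skips[lvl])
            h = nn.relu(nn.conv2d(h, P[f"dec{lvl}.w"], P[f"dec{lvl}.b"]))
        seg = nn.softmax(nn.conv2d(h, P["seg.w"], P["seg.b"], pad=0), axis=1)
        # open/closed head reads the full output segmentation mask as
        # block-wise class-area fractions (rescaled to O(1)) plus block-wise
        # peak class probabilities: the peaks keep a faint residual lumen
        # below the 0.5 level distinguishable from a fully closed vein, and
        # the artery/background channels keep a closed-vein mask (empty vein
        # channel) distinguishable from a vessel-free background scene
        area = nn.weighted_sum([(self.OC_AREA_SCALE, nn.grid_pool(seg, self.OC_GRID))])
        peak = nn.grid_max_pool(seg, self.OC_GRID)
        oc = nn.relu(nn.dense(nn.concat_features(area, peak),
                              P["oc_d1.w"], P["oc_d1.b"]))
        oc = nn.sigmoid(nn.dense(oc, P["oc_d2.w"], P["oc_d2.b"]))
        return seg, lm, oc

    # -- bookkeeping -------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def parameters(self) -> list[nn.Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def save(self, path: str, extra: Mapping[str, object] | None = None) -> None:
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 **{k: p.data for k, p in self.params.items()})
        sidecar = {"region": self.region.region, "arch_config": self.config,
                   "seed": self.seed, **(dict(extra) if extra else {})}
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "TriptychModel":
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json") as fh:
            sidecar = json.load(fh)
        model = cls(_REGIONS[sidecar["region"]], sidecar["arch_config"],
                    seed=sidecar.get("seed", 0))
        weights = np.load(base + ".npz")
        for k in model.params:
            model.params[k].data = weights[k]      # dtype preserved as saved
        return model


def build_model(region: "ModelRegion | str",
                arch_config: Mapping[str, int] | None = None,
                seed: int = 0) -> TriptychModel:
    """Instantiate a regional triple-task model.

    ``region`` is a :class:`ModelRegion` or one of ``"groin_thigh"`` /
    ``"knee"``.  ``arch_config`` keys: ``levels`` (encoder depth),
    ``base_width`` (channels at full resolution, doubling per level) and
    ``resolution`` (internal square input size, divisible by 2^levels).
    """
    if isinstance(region, str):
        if region not in _REGIONS:
            raise ValueError(f"unknown region {region!r}; expected one of {sorted(_REGIONS)}")
        region = _REGIONS[region]
    return TriptychModel(region, arch_config, seed=seed)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict(model: TriptychModel, window: FrameWindow
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Single-window inference at native 150x150 output resolution.

    Returns (seg probability map (H, W, 3) for the last-most frame,
    landmark posterior aligned with ``model.region.class_names``, closed
    probability).
    """
    seg, lm, oc = _predict_batch(model, window.frames[None])
    return seg[0], lm[0], float(oc[0])


def _predict_batch(model: TriptychModel, windows: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    res = model.config["resolution"]
    h_out = windows.shape[-2]
    x = _resize_stack(windows, res)
    seg_t, lm_t, oc_t = model.forward(x)
    seg = seg_t.data.transpose(0, 2, 3, 1)          # N, R, R, 3
    if h_out != res:
        up = np.stack([
            np.stack([_sk_resize(seg[i, :, :, c], (h_out, h_out), order=1,
                                 preserve_range=True, anti_aliasing=False)
                      for c in range(N_SEG_CLASSES)], axis=-1)
            for i in range(seg.shape[0])])
        up /= np.clip(up.sum(axis=-1, keepdims=True), 1e-12, None)
        seg = up
    return seg, lm_t.data, oc_t.data[:, 0]


def predict_sequence(model: TriptychModel, sequence: "RenderedSequence | np.ndarray",
                     batch_size: int = 16
                     ) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Run the sliding window over a whole sequence (one output per frame)."""
    windows = np.stack([w.frames for w in sliding_windows(sequence)])
    outputs: list[tuple[np.ndarray, np.ndarray, float]] = []
    for start in range(0, windows.shape[0], batch_size):
        seg, lm, oc = _predict_batch(model, windows[start:start + batch_size])
        outputs.extend((seg[i], lm[i], float(oc[i])) for i in range(seg.shape[0]))
    return outputs


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def default_optim_config() -> dict[str, object]:
    return {
        "epochs": 50, "lr": 1e-3, "batch_size": 8, "seed": 0,
        "windows_per_sequence": 6, "augment": True,
        "augment_config": None,            # None -> standard envelope
        "loss_weights": LossWeights(),
    }


def _one_hot(index: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[index] = 1.0
    return v


def _sequence_training_samples(seq: RenderedSequence, region: ModelRegion,
                               res: int, k_windows: int,
                               rng: np.random.Generator):
    """Sample windows from one sequence: (window, one-hot mask, lm, oc)."""
    n = seq.n_frames
    idx = np.unique(np.linspace(0, n - 1, k_windows).astype(int)) if k_windows < n \
        else np.arange(n)
    windows = np.stack([w.frames for w in sliding_windows(seq)])
    frames = _resize_stack(windows[idx], res)
    names = region.class_names
    lm_idx = names.index(seq.landmark_label) if seq.landmark_label in names \
        else names.index("background")
    samples = []
    for j, t in enumerate(idx):
        mask_small = _sk_resize(seq.masks[t].astype(float), (res, res), order=0,
                                preserve_range=True, anti_aliasing=False).astype(int)
        onehot = np.stack([(mask_small == c).astype(float)
                           for c in range(N_SEG_CLASSES)])
        oc = 1.0 if seq.open_closed[t] == "closed" else 0.0
        # the open/closed label is undefined for scenes without a vein;
        # such windows get zero weight in the compression loss
        oc_w = 1.0 if seq.rest_vein_area > 0 else 0.0
        samples.append((frames[j], onehot, _one_hot(lm_idx, region.n_classes),
                        oc, oc_w))
    return samples


def train(model: TriptychModel, manifest: DatasetManifest,
          optim_config: Mapping[str, object] | None = None,
          sequences: "Sequence[RenderedSequence] | None" = None,
          ) -> list[dict[str, float]]:
    """Train a regional model on a synthetic dataset manifest.

    Training windows are drawn from every training-split sequence whose
    landmark belongs to the model's region (plus background sequences);
    targets are the last-most frame's mask, landmark and open/closed
    labels.  Adam (momentum 0.9) optimises the composite loss; the
    augmentation envelope is applied per window per epoch, with the
    translation range scaled to the internal resolution.  Returns the
    per-epoch history of the three loss components and the total.

    ``sequences`` short-circuits manifest realization when the rendered
    sequences are already in memory (index-aligned with
    ``manifest.records``).
    """
    cfg = default_optim_config()
    if optim_config:
        cfg.update(optim_config)
    weights: LossWeights = cfg["loss_weights"]          # type: ignore[assignment]
    res = model.config["resolution"]
    rng = np.random.default_rng(int(cfg["seed"]))

    records = list(manifest.records)
    usable = [i for i, r in enumerate(records)
              if r.split == "train"
              and (r.landmark in model.region.landmarks or r.landmark == "background")]
    if not usable:
        raise ValueError("no training sequences for this model's region")

    samples = []
    for i in usable:
        seq = sequences[i] if sequences is not None else realize(records[i])
        samples.extend(_sequence_training_samples(
            seq, model.region, res, int(cfg["windows_per_sequence"]), rng))
    X = np.stack([s[0] for s in samples])
    Ymask = np.stack([s[1] for s in samples])
    Ylm = np.stack([s[2] for s in samples])
    Yoc = np.array([s[3] for s in samples])
    Woc = np.array([s[4] for s in samples])

    do_aug = bool(cfg["augment"])
    aug_cfg = cfg["augment_config"] or {
        "flip": True, "translate_px": 15.0 * res / FRAME_SIZE,
        "rotate_deg": 15.0, "zoom": 0.05, "intensity": 0.3,
    }
    optim = nn.Adam(model.parameters(), lr=float(cfg["lr"]))
    batch = int(cfg["batch_size"])
    history: list[dict[str, float]] = []
    m = X.shape[0]
    for epoch in range(int(cfg["epochs"])):
        order = rng.permutation(m)
        tot = {"seg": 0.0, "landmark": 0.0, "open_closed": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, m, batch):
            sel = order[start:start + batch]
            xb = X[sel].copy()
            mb = Ymask[sel].copy()
            if do_aug:
                for j, i_s in enumerate(sel):
                    lab = np.argmax(mb[j], axis=0)
                    fa, la = augment(xb[j], lab, seed=int(rng.integers(2**31)),
                                     config=aug_cfg)
                    xb[j] = fa
                    mb[j] = np.stack([(la == c).astype(float)
                                      for c in range(N_SEG_CLASSES)])
            seg_t, lm_t, oc_t = model.forward(xb.astype(np.float32))
            l_seg = nn.bce(seg_t, mb, scale=1.0 / seg_t.data.size)
            l_lm = nn.bce(lm_t, Ylm[sel], scale=1.0 / len(sel))
            w_oc = Woc[sel]
            l_oc = nn.bce(oc_t, Yoc[sel][:, None],
                          scale=1.0 / max(1.0, w_oc.sum()),
                          weight=w_oc[:, None])
            loss = nn.weighted_sum([(weights.alpha, l_seg),
                                    (weights.beta, l_lm),
                                    (weights.gamma, l_oc)])
            optim.zero_grad()
            loss.backward()
            optim.step()
            tot["seg"] += float(l_seg.data)
            tot["landmark"] += float(l_lm.data)
            tot["open_closed"] += float(l_oc.data)
            tot["total"] += float(loss.data)
            n_batches += 1
        history.append({k: v / n_batches for k, v in tot.items()} | {"epoch": epoch})
    return history


# ---------------------------------------------------------------------------
# Naive black-box baseline
# ---------------------------------------------------------------------------

class _FrameEncoder:
    """Small convolutional open/closed frame classifier; its penultimate
    128-unit layer provides the per-frame embeddings."""

    def __init__(self, res: int, seed: int):
        rng = np.random.default_rng(seed)
        self.res = res
        self.P = {
            "c1.w": nn.parameter(nn.he_conv(rng, 8, 1, 3)),
            "c1.b": nn.parameter(np.zeros(8)),
            "c2.w": nn.parameter(nn.he_conv(rng, 8, 8, 3)),
            "c2.b": nn.parameter(np.zeros(8)),
            "d1.w": nn.parameter(nn.he_dense(rng, 8, 128)),
            "d1.b": nn.parameter(np.zeros(128)),
            "d2.w": nn.parameter(nn.he_dense(rng, 128, 1)),
            "d2.b": nn.parameter(np.zeros(1)),
        }

    def forward(self, x: np.ndarray, with_head: bool = True):
        P = self.P
        t = nn.Tensor(x[:, None])
        h = nn.relu(nn.conv2d(t, P["c1.w"], P["c1.b"], stride=2))
        h = nn.relu(nn.conv2d(h, P["c2.w"], P["c2.b"], stride=2))
        emb = nn.relu(nn.dense(nn.global_avg_pool(h), P["d1.w"], P["d1.b"]))
        if not with_head:
            return emb
        return emb, nn.sigmoid(nn.dense(emb, P["d2.w"], P["d2.b"]))

    def parameters(self):
        return [self.P[k] for k in sorted(self.P)]


class _Seq1DCNN:
    """3-layer 1-D CNN over per-frame embeddings (channels x time)."""

    def __init__(self, in_ch: int, seed: int):
        rng = np.random.default_rng(seed)
        self.P = {
            "c1.w": nn.parameter(nn.he_conv(rng, 16, in_ch, 3)),
            "c1.b": nn.parameter(np.zeros(16)),
            "c2.w": nn.parameter(nn.he_conv(rng, 16, 16, 3)),
            "c2.b": nn.parameter(np.zeros(16)),
            "c3.w": nn.parameter(nn.he_conv(rng, 8, 16, 3)),
            "c3.b": nn.parameter(np.zeros(8)),
            "d.w": nn.parameter(nn.he_dense(rng, 8, 1)),
            "d.b": nn.parameter(np.zeros(1)),
        }

    def forward(self, x: np.ndarray):
        # x: (N, C, T) handled as (N, C, 1, T) so the 2-D conv machinery applies
        P = self.P
        t = nn.Tensor(x[:, :, None, :])
        h = nn.relu(_conv1d(t, P["c1.w"], P["c1.b"], stride=1))
        h = nn.relu(_conv1d(h, P["c2.w"], P["c2.b"], stride=2))
        h = nn.relu(_conv1d(h, P["c3.w"], P["c3.b"], stride=1))
        return nn.sigmoid(nn.dense(nn.global_avg_pool(h), P["d.w"], P["d.b"]))

    def parameters(self):
        return [self.P[k] for k in sorted(self.P)]


def _conv1d(x: nn.Tensor, w: nn.Tensor, b: nn.Tensor, stride: int) -> nn.Tensor:
    # 1-D convolution expressed as a 2-D one over a height-1 image; the
    # square kernel sees zero padding on the dummy axis, which contributes
    # nothing because the height-1 input occupies the centre row
    return nn.conv2d(x, w, b, stride=stride, pad=1)


def baseline_blackbox(
    train_sequences: Sequence[RenderedSequence],
    train_labels: Sequence[int],
    test_sequences: Sequence[RenderedSequence],
    seed: int = 0,
    res: int = 48,
    time_len: int = 32,
    encoder_epochs: int = 3,
    classifier_epochs: int = 30,
) -> np.ndarray:
    """The naive sequence classifier the explainable pipeline is compared to.

    Per-frame 128-dimensional embeddings come from a small convolutional
    encoder trained on the open/closed frame task; embeddings are stacked
    along time (padded/cropped to ``time_len``) and a 3-layer 1-D CNN learns
    a direct healthy/pathological decision.  Returns pathological-probability
    scores for ``test_sequences``.
    """
    labels = np.asarray(train_labels, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("baseline training requires both healthy and pathological sequences")
    rng = np.random.default_rng(seed)

    enc = _FrameEncoder(res, seed=int(rng.integers(2**31)))
    frames, oc = [], []
    for seq in train_sequences:
        idx = np.linspace(0, seq.n_frames - 1, 6).astype(int)
        frames.append(_resize_stack(seq.frames[idx], res))
        oc.extend(1.0 if seq.open_closed[t] == "closed" else 0.0 for t in idx)
    Xf = np.concatenate(frames)
    Yf = np.array(oc)[:, None]
    opt = nn.Adam(enc.parameters(), lr=1e-3)
    for _ in range(encoder_epochs):
        order = rng.permutation(Xf.shape[0])
        for start in range(0, Xf.shape[0], 16):
            sel = order[start:start + 16]
            _, p = enc.forward(Xf[sel])
            loss = nn.bce(p, Yf[sel], scale=1.0 / len(sel))
            opt.zero_grad()
            loss.backward()
            opt.step()

    def embed(seq: RenderedSequence) -> np.ndarray:
        x = _resize_stack(seq.frames, res)
        emb = enc.forward(x, with_head=False).data          # (T, 128)
        if emb.shape[0] >= time_len:
            emb = emb[:time_len]
        else:
            emb = np.pad(emb, ((0, time_len - emb.shape[0]), (0, 0)))
        return emb.T                                         # (128, T)

    Xtr = np.stack([embed(s) for s in train_sequences])
    cls = _Seq1DCNN(128, seed=int(rng.integers(2**31)))
    opt2 = nn.Adam(cls.parameters(), lr=1e-3)
    for _ in range(classifier_epochs):
        order = rng.permutation(Xtr.shape[0])
        for start in range(0, Xtr.shape[0], 8):
            sel = order[start:start + 8]
            p = cls.forward(Xtr[sel])
            loss = nn.bce(p, labels[sel][:, None], scale=1.0 / len(sel))
            opt2.zero_grad()
            loss.backward()
            opt2.step()

    Xte = np.stack([embed(s) for s in test_sequences])
    return cls.forward(Xte).data[:, 0]
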