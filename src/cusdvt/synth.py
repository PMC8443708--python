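"""Seeded synthetic compression-ultrasound sequences with exact ground truth.

The generator emulates the two-point compression exam on a 150x150 B-mode
frame: each anatomical landmark (LM0-LM10) has a characteristic arrangement
of vessel cross-sections (compressible veins, pulsating incompressible
arteries) rendered as dark elliptical lumina on a bright, speckled tissue
background.  Probe pressure is a dimensionless per-frame scalar in [0, 1]:
a healthy vein's vertical semi-axis shrinks as ``b·max(0, 1 − p/p_collapse)``
and fully closes at its collapse pressure, while a thrombosed vein never
shrinks below a residual fraction of its resting height — the physical
signature the exam protocol must recover.  Arteries pulsate within ±10% of
their resting height and never close.

Every output is a pure function of (configuration, seed); masks are exact
rendered ellipse interiors (speckle never touches them), and the per-frame
open/closed label is recomputed from the mask by an area rule, so the
ground truth is self-consistent frame by frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import transform as sktf

__all__ = [
    "FRAME_SIZE",
    "LANDMARKS",
    "LANDMARK_LAYOUTS",
    "VesselSpec",
    "SceneSpec",
    "CompressionProfile",
    "RenderedSequence",
    "make_scene",
    "render_sequence",
    "ramp_profile",
    "augment",
    "default_augment_config",
    "SequenceRecord",
    "DatasetManifest",
    "make_dataset",
    "realize",
]

FRAME_SIZE = 150
CLOSED_AREA_FRACTION = 0.05     # "fully compressed" = vein area <= 5% of rest
MIN_RESIDUAL_FRACTION = 0.3

LANDMARKS = tuple(f"LM{i}" for i in range(11))
BACKGROUND = "background"

# Canonical vessel arrangements per landmark: (class, (row, col) centre,
# (horizontal, vertical) semi-axes).  Compositions follow the anatomical
# descriptions (e.g. LM3: common femoral vein with superficial and deep
# femoral arteries -> 1 vein + 2 arteries; LM8: popliteal vein and artery);
# exact placements are this generator's own archetypes, jittered per seed.
LANDMARK_LAYOUTS: dict[str, tuple[tuple[str, tuple[int, int], tuple[int, int]], ...]] = {
    "LM0": (("vein", (75, 75), (19, 15)),),
    # saphenofemoral junction: small superficial great saphenous vein above
    # the large common femoral vein
    "LM1": (("vein", (48, 62), (9, 7)), ("vein", (84, 82), (17, 13))),
    # common femoral vein medial to its artery, similar depth
    "LM2": (("vein", (76, 52), (17, 13)), ("artery", (72, 98), (12, 12))),
    "LM3": (("vein", (78, 48), (17, 13)), ("artery", (60, 92), (11, 11)),
            ("artery", (92, 100), (10, 10))),
    "LM4": (("vein", (62, 40), (13, 11)), ("vein", (92, 62), (12, 10)),
            ("artery", (52, 90), (10, 10)), ("artery", (86, 108), (10, 10))),
    "LM5": (("vein", (58, 58), (13, 11)), ("vein", (96, 92), (11, 9))),
    "LM6": (("vein", (72, 62), (14, 11)), ("artery", (64, 100), (11, 11))),
    "LM7": (("vein", (84, 78), (13, 10)), ("artery", (66, 42), (11, 11))),
    "LM8": (("vein", (66, 74), (17, 13)), ("artery", (100, 76), (11, 11))),
    "LM9": (("vein", (74, 54), (13, 10)), ("artery", (98, 94), (10, 10))),
    "LM10": (("vein", (58, 48), (10, 8)), ("vein", (72, 84), (9, 7)),
             ("vein", (92, 56), (9, 7)), ("artery", (100, 102), (9, 9))),
    BACKGROUND: (),
}

ARTERY_PULSE_AMPLITUDE = 0.08   # fraction of resting vertical semi-axis
ARTERY_PULSE_PERIOD = 10.0      # frames per cardiac cycle

TISSUE_INTENSITY = 0.55


@dataclass(frozen=True)
class VesselSpec:
    """One vessel cross-section: geometry, echo intensity and compressibility."""

    vessel_class: str                   # "artery" | "vein"
    center: tuple[int, int]             # (row, col), 0-based, origin top-left
    semi_axes: tuple[float, float]      # (horizontal a, vertical b) in pixels
    echogenicity: float                 # lumen intensity in [0, 1]
    collapse_pressure: float = 1.0      # pressure closing a healthy vein
    thrombosed: bool = False
    residual_fraction: float = 1.0      # min vertical-axis fraction if thrombosed

    def __post_init__(self) -> None:
        if self.vessel_class not in ("artery", "vein"):
            raise ValueError(f"unknown vessel class {self.vessel_class!r}")
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        r, c = self.center
        margin = 1.0 + ARTERY_PULSE_AMPLITUDE
        if not (0 <= r - b * margin and r + b * margin < FRAME_SIZE
                and 0 <= c - a and c + a < FRAME_SIZE):
            raise ValueError("ellipse does not fit inside the frame at rest")
        if not 0.0 <= self.echogenicity <= 1.0:
            raise ValueError("echogenicity must be in [0, 1]")
        if not 0.0 < self.collapse_pressure <= 1.0:
            raise ValueError("collapse pressure must be in (0, 1]")
        if self.vessel_class == "artery" and self.thrombosed:
            raise ValueError("arteries cannot be thrombosed")
        if self.thrombosed and not MIN_RESIDUAL_FRACTION <= self.residual_fraction <= 1.0:
            raise ValueError(
                f"thrombosed residual fraction must be in "
                f"[{MIN_RESIDUAL_FRACTION}, 1]"
            )

    def vertical_axis_at(self, pressure: float, t: int, pulse_phase: float) -> float:
        """Vertical semi-axis at frame ``t`` under probe ``pressure``."""
        b = self.semi_axes[1]
        if self.vessel_class == "artery":
            osc = ARTERY_PULSE_AMPLITUDE * math.sin(
                2 * math.pi * t / ARTERY_PULSE_PERIOD + pulse_phase)
            return b * min(1.1, max(0.9, 1.0 + osc))
        squeeze = max(0.0, 1.0 - pressure / self.collapse_pressure)
        if self.thrombosed:
            squeeze = max(self.residual_fraction, squeeze)
        return b * squeeze


@dataclass(frozen=True)
class SceneSpec:
    """A landmark's vessel arrangement plus its texture parameters."""

    landmark: str
    vessels: tuple[VesselSpec, ...]
    texture_seed: int
    speckle_params: tuple[float, float] = (2.0, 0.35)   # (grain px, contrast)

    def __post_init__(self) -> None:
        if self.landmark not in LANDMARK_LAYOUTS:
            raise ValueError(f"unknown landmark {self.landmark!r}")
        expected = [cls for cls, _, _ in LANDMARK_LAYOUTS[self.landmark]]
        got = [v.vessel_class for v in self.vessels]
        if sorted(expected) != sorted(got):
            raise ValueError(
                f"{self.landmark}: vessel composition {got} does not match "
                f"the landmark's arrangement {expected}"
            )

    @property
    def pathological(self) -> bool:
        return any(v.thrombosed for v in self.vessels)


@dataclass(frozen=True)
class CompressionProfile:
    """Per-frame dimensionless probe pressure in [0, 1]."""

    pressure: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.pressure) == 0:
            raise ValueError("profile must contain at least one frame")
        if any(not 0.0 <= p <= 1.0 for p in self.pressure):
            raise ValueError("pressure values must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.pressure)


def ramp_profile(n_rest: int = 3, n_up: int = 7, n_plateau: int = 4,
                 n_down: int = 6, peak: float = 1.0) -> CompressionProfile:
    """Medium-paced settle / compress / hold / release pressure profile.

    The leading rest phase mirrors the exam flow: the operator settles the
    probe on the landmark before compressing.
    """
    rest = np.zeros(n_rest)
    up = np.linspace(0.0, peak, n_up, endpoint=False)
    plateau = np.full(n_plateau, peak)
    down = np.linspace(peak, 0.0, n_down + 1)[1:]
    return CompressionProfile(tuple(np.r_[rest, up, plateau, down].tolist()))


@dataclass(frozen=True)
class RenderedSequence:
    """A rendered compression clip with per-frame ground truth."""

    frames: np.ndarray            # (n, 150, 150) float in [0, 1]
    masks: np.ndarray             # (n, 150, 150) uint8 in {0 bg, 1 artery, 2 vein}
    landmark_label: str
    open_closed: tuple[str, ...]  # per frame, "open" | "closed"
    scene: SceneSpec
    profile: CompressionProfile
    seed: int
    rest_vein_area: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def vein_area_ratio(self) -> np.ndarray:
        """Per-frame total vein area over the rest-state vein area."""
        areas = (self.masks == 2).sum(axis=(1, 2))
        return areas / max(1, self.rest_vein_area)


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def make_scene(landmark: str, pathology: bool, seed: int,
               residual_fraction: float = 0.5) -> SceneSpec:
    """Build a seeded scene for ``landmark``; exactly one vein thrombosed
    when ``pathology``.

    Positions are jittered ±3 px and sizes ±10% around the landmark's
    archetype; vein collapse pressures are drawn in [0.5, 0.8] so a ramp to
    full pressure always closes every healthy vein.
    """
    if landmark not in LANDMARK_LAYOUTS:
        raise ValueError(f"unknown landmark id {landmark!r}")
    lm_index = (LANDMARKS.index(landmark) if landmark in LANDMARKS
                else len(LANDMARKS))
    rng = np.random.default_rng(np.random.SeedSequence([seed, lm_index,
                                                        int(pathology)]))
    layout = LANDMARK_LAYOUTS[landmark]
    vein_idx = [i for i, (cls, _, _) in enumerate(layout) if cls == "vein"]
    if pathology and not vein_idx:
        raise ValueError(f"{landmark}: a pathological scene needs a vein")
    thrombosed_idx = int(rng.choice(vein_idx)) if pathology else -1

    vessels = []
    for i, (cls, (r, c), (a, b)) in enumerate(layout):
        jr, jc = rng.integers(-3, 4, size=2)
        scale = rng.uniform(0.9, 1.1)
        vessels.append(VesselSpec(
            vessel_class=cls,
            center=(int(r + jr), int(c + jc)),
            semi_axes=(a * scale, b * scale),
            echogenicity=float(rng.uniform(0.08, 0.20)),
            collapse_pressure=float(rng.uniform(0.5, 0.8)) if cls == "vein" else 1.0,
            thrombosed=(i == thrombosed_idx),
            residual_fraction=residual_fraction if i == thrombosed_idx else 1.0,
        ))
    return SceneSpec(
        landmark=landmark,
        vessels=tuple(vessels),
        texture_seed=int(rng.integers(0, 2**31 - 1)),
        speckle_params=(float(rng.uniform(1.5, 2.5)), float(rng.uniform(0.25, 0.45))),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_ROWS, _COLS = np.mgrid[0:FRAME_SIZE, 0:FRAME_SIZE].astype(float)


def _ellipse_mask(center: tuple[float, float], a: float, b: float) -> np.ndarray:
    if b <= 0 or a <= 0:
        return np.zeros((FRAME_SIZE, FRAME_SIZE), dtype=bool)
    r0, c0 = center
    return ((_ROWS - r0) / b) ** 2 + ((_COLS - c0) / a) ** 2 <= 1.0


def _rest_vein_area(scene: SceneSpec) -> int:
    area = 0
    for v in scene.vessels:
        if v.vessel_class == "vein":
            area += int(_ellipse_mask(v.center, *v.semi_axes).sum())
    return area


def render_sequence(scene: SceneSpec, profile: CompressionProfile, seed: int,
                    speckle: bool = True, render_frames: bool = True,
                    closed_area_fraction: float = CLOSED_AREA_FRACTION,
                    ) -> RenderedSequence:
    """Render a compression clip from a scene and a pressure profile.

    Healthy veins close when pressure reaches their collapse pressure;
    thrombosed veins retain their residual lumen; arteries pulsate.
    Speckle (multiplicative low-pass-filtered noise) is applied to the
    frames only — masks are the exact rendered ellipse interiors.
    ``render_frames=False`` leaves the frames black (masks and labels only),
    which is enough for ground-truth-driven protocol runs.
    """
    n = profile.n_frames
    rng = np.random.default_rng(seed)
    tex_rng = np.random.default_rng(scene.texture_seed)
    grain, contrast = scene.speckle_params

    phases = {id(v): float(rng.uniform(0, 2 * math.pi)) for v in scene.vessels}
    rest_area = _rest_vein_area(scene)

    if render_frames and speckle:
        tex = gaussian_filter(tex_rng.standard_normal((FRAME_SIZE, FRAME_SIZE)), grain)
        tex /= max(1e-9, tex.std())
    else:
        tex = None

    frames = np.zeros((n, FRAME_SIZE, FRAME_SIZE), dtype=np.float32)
    masks = np.zeros((n, FRAME_SIZE, FRAME_SIZE), dtype=np.uint8)
    open_closed = []
    for t, p in enumerate(profile.pressure):
        frame = np.full((FRAME_SIZE, FRAME_SIZE), TISSUE_INTENSITY, dtype=float)
        mask = np.zeros((FRAME_SIZE, FRAME_SIZE), dtype=np.uint8)
        for v in scene.vessels:
            b_t = v.vertical_axis_at(p, t, phases[id(v)])
            region = _ellipse_mask(v.center, v.semi_axes[0], b_t)
            mask[region] = 1 if v.vessel_class == "artery" else 2
            if render_frames:
                frame[region] = v.echogenicity
        if render_frames:
            if tex is not None:
                frame = frame * (1.0 + contrast * tex)
                frame += 0.02 * rng.standard_normal(frame.shape)
            frames[t] = np.clip(frame, 0.0, 1.0)
        masks[t] = mask
        vein_area = int((mask == 2).sum())
        # scenes without any vein (pure background) are never "closed"
        closed = rest_area > 0 and vein_area <= closed_area_fraction * rest_area
        open_closed.append("closed" if closed else "open")

    seq = RenderedSequence(
        frames=frames, masks=masks, landmark_label=scene.landmark,
        open_closed=tuple(open_closed), scene=scene, profile=profile,
        seed=seed, rest_vein_area=rest_area,
    )
    if scene.pathological and "closed" in seq.open_closed:
        raise AssertionError("thrombosed scene produced a closed frame")
    return seq


# ---------------------------------------------------------------------------
# Training-time augmentation
# ---------------------------------------------------------------------------

def default_augment_config() -> dict[str, float | bool]:
    """The standard augmentation envelope: random left/right flip, ±15 px
    translation, ±15° rotation, zoom up to a factor 0.05, intensity
    rescaling within ±0.3."""
    return {"flip": True, "translate_px": 15.0, "rotate_deg": 15.0,
            "zoom": 0.05, "intensity": 0.3}


def augment(window: np.ndarray, mask: np.ndarray, seed: int,
            config: Mapping[str, float | bool] | None = None,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random augmentation to a 9-frame window and its mask.

    The same geometric transform (flip, translation, rotation, zoom) is
    applied to every frame and to the mask; the intensity rescale touches
    frames only.  Frames are interpolated bilinearly, the mask with nearest
    neighbour so no new labels appear.  Deterministic given ``seed``.
    """
    cfg = default_augment_config()
    if config:
        cfg.update(config)
    window = np.asarray(window, dtype=float)
    mask = np.asarray(mask)
    if window.ndim != 3 or window.shape[1:] != mask.shape:
        raise ValueError("window must be (n_frames, H, W) matching the mask shape")
    rng = np.random.default_rng(seed)

    do_flip = bool(cfg["flip"]) and rng.random() < 0.5
    t_max = float(cfg["translate_px"])
    tx, ty = rng.uniform(-t_max, t_max, size=2) if t_max else (0.0, 0.0)
    r_max = float(cfg["rotate_deg"])
    theta = math.radians(rng.uniform(-r_max, r_max)) if r_max else 0.0
    z_max = float(cfg["zoom"])
    zoom = 1.0 + (rng.uniform(-z_max, z_max) if z_max else 0.0)
    i_max = float(cfg["intensity"])
    gain = 1.0 + (rng.uniform(-i_max, i_max) if i_max else 0.0)

    h, w = mask.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    tform = (sktf.AffineTransform(translation=(-cx, -cy))
             + sktf.AffineTransform(rotation=theta, scale=(zoom, zoom))
             + sktf.AffineTransform(translation=(cx + tx, cy + ty)))

    def warp(img: np.ndarray, order: int) -> np.ndarray:
        src = img[:, ::-1] if do_flip else img
        return sktf.warp(src.astype(float), tform.inverse, order=order,
                         mode="constant", cval=0.0, preserve_range=True)

    identity = not do_flip and tx == ty == 0.0 and theta == 0.0 and zoom == 1.0
    if identity:
        out_frames = window.copy()
        out_mask = mask.copy()
    else:
        out_frames = np.stack([warp(f, order=1) for f in window])
        out_mask = warp(mask, order=0).round().astype(mask.dtype)
    out_frames = np.clip(out_frames * gain, 0.0, 1.0)
    return out_frames, out_mask


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """Everything needed to regenerate one sequence bit-identically."""

    sequence_id: str
    subject_id: str
    landmark: str
    pathology: bool
    scene_seed: int
    render_seed: int
    split: str                       # "train" | "val"
    n_frames: int
    peak_pressure: float
    speckle: bool

    def profile(self) -> CompressionProfile:
        n_rest = max(1, round(self.n_frames * 0.15))
        n_up = max(1, round(self.n_frames * 0.35))
        n_plateau = max(1, round(self.n_frames * 0.20))
        n_down = self.n_frames - n_rest - n_up - n_plateau
        return ramp_profile(n_rest, n_up, n_plateau, n_down,
                            peak=self.peak_pressure)


@dataclass(frozen=True)
class DatasetManifest:
    seed: int
    records: tuple[SequenceRecord, ...]
    config: Mapping[str, object]

    def split(self, which: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.split == which]

    def subjects(self, which: str | None = None) -> set[str]:
        recs = self.records if which is None else self.split(which)
        return {r.subject_id for r in recs}


def realize(record: SequenceRecord) -> RenderedSequence:
    """Regenerate the sequence a record describes (pure function of the record)."""
    scene = make_scene(record.landmark, record.pathology, record.scene_seed)
    return render_sequence(scene, record.profile(), record.render_seed,
                           speckle=record.speckle)


def make_dataset(config: Mapping[str, object]) -> DatasetManifest:
    """Plan a seeded synthetic dataset with a subject-level validation split.

    ``config`` keys: ``landmarks`` (mapping landmark → sequence count),
    ``n_subjects``, ``pathology_fraction``, ``val_fraction`` (default 0.1,
    drawn at subject level so no subject straddles the split), ``n_frames``,
    ``peak_pressure``, ``speckle``, ``seed``.  The manifest records per-
    sequence seeds so any sequence can be regenerated bit-identically.
    """
    landmarks: Mapping[str, int] = config["landmarks"]          # type: ignore[assignment]
    n_subjects = int(config.get("n_subjects", 10))
    pathology_fraction = float(config.get("pathology_fraction", 0.0))
    val_fraction = float(config.get("val_fraction", 0.1))
    n_frames = int(config.get("n_frames", 20))
    peak = float(config.get("peak_pressure", 1.0))
    speckle = bool(config.get("speckle", True))
    seed = int(config["seed"])

    if not 0.0 <= pathology_fraction <= 1.0:
        raise ValueError("pathology_fraction must be in [0, 1]")
    unknown = set(landmarks) - set(LANDMARK_LAYOUTS)
    if unknown:
        raise ValueError(f"unknown landmarks in config: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    subject_ids = [f"S{i:03d}" for i in range(n_subjects)]
    order = rng.permutation(n_subjects)
    n_val = max(1, int(round(n_subjects * val_fraction))) if val_fraction > 0 else 0
    val_subjects = {subject_ids[i] for i in order[:n_val]}

    records = []
    k = 0
    for landmark in sorted(landmarks):
        for _ in range(int(landmarks[landmark])):
            subject = subject_ids[k % n_subjects]
            pathology = (landmark != BACKGROUND
                         and bool(rng.random() < pathology_fraction))
            records.append(SequenceRecord(
                sequence_id=f"seq{k:04d}",
                subject_id=subject,
                landmark=landmark,
                pathology=pathology,
                scene_seed=int(rng.integers(0, 2**31 - 1)),
                render_seed=int(rng.integers(0, 2**31 - 1)),
                split="val" if subject in val_subjects else "train",
                n_frames=n_frames,
                peak_pressure=peak,
                speckle=speckle,
            ))
            k += 1
    return DatasetManifest(seed=seed, records=tuple(records),
                           config={k: v for k, v in config.items()})
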