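"""On-disk formats: frame-stack sequences, manifests and result files.

The canonical sequence format is a directory with 8-bit grayscale frames
(``frames/frame_%05d.png``), indexed masks (``masks/mask_%05d.png``,
values 0 = background, 1 = artery, 2 = vein) and a ``sequence.json``
manifest.  Frames are normalised to [0, 1] and resampled bilinearly to
150x150 on read.  mp4 import is supported when an ffmpeg-capable imageio
plugin is available; the frame-stack layout is always the ground truth.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Any, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

from .synth import FRAME_SIZE, DatasetManifest, RenderedSequence, SequenceRecord

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_manifest",
    "read_manifest",
    "config_hash",
    "write_results",
]


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable 12-hex-digit digest of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_sequence(seq: RenderedSequence, out_dir: str | os.PathLike) -> Path:
    """Write a rendered sequence in the frame-stack layout; returns the dir."""
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for t in range(seq.n_frames):
        frame8 = np.clip(seq.frames[t] * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(out / "frames" / f"frame_{t:05d}.png", frame8)
        iio.imwrite(out / "masks" / f"mask_{t:05d}.png", seq.masks[t])
    manifest = {
        "landmark": seq.landmark_label,
        "n_frames": seq.n_frames,
        "seed": seq.seed,
        "pressure": list(seq.profile.pressure),
        "open_closed": list(seq.open_closed),
        "pathology": seq.scene.pathological,
        "rest_vein_area": seq.rest_vein_area,
    }
    with open(out / "sequence.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def _load_frames(paths: Sequence[Path]) -> np.ndarray:
    frames = []
    bad = []
    for p in paths:
        try:
            img = iio.imread(p)
        except Exception:
            bad.append(str(p))
            continue
        f = np.asarray(img, dtype=float)
        if f.ndim == 3:
            f = f.mean(axis=-1)
        f = f / 255.0 if f.max() > 1.0 else f
        if f.shape != (FRAME_SIZE, FRAME_SIZE):
            f = _sk_resize(f, (FRAME_SIZE, FRAME_SIZE), order=1,
                           preserve_range=True, anti_aliasing=False)
        frames.append(np.clip(f, 0.0, 1.0))
    if bad:
        raise IOError(f"unreadable frames: {bad}")
    return np.stack(frames)


def read_sequence(path: str | os.PathLike) -> dict[str, Any]:
    """Load a sequence directory (or mp4 file) into memory.

    Returns ``{"frames", "masks" (or None), "manifest"}`` with frames in
    [0, 1] at 150x150.  mp4 input is converted to the frame-stack form in
    memory; it requires an ffmpeg-capable imageio backend.
    """
    p = Path(path)
    if p.is_file() and p.suffix.lower() == ".mp4":
        try:
            raw = iio.imread(p, plugin="pyav")
        except Exception:
            try:
                raw = iio.imread(p)
            except Exception as exc:   # no decoder available
                raise IOError(
                    f"cannot decode {p}: no mp4-capable imageio backend; "
                    f"convert to the frame-stack directory layout instead"
                ) from exc
        frames = np.asarray(raw, dtype=float)
        if frames.ndim == 4:
            frames = frames.mean(axis=-1)
        frames = np.stack([
            _sk_resize(f / 255.0, (FRAME_SIZE, FRAME_SIZE), order=1,
                       preserve_range=True, anti_aliasing=False)
            for f in frames])
        return {"frames": np.clip(frames, 0, 1), "masks": None, "manifest": {}}

    if not p.is_dir():
        raise IOError(f"sequence path {p} does not exist")
    frame_paths = sorted((p / "frames").glob("frame_*.png"))
    if not frame_paths:
        raise IOError(f"no frames found under {p / 'frames'}")
    frames = _load_frames(frame_paths)

    masks = None
    mask_dir = p / "masks"
    if mask_dir.is_dir():
        mask_paths = sorted(mask_dir.glob("mask_*.png"))
        if len(mask_paths) != len(frame_paths):
            raise IOError(
                f"frame/mask count mismatch: {len(frame_paths)} frames, "
                f"{len(mask_paths)} masks")
        masks = np.stack([np.asarray(iio.imread(m)) for m in mask_paths]).astype(np.uint8)

    manifest: dict[str, Any] = {}
    mf = p / "sequence.json"
    if mf.exists():
        with open(mf) as fh:
            manifest = json.load(fh)
    return {"frames": frames, "masks": masks, "manifest": manifest}


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    records = [vars(r) if not hasattr(r, "__dataclass_fields__") else
               {k: getattr(r, k) for k in r.__dataclass_fields__}
               for r in manifest.records]
    payload = {"seed": manifest.seed, "config": dict(manifest.config),
               "config_hash": config_hash(dict(manifest.config)),
               "records": records}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def read_manifest(path: str | os.PathLike) -> DatasetManifest:
    with open(path) as fh:
        payload = json.load(fh)
    records = tuple(SequenceRecord(**r) for r in payload["records"])
    return DatasetManifest(seed=payload["seed"], records=records,
                           config=payload["config"])


def write_results(objects: Mapping[str, Any], out_dir: str | os.PathLike,
                  config: Mapping[str, Any] | None = None) -> list[Path]:
    """Write result objects deterministically: DataFrames to CSV, mappings
    to JSON; every artifact embeds the configuration hash."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config or {})
    written = []
    for name, obj in sorted(objects.items()):
        if hasattr(obj, "to_csv"):            # pandas DataFrame / Series
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False)
        else:
            path = out / f"{name}.json"
            with open(path, "w") as fh:
                json.dump({"config_hash": chash, "data": obj}, fh, indent=2,
                          sort_keys=True, default=_json_default)
        written.append(path)
    return written


def _json_default(o: Any):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    return str(o)
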