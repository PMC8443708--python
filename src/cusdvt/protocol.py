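"""The two-point compression exam automaton.

Per-window network outputs are turned into a per-sequence compression
verdict at a consolidated landmark group, attempts are limited per group,
and the three required groups (two in the groin, one at the knee)
aggregate to the patient-level decision: every group must show a fully
compressible vein to exclude DVT; a vein that resists compression marks
the patient as a suspected DVT case; an exam that never adequately images
a group is incomplete and triggers a referral recommendation.

A sequence is *compressible* when (a) the landmark gate holds — enough
windows are recognised as the target group — and (b) closure is detected,
either by the open/closed head (posterior above threshold for a run of
consecutive windows) or by the predicted vein area collapsing to a small
fraction of its in-sequence baseline.  The two closure gates are combined
with a configurable OR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .net import VEIN_CHANNEL

__all__ = [
    "CONSOLIDATED_GROUPS",
    "REQUIRED_GROUPS",
    "LandmarkGroup",
    "ProtocolThresholds",
    "SequenceVerdict",
    "PatientVerdict",
    "consolidate_posterior",
    "sequence_verdict",
    "temporal_quality",
    "attempt_loop",
    "patient_verdict",
    "exam_score",
    "oracle_outputs",
    "group_for_landmark",
]


@dataclass(frozen=True)
class LandmarkGroup:
    id: str
    members: tuple[str, ...]


GROIN_A = LandmarkGroup("GROIN_A", ("LM0", "LM1"))
GROIN_B = LandmarkGroup("GROIN_B", ("LM2", "LM3", "LM4"))
THIGH = LandmarkGroup("THIGH", ("LM6", "LM7"))
KNEE = LandmarkGroup("KNEE", ("LM8", "LM9", "LM10"))

# Consolidated groups used for reporting; the two-point exam requires
# GROIN_A, GROIN_B and KNEE (the thigh group belongs to the three-point
# protocol variant and is not part of the required set).
CONSOLIDATED_GROUPS: tuple[LandmarkGroup, ...] = (GROIN_A, GROIN_B, THIGH, KNEE)
REQUIRED_GROUPS: tuple[LandmarkGroup, ...] = (GROIN_A, GROIN_B, KNEE)
_GROUPS = {g.id: g for g in CONSOLIDATED_GROUPS}


def group_for_landmark(landmark: str) -> LandmarkGroup | None:
    for g in CONSOLIDATED_GROUPS:
        if landmark in g.members:
            return g
    return None


@dataclass(frozen=True)
class ProtocolThresholds:
    """Decision thresholds of the exam automaton (all configurable)."""

    tau_landmark: float = 0.5       # min fraction of windows matching the group
    tau_closed: float = 0.5         # open/closed posterior threshold
    k_consecutive: int = 3          # required run length of closed windows
    area_epsilon: float = 0.05      # vein-area collapse threshold vs baseline
    gate_mode: str = "or"           # how posterior and area gates combine

    def __post_init__(self) -> None:
        if self.gate_mode not in ("or", "and", "posterior", "area"):
            raise ValueError(f"unknown gate mode {self.gate_mode!r}")
        if self.k_consecutive < 1:
            raise ValueError("k_consecutive must be >= 1")


@dataclass(frozen=True)
class SequenceVerdict:
    group: LandmarkGroup
    status: str                     # compressible | non_compressible | inadequate
    min_area_ratio: float
    max_closed_posterior: float
    landmark_match_fraction: float


@dataclass(frozen=True)
class PatientVerdict:
    status: str                     # dvt_excluded | suspected_dvt | incomplete_exam
    group_results: Mapping[str, str]
    attempts_used: Mapping[str, int]
    refer: bool = False


def consolidate_posterior(posterior: np.ndarray, class_names: Sequence[str]
                          ) -> dict[str, float]:
    """Sum member-class posteriors into consolidated groups (+ background).

    Classes outside any consolidated group (e.g. LM5 in the two-point
    protocol) are accumulated under ``"other"``.
    """
    if len(posterior) != len(class_names):
        raise ValueError("posterior length does not match class names")
    out: dict[str, float] = {g.id: 0.0 for g in CONSOLIDATED_GROUPS}
    out["background"] = 0.0
    out["other"] = 0.0
    for p, name in zip(posterior, class_names):
        if name == "background":
            out["background"] += float(p)
        else:
            g = group_for_landmark(name)
            out[g.id if g else "other"] += float(p)
    return out


def _vein_area(seg_prob: np.ndarray, threshold: float = 0.5) -> float:
    # thresholded pixel count from the channel-last (H, W, 3) probability map;
    # counting beats summing raw probabilities, which diffuse background mass
    return float((seg_prob[..., VEIN_CHANNEL] >= threshold).sum())


def sequence_verdict(
    window_outputs: Sequence[tuple[np.ndarray, np.ndarray, float]],
    target_group: "LandmarkGroup | str",
    class_names: Sequence[str],
    thresholds: ProtocolThresholds = ProtocolThresholds(),
) -> SequenceVerdict:
    """Classify one compression sequence against its target landmark group.

    ``window_outputs`` is the per-window stream of (segmentation probability
    map, landmark posterior, closed posterior).
    """
    if len(window_outputs) == 0:
        raise ValueError("window output stream is empty")
    group = _GROUPS[target_group] if isinstance(target_group, str) else target_group

    matches = 0
    areas = np.empty(len(window_outputs))
    closed_post = np.empty(len(window_outputs))
    for t, (seg, lm, oc) in enumerate(window_outputs):
        cons = consolidate_posterior(np.asarray(lm), class_names)
        if max(cons, key=lambda k: cons[k]) == group.id:
            matches += 1
        areas[t] = _vein_area(np.asarray(seg))
        closed_post[t] = oc
    match_fraction = matches / len(window_outputs)
    baseline = float(areas.max())
    ratios = areas / baseline if baseline > 0 else np.ones_like(areas)
    min_ratio = float(ratios.min())
    max_post = float(closed_post.max())

    closed_runs = _max_run(closed_post >= thresholds.tau_closed)
    posterior_gate = closed_runs >= thresholds.k_consecutive
    area_gate = min_ratio <= thresholds.area_epsilon
    if thresholds.gate_mode == "or":
        closure = posterior_gate or area_gate
    elif thresholds.gate_mode == "and":
        closure = posterior_gate and area_gate
    elif thresholds.gate_mode == "posterior":
        closure = posterior_gate
    else:
        closure = area_gate

    if match_fraction < thresholds.tau_landmark:
        status = "inadequate"
    elif closure:
        status = "compressible"
    else:
        status = "non_compressible"
    return SequenceVerdict(group=group, status=status,
                           min_area_ratio=min_ratio,
                           max_closed_posterior=max_post,
                           landmark_match_fraction=match_fraction)


def _max_run(flags: np.ndarray) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def temporal_quality(
    window_outputs: Sequence[tuple[np.ndarray, np.ndarray, float]],
    min_vein_pixels: float = 5.0,
    border_margin: int = 2,
    pace_band: tuple[int, int] = (3, 50),
    vein_prob_threshold: float = 0.5,
) -> dict[str, object]:
    """Heuristic temporal quality flags for operator feedback.

    ``vessel_in_frame``: fraction of windows with a visible vein;
    ``vessel_near_border``: the vein's bounding box touches the image edge
    in any window; ``compression_pace``: number of windows from the last
    fully-open state to the first closure, flagged when outside the band.
    """
    if len(window_outputs) == 0:
        raise ValueError("window output stream is empty")
    n = len(window_outputs)
    in_frame = 0
    near_border = False
    areas = np.empty(n)
    for t, (seg, _, _) in enumerate(window_outputs):
        vein = np.asarray(seg)[..., VEIN_CHANNEL] >= vein_prob_threshold
        areas[t] = vein.sum()
        if areas[t] >= min_vein_pixels:
            in_frame += 1
            rows = np.flatnonzero(vein.any(axis=1))
            cols = np.flatnonzero(vein.any(axis=0))
            h, w = vein.shape
            if (rows[0] < border_margin or rows[-1] >= h - border_margin
                    or cols[0] < border_margin or cols[-1] >= w - border_margin):
                near_border = True
    vessel_in_frame = in_frame / n

    baseline = areas.max()
    pace = None
    if baseline > 0:
        ratios = areas / baseline
        closed_idx = np.flatnonzero(ratios <= 0.05)
        if closed_idx.size:
            first_closed = int(closed_idx[0])
            open_before = np.flatnonzero(ratios[:first_closed] >= 0.9)
            start = int(open_before[-1]) if open_before.size else 0
            pace = first_closed - start
    lo, hi = pace_band
    return {
        "vessel_in_frame": vessel_in_frame,
        "vessel_in_frame_flag": vessel_in_frame == 0.0,
        "vessel_near_border": near_border,
        "compression_pace": pace,
        "compression_pace_flag": pace is not None and not lo <= pace <= hi,
    }


def attempt_loop(group: "LandmarkGroup | str",
                 verdicts: Iterable[SequenceVerdict],
                 max_attempts: int = 3) -> tuple[str, int]:
    """Repeat compressions at one group until success or attempts run out.

    Stops at the first compressible verdict.  After ``max_attempts``
    without success the group keeps the worst informative verdict seen:
    non-compressible dominates inadequate (a vein seen resisting pressure
    must not be downgraded by a later badly-imaged attempt).
    """
    if not 1 <= max_attempts <= 10:
        raise ValueError("max_attempts must be in [1, 10]")
    group_id = group if isinstance(group, str) else group.id
    attempts = 0
    saw_non_compressible = False
    saw_any = False
    for v in verdicts:
        if v.group.id != group_id:
            raise ValueError(f"verdict for group {v.group.id} in {group_id} loop")
        saw_any = True
        attempts += 1
        if v.status == "compressible":
            return "compressible", attempts
        if v.status == "non_compressible":
            saw_non_compressible = True
        if attempts >= max_attempts:
            break
    if not saw_any:
        return "missing", 0
    return ("non_compressible" if saw_non_compressible else "inadequate"), attempts


def patient_verdict(group_statuses: Mapping[str, str],
                    attempts_used: Mapping[str, int] | None = None) -> PatientVerdict:
    """Aggregate required-group statuses into the patient-level decision.

    All three groups compressible → DVT excluded; any non-compressible
    group → suspected DVT; otherwise (a group inadequate or missing, none
    non-compressible) → incomplete exam with a referral recommendation.
    """
    statuses = {g.id: group_statuses.get(g.id, "missing") for g in REQUIRED_GROUPS}
    valid = {"compressible", "non_compressible", "inadequate", "missing"}
    bad = {s for s in statuses.values() if s not in valid}
    if bad:
        raise ValueError(f"unknown group statuses: {sorted(bad)}")
    if any(s == "non_compressible" for s in statuses.values()):
        status, refer = "suspected_dvt", True
    elif all(s == "compressible" for s in statuses.values()):
        status, refer = "dvt_excluded", False
    else:
        status, refer = "incomplete_exam", True
    return PatientVerdict(status=status, group_results=statuses,
                          attempts_used=dict(attempts_used or {}), refer=refer)


def exam_score(group_evidence: Mapping[str, float]) -> float:
    """Continuous patient-level DVT score for ROC analysis.

    ``group_evidence`` maps each required group to the maximum closed
    posterior achieved there; the score is the largest residual
    ``1 − max_closed_posterior`` over groups — high when any group resists
    closure.  (The published system plots patient-level ROCs without
    defining the underlying score; this monotone surrogate is this
    package's own construction.)
    """
    if not group_evidence:
        raise ValueError("no group evidence")
    return max(1.0 - float(v) for v in group_evidence.values())


def oracle_outputs(sequence, class_names: Sequence[str]
                   ) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Ground-truth window outputs: the simulator's own masks and labels
    presented in the network-output format (one-hot segmentation, one-hot
    landmark posterior, closed indicator), bypassing any model."""
    names = list(class_names)
    lm_idx = names.index(sequence.landmark_label) if sequence.landmark_label in names \
        else names.index("background")
    lm = np.zeros(len(names))
    lm[lm_idx] = 1.0
    outputs = []
    for t in range(sequence.n_frames):
        mask = sequence.masks[t]
        seg = np.stack([(mask == c).astype(float) for c in range(3)], axis=-1)
        oc = 1.0 if sequence.open_closed[t] == "closed" else 0.0
        outputs.append((seg, lm, oc))
    return outputs
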