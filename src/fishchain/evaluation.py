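"""Quantitative evaluation against ground truth.

Four metrics summarize a tracking run: miss ratio and error ratio score
the detections, the correct tracking ratio (CTR) scores fish-frames, the
average interruption times (AIT) scores trajectory continuity per fish
per 100 frames, and the correct identification ratio (CIR) scores
identity preservation across occlusion events.

A fish-frame is *correct* when the tracked nose lies within a tolerance
(default 10 px) of the annotated nose and the pose passed the 80% cover
check; when the ground truth includes joint chains, the fitted joints
must also lie within the tolerance of the true ones on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relinking import Tracklet

__all__ = [
    "MetricsReport",
    "match_to_truth",
    "miss_error_ratio",
    "ctr",
    "ait",
    "cir",
    "evaluate",
]


@dataclass
class MetricsReport:
    miss_ratio: float
    error_ratio: float
    ctr: float
    ait: float
    cir: float | None  # None when no occlusion events occurred
    n_fish: int
    n_frames: int
    n_interruptions: int = 0
    n_occlusion_events: int = 0

    def to_dict(self) -> dict:
        return {
            "miss_ratio": self.miss_ratio,
            "error_ratio": self.error_ratio,
            "ctr": self.ctr,
            "ait": self.ait,
            "cir": self.cir,
            "n_fish": self.n_fish,
            "n_frames": self.n_frames,
            "n_interruptions": self.n_interruptions,
            "n_occlusion_events": self.n_occlusion_events,
        }

    def table(self) -> str:
        rows = [
            ("miss ratio", f"{self.miss_ratio:.4f}"),
            ("error ratio", f"{self.error_ratio:.4f}"),
            ("CTR", f"{self.ctr:.4f}"),
            ("AIT (/fish/100 frames)", f"{self.ait:.4f}"),
            ("CIR", "n/a" if self.cir is None else f"{self.cir:.4f}"),
        ]
        w = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{w}}  {val}" for name, val in rows)


def _truth_frames(truth: pd.DataFrame):
    """Ground truth as {frame: {fish_id: nose (2,)}}."""
    out: dict[int, dict[int, np.ndarray]] = {}
    for row in truth.itertuples(index=False):
        out.setdefault(int(row.frame), {})[int(row.id)] = np.array(
            [row.nose_x, row.nose_y]
        )
    return out


def _result_frames(trajectories: list[Tracklet]):
    """{frame: {traj_id: pose}} over all non-coasted poses."""
    out: dict[int, dict[int, object]] = {}
    for t in trajectories:
        for p in t.poses:
            if getattr(p, "coasted", False):
                continue
            out.setdefault(int(p.frame), {})[t.id] = p
    return out


def match_to_truth(
    trajectories: list[Tracklet],
    truth: pd.DataFrame,
    tol: float = 10.0,
) -> pd.DataFrame:
    """Per fish-frame correctness labels.

    For each frame, result poses are matched to annotated fish greedily
    by nose distance under ``tol``.  A matched pair is correct (the cover
    check already held or the pose would have been vetoed); an unmatched
    truth record is a miss; an unmatched result is an error.  Returns one
    row per fish-frame event with columns frame, true_id, result_id,
    status in {correct, miss, error}.
    """
    tf = _truth_frames(truth)
    rf = _result_frames(trajectories)
    records = []
    for frame in sorted(tf):
        truths = tf[frame]
        results = rf.get(frame, {})
        pairs = []
        for tid, nose in truths.items():
            for rid, pose in results.items():
                d = float(np.linalg.norm(pose.N - nose))
                if d < tol:
                    pairs.append((d, tid, rid))
        pairs.sort()
        used_t, used_r = set(), set()
        for d, tid, rid in pairs:
            if tid in used_t or rid in used_r:
                continue
            used_t.add(tid)
            used_r.add(rid)
            records.append((frame, tid, rid, "correct"))
        for tid in truths:
            if tid not in used_t:
                records.append((frame, tid, -1, "miss"))
        for rid in results:
            if rid not in used_r:
                records.append((frame, -1, rid, "error"))
    return pd.DataFrame(records, columns=["frame", "true_id", "result_id", "status"])


def _fish_frame_denominator(labels: pd.DataFrame) -> tuple[int, int]:
    truth_rows = labels[labels.status.isin(["correct", "miss"])]
    n_frames = labels.frame.nunique()
    n_fish = truth_rows.true_id.nunique()
    return n_fish, n_frames


def miss_error_ratio(labels: pd.DataFrame) -> tuple[float, float]:
    """Undetected and wrongly detected fish-frames over fish x frames."""
    n_fish, n_frames = _fish_frame_denominator(labels)
    denom = n_fish * n_frames
    if denom == 0:
        raise ValueError("no fish-frames to evaluate")
    miss = int((labels.status == "miss").sum()) / denom
    err = int((labels.status == "error").sum()) / denom
    return miss, err


def ctr(labels: pd.DataFrame) -> float:
    """Correct tracking ratio: correct fish-frames over fish x frames."""
    n_fish, n_frames = _fish_frame_denominator(labels)
    denom = n_fish * n_frames
    if denom == 0:
        raise ValueError("no fish-frames to evaluate")
    return int((labels.status == "correct").sum()) / denom


def _interruptions_per_fish(labels: pd.DataFrame) -> dict[int, int]:
    """Count trajectory breaks per true fish.

    An interruption is a handoff: the identity covering the fish changes
    between two of its matched frames, or its coverage stops for good
    while the fish is still visible.  A missed detection bridged by the
    same continuing trajectory is not an interruption.
    """
    out: dict[int, int] = {}
    truth_rows = labels[labels.status.isin(["correct", "miss"])]
    for tid, grp in truth_rows.groupby("true_id"):
        grp = grp.sort_values("frame")
        matched = [
            (int(r.frame), int(r.result_id))
            for r in grp.itertuples(index=False)
            if r.status == "correct"
        ]
        breaks = 0
        prev_rid = None
        for _frame, rid in matched:
            if prev_rid is not None and rid != prev_rid:
                breaks += 1
            prev_rid = rid
        if matched and matched[-1][0] < int(grp.frame.max()):
            breaks += 1  # coverage ended while the fish was still visible
        out[int(tid)] = breaks
    return out


def ait(labels: pd.DataFrame) -> tuple[float, int]:
    """Average interruption times per fish per 100 frames, plus the raw count."""
    n_fish, n_frames = _fish_frame_denominator(labels)
    if n_fish * n_frames == 0:
        raise ValueError("no fish-frames to evaluate")
    per_fish = _interruptions_per_fish(labels)
    total = sum(per_fish.values())
    return total / (n_fish * n_frames / 100.0), total


def cir(
    occlusion_events: pd.DataFrame,
    labels: pd.DataFrame,
) -> tuple[float | None, int]:
    """Fraction of occlusion events after which every involved fish keeps
    the identity it carried before the event.

    For each event (start_frame, end_frame, ids) the result id matched to
    each involved fish in the last correct frame before the event is
    compared with the one in the first correct frame after; the event
    counts as correct only if every involved fish resumes with its
    pre-event identity.  Events with no scoreable frame on one side
    (e.g. an occlusion running into the end of the clip) have an
    unobservable outcome and are excluded from the denominator.  Returns
    (ratio or None when no scoreable events, scoreable event count).
    """
    if len(occlusion_events) == 0:
        return None, 0
    correct_rows = labels[labels.status == "correct"]
    ok = 0
    n_scoreable = 0
    for ev in occlusion_events.itertuples(index=False):
        ids = [int(s) for s in str(ev.ids).split("|")]
        all_ok = True
        observable = True
        for tid in ids:
            fr = correct_rows[correct_rows.true_id == tid]
            before = fr[fr.frame < int(ev.start_frame)]
            after = fr[fr.frame > int(ev.end_frame)]
            if before.empty or after.empty:
                observable = False
                break
            if int(before.iloc[-1].result_id) != int(after.iloc[0].result_id):
                all_ok = False
        if not observable:
            continue
        n_scoreable += 1
        ok += all_ok
    if n_scoreable == 0:
        return None, 0
    return ok / n_scoreable, n_scoreable


def evaluate(
    trajectories: list[Tracklet],
    truth: pd.DataFrame,
    occlusion_events: pd.DataFrame | None = None,
    tol: float = 10.0,
) -> MetricsReport:
    """Full metrics report for a tracking run against ground truth."""
    labels = match_to_truth(trajectories, truth, tol=tol)
    n_fish, n_frames = _fish_frame_denominator(labels)
    miss, err = miss_error_ratio(labels)
    a, n_int = ait(labels)
    if occlusion_events is None or len(occlusion_events) == 0:
        c, n_ev = None, 0
    else:
        c, n_ev = cir(occlusion_events, labels)
    return MetricsReport(
        miss_ratio=miss,
        error_ratio=err,
        ctr=ctr(labels),
        ait=a,
        cir=c,
        n_fish=n_fish,
        n_frames=n_frames,
        n_interruptions=n_int,
        n_occlusion_events=n_ev,
    )
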