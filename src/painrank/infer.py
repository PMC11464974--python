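"""Sequential pain-intensity inference, pain-group mapping and evaluation.

A trained ranker turns a facial image sequence into a sequential network
pain intensity (SNPI) trace: the Euclidean distance between each frame's
embedding and a neutral reference frame's embedding (default: the first
frame of the sequence; a consecutive-frame delta variant is available).
SNPI is reported in raw embedding-distance units.

Traces map to five ordered pain groups PG1..PG5 through four ascending
thresholds (half-open intervals, ties going up), and group sequences
run-length encode into an expression timeline with a fixed transition
interval (default 0.5 s) inserted at every group change — the schedule a
pain-expression avatar would animate (neutral -> expression -> neutral).

Evaluation follows the corpus-style protocol: Pearson correlation (PCC)
between SNPI and the PSPI labels, mean absolute error (MAE) after a
rank-preserving assignment of SNPI onto the label distribution, and a
confusion matrix over the four pain states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .pspi import PainGroup, PainState, bin_pain_state
from .ranker import load_frames

__all__ = [
    "IntensityTrace", "GroupThresholds", "TimelineSegment", "ExpressionTimeline",
    "EvalReport", "snpi_trace", "trace_for_sequence", "map_to_group",
    "calibrate_thresholds", "build_timeline", "pcc", "mae",
    "rank_match", "evaluate_predictions", "evaluate",
]


@dataclass
class IntensityTrace:
    """Per-frame SNPI values for one (subject, level) sequence."""

    subject_id: str
    level: int
    snpi: np.ndarray
    reference_frame_index: int

    def to_json(self) -> str:
        return json.dumps({"subject": self.subject_id, "level": self.level,
                           "reference_frame_index": self.reference_frame_index,
                           "snpi": [float(v) for v in self.snpi]})


@dataclass(frozen=True)
class GroupThresholds:
    """Four strictly ascending cut points on the SNPI scale."""

    cuts: tuple

    def __post_init__(self):
        c = tuple(float(v) for v in self.cuts)
        if len(c) != 4 or any(a >= b for a, b in zip(c, c[1:])):
            raise ValueError(f"need four strictly ascending thresholds, got {self.cuts}")
        object.__setattr__(self, "cuts", c)


@dataclass(frozen=True)
class TimelineSegment:
    group: PainGroup
    onset_s: float
    duration_s: float


@dataclass
class ExpressionTimeline:
    """Contiguous expression segments plus the transitions between them."""

    segments: list
    transitions: list            # (from_group, to_group, onset_s)
    transition_interval_s: float = 0.5

    @property
    def total_duration_s(self) -> float:
        last = self.segments[-1]
        return last.onset_s + last.duration_s

    def to_json(self) -> str:
        return json.dumps({
            "transition_interval_s": self.transition_interval_s,
            "segments": [{"group": s.group.name, "onset_s": s.onset_s,
                          "duration_s": s.duration_s} for s in self.segments],
            "transitions": [{"from": a.name, "to": b.name, "onset_s": t}
                            for a, b, t in self.transitions],
        })


@dataclass
class EvalReport:
    pcc: float
    mae: float
    confusion: pd.DataFrame      # rows: true state, cols: predicted state
    model_id: str = ""

    def to_json(self) -> str:
        return json.dumps({"pcc": self.pcc, "mae": self.mae, "model_id": self.model_id,
                           "confusion": self.confusion.to_dict()})


# ---------------------------------------------------------------- traces

def snpi_trace(model: nn.RankerModel, frames: np.ndarray,
               reference: int | str = 0) -> np.ndarray:
    """SNPI values for an ordered frame stack (n, H, W).

    ``reference`` is a frame position (default 0, the sequence's first,
    presumed-neutral frame) or ``"previous"`` for the consecutive-frame delta
    variant (first value 0).  Causal: the value at t depends only on frames
    up to t and the reference.
    """
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0:
        raise ValueError("empty sequence")
    emb = nn.embed(model, frames)
    if reference == "previous":
        d = np.linalg.norm(np.diff(emb, axis=0), axis=1)
        return np.concatenate([[0.0], d])
    ref = int(reference)
    return np.linalg.norm(emb - emb[ref], axis=1)


def trace_for_sequence(model: nn.RankerModel, seq: pd.DataFrame,
                       frames: dict[int, np.ndarray],
                       reference: int | str = 0) -> IntensityTrace:
    """Build an IntensityTrace for one (subject, level) manifest slice."""
    seq = seq.sort_values("frame_index")
    stack = np.stack([frames[i] for i in seq.index])
    ref_pos = 0 if reference == "previous" else int(reference)
    return IntensityTrace(
        subject_id=str(seq["subject_id"].iloc[0]), level=int(seq["level"].iloc[0]),
        snpi=snpi_trace(model, stack, reference),
        reference_frame_index=int(seq["frame_index"].iloc[ref_pos]),
    )


# ---------------------------------------------------------------- groups

def map_to_group(snpi: np.ndarray | IntensityTrace,
                 thresholds: GroupThresholds) -> list[PainGroup]:
    """Threshold SNPI into PG1..PG5 (half-open intervals, ties go up)."""
    values = snpi.snpi if isinstance(snpi, IntensityTrace) else np.asarray(snpi, dtype=float)
    idx = np.searchsorted(thresholds.cuts, np.atleast_1d(values), side="right")
    return [PainGroup(int(i) + 1) for i in idx]


def calibrate_thresholds(traces, method: str = "quantile") -> GroupThresholds:
    """Cut points from pooled calibration traces (default: 20/40/60/80th pct)."""
    if method != "quantile":
        raise ValueError(f"unknown calibration method {method!r}")
    arrs = [t.snpi if isinstance(t, IntensityTrace) else np.asarray(t, dtype=float)
            for t in traces]
    if not arrs:
        raise ValueError("no calibration traces")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        raise ValueError("all SNPI values equal; quantile thresholds are degenerate")
    cuts = np.percentile(pooled, [20, 40, 60, 80])
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("degenerate quantiles; pooled SNPI lacks spread for 5 groups")
    return GroupThresholds(tuple(cuts))


def build_timeline(groups: list[PainGroup], frame_rate: float,
                   transition_interval_s: float = 0.5) -> ExpressionTimeline:
    """Run-length encode a per-frame group sequence into an animation timeline.

    Consecutive equal groups merge into one segment of run_length/frame_rate
    seconds; each group change inserts a neutral transition of
    ``transition_interval_s`` seconds, shifting subsequent onsets.
    """
    if not groups:
        raise ValueError("empty group sequence")
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be positive, got {frame_rate}")
    runs: list[tuple[PainGroup, int]] = []
    for g in groups:
        if runs and runs[-1][0] == g:
            runs[-1] = (g, runs[-1][1] + 1)
        else:
            runs.append((g, 1))
    segments, transitions = [], []
    t = 0.0
    for k, (g, n) in enumerate(runs):
        if k:
            transitions.append((runs[k - 1][0], g, t))
            t += transition_interval_s
        dur = n / frame_rate
        segments.append(TimelineSegment(g, t, dur))
        t += dur
    return ExpressionTimeline(segments, transitions, transition_interval_s)


# ---------------------------------------------------------------- metrics

def pcc(a, b) -> float:
    """Pearson correlation coefficient; requires nonconstant inputs."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("pcc needs two equal-length vectors of size >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("pcc undefined for a zero-variance input")
    return float(stats.pearsonr(a, b).statistic)


def mae(a, b) -> float:
    """Mean absolute error."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("mae needs two equal-length nonempty vectors")
    return float(np.mean(np.abs(a - b)))


# ---------------------------------------------------------------- evaluation

def rank_match(predictions: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rank-preserving assignment of predictions onto the label distribution.

    The frame with the k-th smallest prediction receives the k-th smallest
    label value, so the output is a monotone re-scaling of the predictions
    onto the empirical label scale.  Feeding the labels back reproduces them
    exactly.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    order = np.argsort(predictions, kind="stable")
    out = np.empty_like(labels)
    out[order] = np.sort(labels)
    return out


def evaluate_predictions(snpi: np.ndarray, labels: np.ndarray,
                         model_id: str = "") -> EvalReport:
    """PCC / MAE / pain-state confusion for per-frame intensities vs PSPI labels."""
    snpi = np.asarray(snpi, dtype=float)
    labels = np.asarray(labels, dtype=float)
    r = pcc(snpi, labels)
    pred_pspi = rank_match(snpi, labels)
    err = mae(pred_pspi, labels)
    names = [s.value for s in PainState]
    conf = pd.DataFrame(0, index=names, columns=names)
    for p, y in zip(pred_pspi, labels):
        conf.loc[bin_pain_state(int(round(y))).value,
                 bin_pain_state(int(round(p))).value] += 1
    return EvalReport(pcc=r, mae=err, confusion=conf, model_id=model_id)


def evaluate(model: nn.RankerModel, manifest: pd.DataFrame, root: str | Path = ".",
             frames: dict[int, np.ndarray] | None = None,
             reference: int | str = 0) -> EvalReport:
    """Evaluate a ranker on a labeled manifest, sequence by sequence.

    SNPI is computed per (subject, level) sequence against its reference
    frame and compared to the manifest's PSPI labels.
    """
    if "pspi" not in manifest or manifest["pspi"].isna().any():
        raise ValueError("evaluation requires PSPI labels for every frame")
    if frames is None:
        frames = load_frames(manifest, root)
    snpi_all, labels = [], []
    for _, seq in manifest.groupby(["subject_id", "level"], sort=True):
        seq = seq.sort_values("frame_index")
        tr = trace_for_sequence(model, seq, frames, reference)
        snpi_all.append(tr.snpi)
        labels.append(seq["pspi"].to_numpy(dtype=float))
    return evaluate_predictions(np.concatenate(snpi_all), np.concatenate(labels),
                                model_id=str(model.meta.get("config", {}).get("loss_kind", "")))
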