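"""Direction tuning from drifting-grating responses, per imaging modality.

Stimuli are full-field gratings drifting in one of 12 directions (30-degree
steps), each presented for 2 s with 1 s of gray screen between
presentations, 8 repeats per direction in random order.  For each ROI the
neuropil-subtracted fluorescence trace is converted to dF/F, trial
responses are averaged per direction, and the preferred direction is the
one evoking the largest peak of the trial-averaged dF/F.  Cross-modality
agreement between paired two-photon and three-photon recordings is
summarized by the percentage of ROIs with identical preferred directions
(chance: 1/12) and by the Pearson correlation of the traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "DIRECTIONS_DEG",
    "CHANCE_MATCH_PERCENT",
    "StimulusSchedule",
    "DirectionTuningResult",
    "neuropil_subtract",
    "delta_f_over_f",
    "trial_average_responses",
    "preferred_direction",
    "match_percentage",
    "trace_correlation",
    "extract_traces",
    "compute_tuning",
]

#: The 12 drift directions, degrees.
DIRECTIONS_DEG = np.arange(0, 360, 30)

#: Chance level for identical preferred directions, percent (1/12).
CHANCE_MATCH_PERCENT = 100.0 / len(DIRECTIONS_DEG)


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered grating presentations: direction, onset (s), duration (s).

    A valid schedule has 12 distinct directions with an equal number of
    non-overlapping presentations each (8 in the native design, separated
    by 1 s of gray screen).
    """

    table: pd.DataFrame
    gray_s: float = 1.0

    def __post_init__(self) -> None:
        t = self.table
        required = {"direction_deg", "onset_s", "duration_s"}
        if not required.issubset(t.columns):
            raise ValueError(f"schedule needs columns {sorted(required)}")
        dirs = np.sort(t["direction_deg"].unique())
        if not np.array_equal(dirs, DIRECTIONS_DEG):
            raise ValueError("schedule must contain exactly the 12 standard directions")
        counts = t["direction_deg"].value_counts()
        if counts.nunique() != 1:
            raise ValueError("each direction needs the same number of presentations")
        onsets = t["onset_s"].to_numpy()
        ends = onsets + t["duration_s"].to_numpy()
        order = np.argsort(onsets)
        if np.any(onsets[order][1:] < ends[order][:-1]):
            raise ValueError("presentations overlap")
        object.__setattr__(
            self, "table", t.sort_values("onset_s").reset_index(drop=True)
        )

    @property
    def repeats(self) -> int:
        return int(self.table["direction_deg"].value_counts().iloc[0])

    @property
    def total_s(self) -> float:
        last = self.table.iloc[-1]
        return float(last["onset_s"] + last["duration_s"] + self.gray_s)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, gray_s: float = 1.0) -> "StimulusSchedule":
        return cls(table=pd.read_csv(path), gray_s=gray_s)


@dataclass(frozen=True)
class DirectionTuningResult:
    """Per-ROI direction tuning for one modality.

    ``responses`` is an ``(n_roi, 12)`` frame of mean peak dF/F per
    direction; ``preferred_deg`` the argmax direction per ROI; ``excluded``
    flags ROIs whose baseline was nonpositive after neuropil subtraction
    (dF/F undefined there, preferred direction reported as -1).
    """

    responses: pd.DataFrame
    preferred_deg: np.ndarray
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_rois(self) -> int:
        return len(self.responses)


def neuropil_subtract(f_soma, f_np, r: float = 1.0) -> np.ndarray:
    """Subtract the surrounding-neuropil trace from a soma trace.

    ``F = F_soma - r * F_np`` elementwise, with subtraction coefficient
    ``r = 1`` by default.
    """
    f_soma = np.asarray(f_soma, dtype=float)
    f_np = np.asarray(f_np, dtype=float)
    if f_soma.shape != f_np.shape:
        raise ValueError("soma and neuropil traces must have equal length")
    return f_soma - r * f_np


def _trial_windows(schedule: StimulusSchedule, frame_rate: float, n_frames: int):
    """Per-presentation (pre-start, onset, offset, direction) frame indices."""
    pre = int(round(schedule.gray_s * frame_rate))
    out = []
    for _, row in schedule.table.iterrows():
        on = int(round(row["onset_s"] * frame_rate))
        off = int(round((row["onset_s"] + row["duration_s"]) * frame_rate))
        if off > n_frames:
            raise ValueError("trace does not cover the stimulus schedule")
        out.append((max(on - pre, 0), on, off, row["direction_deg"]))
    return pre, out


def delta_f_over_f(
    trace,
    schedule: Optional[StimulusSchedule] = None,
    frame_rate: Optional[float] = None,
    method: str = "pre_stimulus",
    percentile: float = 10.0,
) -> np.ndarray:
    """Convert a raw trace to dF/F = (F - F0) / F0.

    ``method="pre_stimulus"`` (default) uses, for each presentation, the
    mean over the gray period immediately preceding it as a per-trial F0
    (piecewise-constant over the recording; stimulus-locked and robust to
    slow drift); ``method="percentile"`` uses a single global
    low-percentile F0.  A nonpositive F0 leaves dF/F undefined and raises
    ``ValueError`` (callers flag and exclude such ROIs).
    """
    f = np.asarray(trace, dtype=float)
    if method == "percentile":
        f0 = np.percentile(f, percentile)
        if f0 <= 0:
            raise ValueError("nonpositive baseline; dF/F undefined")
        return (f - f0) / f0
    if method != "pre_stimulus":
        raise ValueError("method must be 'pre_stimulus' or 'percentile'")
    if schedule is None or frame_rate is None:
        raise ValueError("pre_stimulus baseline needs a schedule and frame rate")
    pre, windows = _trial_windows(schedule, frame_rate, len(f))
    onsets = np.array([on for _, on, _, _ in windows])
    baselines = np.array([f[lo:on].mean() if on > lo else f[0] for lo, on, _, _ in windows])
    if np.any(baselines <= 0):
        raise ValueError("nonpositive baseline; dF/F undefined")
    # zero-order hold aligned to the pre-stimulus windows: every frame from
    # the start of a trial's baseline window until the next trial's window
    # uses that trial's F0 (so dF/F is exactly zero-mean over each window)
    starts = np.array([lo for lo, _, _, _ in windows])
    idx = np.clip(np.searchsorted(starts, np.arange(len(f)), side="right") - 1, 0, None)
    f0 = baselines[idx]
    return (f - f0) / f0


def trial_average_responses(
    trace,
    schedule: StimulusSchedule,
    frame_rate: float,
) -> pd.Series:
    """Mean peak response per direction from a dF/F trace.

    For each direction the trials are aligned at stimulus onset (with the
    preceding gray period as baseline window), averaged across repeats, and
    the peak of the trial-averaged trace within the stimulus window is
    taken relative to the mean pre-stimulus baseline ("peak of mean").
    Linear in the trace.  Returns a series indexed by direction (deg).
    """
    f = np.asarray(trace, dtype=float)
    pre, windows = _trial_windows(schedule, frame_rate, len(f))
    n_on = min(off - on for _, on, off, _ in windows)
    out = {}
    for direction in DIRECTIONS_DEG:
        segs, bases = [], []
        for lo, on, off, d in windows:
            if d != direction:
                continue
            segs.append(f[on : on + n_on])
            bases.append(f[lo:on].mean() if on > lo else 0.0)
        if not segs:
            raise ValueError(f"no presentations of direction {direction}")
        mean_seg = np.mean(segs, axis=0)
        out[int(direction)] = float(mean_seg.max() - np.mean(bases))
    return pd.Series(out, name="mean_peak_dff")


def preferred_direction(responses) -> int:
    """Direction (deg) evoking the largest mean peak response.

    Ties are broken toward the smallest angle (argmax returns the first of
    equal maxima over the ascending direction grid).
    """
    if isinstance(responses, pd.Series):
        responses = responses.reindex(sorted(responses.index)).to_numpy()
    r = np.asarray(responses, dtype=float)
    if r.shape != DIRECTIONS_DEG.shape:
        raise ValueError("need one response per direction (12 values)")
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    n_max = int((r == r.max()).sum())
    if n_max > 1:
        logger.info("tie among %d directions; smallest angle reported", n_max)
    return int(DIRECTIONS_DEG[int(np.argmax(r))])


def match_percentage(prefs_a, prefs_b):
    """Percentage of ROIs with identical preferred directions, plus chance.

    Returns ``(percent, chance_percent)`` where chance is ``100/12``
    (about 8.3%), the expected match rate for independent uniform
    preferences over the 12 directions.
    """
    a = np.asarray(prefs_a)
    b = np.asarray(prefs_b)
    if a.shape != b.shape:
        raise ValueError("preference arrays must have the same length")
    if a.size == 0:
        raise ValueError("empty ROI set")
    return 100.0 * float(np.mean(a == b)), CHANCE_MATCH_PERCENT


def trace_correlation(trace_a, trace_b) -> float:
    """Pearson correlation between two (neuropil-subtracted) traces."""
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-D and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for zero-variance trace")
    return float(pearsonr(a, b).statistic)


def extract_traces(frames: np.ndarray, labels: np.ndarray, annulus_px: int = 6):
    """Mean soma and neuropil traces per ROI from a movie and a label mask.

    ``labels`` is an integer image (0 = background, k = ROI k).  The soma
    trace averages the ROI pixels per frame; the neuropil trace averages an
    annulus obtained by dilating the ROI by ``annulus_px`` pixels and
    excluding every ROI.  Segmentation itself is upstream of this package.
    Returns ``(soma, neuropil)`` arrays of shape ``(n_roi, T)`` in label
    order.
    """
    frames = np.asarray(frames, dtype=float)
    labels = np.asarray(labels)
    if frames.ndim != 3 or labels.shape != frames.shape[1:]:
        raise ValueError("labels must match the movie geometry")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("label image contains no ROIs")
    flat = frames.reshape(frames.shape[0], -1)
    any_roi = labels > 0
    soma, neuropil = [], []
    for k in ids:
        mask = labels == k
        ring = ndimage.binary_dilation(mask, iterations=annulus_px) & ~any_roi
        if not ring.any():
            ring = ~any_roi  # fully crowded field: fall back to global neuropil
        soma.append(flat[:, mask.ravel()].mean(axis=1))
        neuropil.append(flat[:, ring.ravel()].mean(axis=1))
    return np.array(soma), np.array(neuropil)


def compute_tuning(
    soma: np.ndarray,
    neuropil: Optional[np.ndarray],
    schedule: StimulusSchedule,
    frame_rate: float,
    r: float = 1.0,
    baseline: str = "pre_stimulus",
) -> DirectionTuningResult:
    """Direction tuning for a bank of ROI traces of one modality.

    Applies neuropil subtraction (if a neuropil bank is given), per-trial
    dF/F, trial averaging and preferred-direction identification.  ROIs
    whose baseline is nonpositive after subtraction are flagged excluded.
    """
    soma = np.atleast_2d(np.asarray(soma, dtype=float))
    traces = (
        neuropil_subtract(soma, np.atleast_2d(np.asarray(neuropil, dtype=float)), r)
        if neuropil is not None
        else soma
    )
    rows, prefs, excluded = [], [], []
    for tr in traces:
        try:
            dff = delta_f_over_f(tr, schedule, frame_rate, method=baseline)
        except ValueError:
            rows.append(pd.Series(np.nan, index=[int(d) for d in DIRECTIONS_DEG]))
            prefs.append(-1)
            excluded.append(True)
            continue
        resp = trial_average_responses(dff, schedule, frame_rate)
        rows.append(resp)
        prefs.append(preferred_direction(resp))
        excluded.append(False)
    n_exc = int(np.sum(excluded))
    if n_exc:
        logger.warning("%d ROIs excluded (nonpositive dF/F baseline)", n_exc)
    return DirectionTuningResult(
        responses=pd.DataFrame(rows).reset_index(drop=True),
        preferred_deg=np.array(prefs),
        excluded=np.array(excluded),
    )
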