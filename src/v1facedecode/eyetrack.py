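"""Gaze preprocessing and saccade screening.

Traces are linearly detrended per run and re-centred on the run's median
gaze position; a saccade is a maximal contiguous stretch of samples whose
radius (Euclidean distance from fixation) exceeds 1.5 degrees of visual
angle for at least 150 ms.  Mean horizontal and vertical fixation positions
are compared across tasks to screen for systematic gaze differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthkit import GazeTrace

__all__ = ["SaccadeEvent", "detect_saccades", "compare_fixation", "detrend_gaze"]


@dataclass(frozen=True)
class SaccadeEvent:
    """One above-threshold gaze excursion (sample indices, peak radius)."""

    onset_sample: int
    offset_sample: int
    peak_radius: float

    def __post_init__(self) -> None:
        if self.offset_sample <= self.onset_sample:
            raise ValueError("offset must follow onset")


def detrend_gaze(trace: GazeTrace) -> GazeTrace:
    """Remove per-axis linear trends and re-centre on the median position."""
    n = len(trace.samples)
    t = np.arange(n, dtype=float)
    out = trace.samples.copy()
    for axis in range(2):
        slope, intercept = np.polyfit(t, out[:, axis], 1)
        out[:, axis] -= slope * t + intercept
        out[:, axis] -= np.median(out[:, axis])
    return GazeTrace(samples=out, rate=trace.rate)


def detect_saccades(
    trace: GazeTrace,
    radius_threshold: float = 1.5,
    min_duration_s: float = 0.150,
    detrend: bool = True,
) -> list[SaccadeEvent]:
    """Classify above-radius excursions of sufficient duration as saccades.

    The duration rule is inclusive: a stretch lasting exactly
    ``min_duration_s`` counts.  The detector is rotation-invariant (it
    thresholds the radius) and, after detrending, translation-equivariant.
    """
    min_samples = int(np.ceil(min_duration_s * trace.rate - 1e-9))
    if min_samples < 2:
        raise ValueError("min_duration must span at least 2 samples at this rate")
    work = detrend_gaze(trace) if detrend else trace
    radius = np.hypot(work.x, work.y)
    above = radius > radius_threshold
    events: list[SaccadeEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_samples:
            events.append(
                SaccadeEvent(
                    onset_sample=int(start),
                    offset_sample=int(stop),
                    peak_radius=float(radius[start:stop].max()),
                )
            )
    return events


def events_to_frame(events: list[SaccadeEvent], rate: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.onset_sample / rate for e in events],
            "offset_s": [e.offset_sample / rate for e in events],
            "peak_radius_deg": [e.peak_radius for e in events],
        }
    )


def compare_fixation(traces_task_a, traces_task_b) -> dict:
    """Compare mean horizontal/vertical fixation position across tasks.

    Per-run mean gaze positions enter a paired t-test per axis (two-sided);
    with unpaired run counts a two-sample test is used instead, with a
    warning.  Returns {"horizontal": (t, p), "vertical": (t, p)}.
    """
    if len(traces_task_a) < 2 or len(traces_task_b) < 2:
        raise ValueError("need at least two traces per task")
    means_a = np.array([tr.samples.mean(axis=0) for tr in traces_task_a])
    means_b = np.array([tr.samples.mean(axis=0) for tr in traces_task_b])
    out = {}
    for axis, name in enumerate(("horizontal", "vertical")):
        a, b = means_a[:, axis], means_b[:, axis]
        if a.size == b.size:
            if np.allclose(a, b):
                out[name] = (0.0, 1.0)
                continue
            t, p = sps.ttest_rel(a, b)
        else:
            warnings.warn("unpaired run counts: falling back to two-sample t-test", stacklevel=2)
            t, p = sps.ttest_ind(a, b)
        out[name] = (float(t), float(p))
    return out
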