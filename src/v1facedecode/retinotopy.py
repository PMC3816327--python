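"""Phase-encoded polar-angle mapping by cross-correlation.

A reference response — the predicted haemodynamic time course for the first
1/8th of a stimulation cycle (a 4-of-32-volume boxcar convolved with the
HRF) — is circularly shifted in steps of 4 volumes (45 degrees of polar
angle).  Each voxel's preferred angle is the shift maximizing the Pearson
correlation with its time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthkit import BoldRun, _circular_convolve

__all__ = ["PhaseMap", "build_phase_reference", "phase_map"]


@dataclass
class PhaseMap:
    """Per-voxel best shift, correlation and recovered polar angle."""

    best_shift: np.ndarray
    best_correlation: np.ndarray
    angle: np.ndarray
    flagged: np.ndarray
    n_shifts: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel": np.arange(self.best_shift.size),
                "shift": self.best_shift,
                "r": self.best_correlation,
                "angle": self.angle,
                "flagged": self.flagged,
            }
        )


def build_phase_reference(
    cycle_volumes: int = 32,
    active_volumes: int = 4,
    n_cycles: int = 1,
    hrf=None,
) -> np.ndarray:
    """Predicted response for the first ``active_volumes`` of each cycle.

    The boxcar is circularly convolved with the HRF over one cycle and tiled,
    so the reference is exactly periodic with period ``cycle_volumes``.  With
    a delta kernel the raw boxcar is returned.
    """
    if cycle_volumes % active_volumes:
        raise ValueError("cycle_volumes must be divisible by active_volumes")
    kernel = np.asarray(getattr(hrf, "samples", hrf), dtype=float) if hrf is not None else np.array([1.0])
    base = np.zeros(cycle_volumes)
    base[:active_volumes] = 1.0
    base = _circular_convolve(base, kernel)
    return np.tile(base, n_cycles)


def phase_map(
    run,
    reference: np.ndarray,
    shift_step_volumes: int = 4,
    cycle_volumes: int = 32,
    correlation_threshold: float = 0.25,
) -> PhaseMap:
    """Cross-correlate every voxel with circularly shifted references.

    For shift index ``k`` the reference is delayed by ``k * shift_step``
    volumes; the recovered angle is ``best_shift * 360 / n_shifts``.
    Zero-variance voxels get r = 0, and voxels whose best correlation falls
    below ``correlation_threshold`` are flagged as unmapped.
    """
    data = np.asarray(getattr(run, "data", run), dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    reference = np.asarray(reference, dtype=float)
    if data.shape[1] != reference.size:
        raise ValueError("run length must equal reference length")
    if cycle_volumes % shift_step_volumes:
        raise ValueError("cycle_volumes must be divisible by shift_step_volumes")
    n_shifts = cycle_volumes // shift_step_volumes

    refs = np.stack([np.roll(reference, k * shift_step_volumes) for k in range(n_shifts)])
    refs_c = refs - refs.mean(axis=1, keepdims=True)
    refs_n = refs_c / np.linalg.norm(refs_c, axis=1, keepdims=True)

    data_c = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(data_c, axis=1)
    zero_var = norms == 0
    safe = np.where(zero_var, 1.0, norms)
    corr = (data_c / safe[:, None]) @ refs_n.T  # voxels x shifts
    corr[zero_var] = 0.0

    best_shift = np.argmax(corr, axis=1)
    best_r = corr[np.arange(data.shape[0]), best_shift]
    flagged = zero_var | (best_r < correlation_threshold)
    return PhaseMap(
        best_shift=best_shift,
        best_correlation=best_r,
        angle=best_shift * (360.0 / n_shifts),
        flagged=flagged,
        n_shifts=n_shifts,
    )
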