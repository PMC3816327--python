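"""Per-run signal conditioning: linear-trend removal and temporal
high-pass filtering (default cutoff 0.006 Hz).

The high-pass is implemented as regression against a drift basis of
half-cycle cosine (DCT-II) components and their quadrature sine partners at
every frequency below the cutoff, orthonormalized.  Including the sine
partners makes the removal phase-free: a sub-cutoff sinusoid of ANY phase is
captured, which a cosine-only basis cannot guarantee.  Both operators are
exactly linear and mean-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthkit import BoldRun

__all__ = ["FilterSpec", "detrend_linear", "highpass", "preprocess_run", "dct_drift_basis"]


@dataclass(frozen=True)
class FilterSpec:
    highpass_hz: float = 0.006
    detrend: bool = True

    def __post_init__(self) -> None:
        if self.highpass_hz <= 0:
            raise ValueError("high-pass cutoff must be positive")


def detrend_linear(run: BoldRun) -> BoldRun:
    """Remove each voxel's best-fit line, re-adding the voxel mean.

    Constant series pass through unchanged; a pure ramp collapses to its mean.
    Idempotent up to numerical precision.
    """
    if run.n_volumes < 3:
        raise ValueError("linear detrending needs at least 3 volumes")
    t = np.arange(run.n_volumes, dtype=float)
    t_c = t - t.mean()
    slope = (run.data @ t_c) / (t_c @ t_c)
    detrended = run.data - slope[:, None] * t_c[None, :]
    return BoldRun(data=detrended, tr=run.tr, run_id=run.run_id)


def dct_drift_basis(n_volumes: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Orthonormal drift basis: DCT-II cosines at frequencies
    ``k / (2 N TR) < cutoff`` plus their quadrature sine partners.

    Returns an (n_volumes, 2k) matrix with orthonormal columns; may have 0
    columns for short runs.
    """
    n = n_volumes
    ks = []
    k = 1
    while k / (2.0 * n * tr) < cutoff_hz:
        ks.append(k)
        k += 1
    if not ks:
        return np.zeros((n, 0))
    i = np.arange(n)
    cols = []
    for k in ks:
        arg = np.pi * k * (2 * i + 1) / (2.0 * n)
        cols.append(np.cos(arg))
        cols.append(np.sin(arg))
    B = np.column_stack(cols)
    B = B - B.mean(axis=0, keepdims=True)  # keep the basis orthogonal to the mean
    q, r = np.linalg.qr(B)
    keep = np.abs(np.diag(r)) > 1e-10 * np.abs(np.diag(r)).max()
    return q[:, keep]


def highpass(run: BoldRun, spec: FilterSpec | float = FilterSpec()) -> BoldRun:
    """Project out drift components below the cutoff (mean preserved).

    Components well above the cutoff are essentially untouched (gain within
    1% of unity at five times the cutoff and beyond).
    """
    if not isinstance(spec, FilterSpec):
        spec = FilterSpec(highpass_hz=float(spec))
    nyquist = 0.5 / run.tr
    if spec.highpass_hz >= nyquist:
        raise ValueError("high-pass cutoff must be below the Nyquist frequency")
    basis = dct_drift_basis(run.n_volumes, run.tr, spec.highpass_hz)
    if basis.shape[1] == 0:
        return BoldRun(data=run.data.copy(), tr=run.tr, run_id=run.run_id)
    coef = run.data @ basis  # voxels x k (basis is orthonormal)
    filtered = run.data - coef @ basis.T
    return BoldRun(data=filtered, tr=run.tr, run_id=run.run_id)


def preprocess_run(run: BoldRun, spec: FilterSpec = FilterSpec()) -> BoldRun:
    """Detrend then high-pass, in that order."""
    out = run
    if spec.detrend:
        out = detrend_linear(out)
    out = highpass(out, spec)
    return out
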