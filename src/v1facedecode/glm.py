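"""Hemodynamic modelling: double-gamma HRF, FIR deconvolution and
single-trial design matrices, ordinary least squares, t-contrasts and
peak/window summaries of deconvolved responses.

The estimators here are deliberately plain OLS (no prewhitening): the model
is a voxel-wise general linear model ``y = X b + e`` fitted independently
per voxel, with ``t = w'b / sqrt(s^2 w'(X'X)^+ w)`` for a contrast vector
``w`` and residual variance ``s^2 = RSS / dof``, ``dof = n - rank(X)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HrfParams",
    "HrfKernel",
    "DesignMatrix",
    "BetaEstimates",
    "TMap",
    "double_gamma_hrf",
    "build_fir_design",
    "build_single_trial_design",
    "build_condition_design",
    "fixed_effects_design",
    "fit_ols",
    "t_contrast",
    "peak_and_window",
]


@dataclass(frozen=True)
class HrfParams:
    """Parameters of the canonical double-gamma hemodynamic response.

    ``peak_delay`` and ``undershoot_delay`` are the gamma delays in seconds
    (mode of each gamma at ``delay - dispersion``), ``ratio`` is the
    peak-to-undershoot amplitude ratio and ``length`` the kernel support in
    seconds.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0


@dataclass(frozen=True)
class HrfKernel:
    """HRF sampled at TR spacing, peak-normalized, with ``samples[0] == 0``."""

    samples: np.ndarray
    tr: float
    params: HrfParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("HRF kernel contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.tr


def double_gamma_hrf(tr: float = 1.0, params: HrfParams | None = None) -> HrfKernel:
    """Difference of two gamma densities (response peak minus late undershoot).

    The kernel is evaluated at ``t = 0, tr, 2 tr, ...`` up to ``params.length``
    and normalized so its maximum is 1.  Gamma shape parameters are
    ``delay / dispersion`` with scale ``dispersion``, so the positive lobe
    peaks at ``peak_delay - peak_dispersion`` seconds (5 s for defaults).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    p = params or HrfParams()
    for name in ("peak_delay", "undershoot_delay", "peak_dispersion", "undershoot_dispersion", "ratio"):
        if getattr(p, name) <= 0:
            raise ValueError(f"HRF parameter {name} must be positive")
    t = np.arange(0.0, p.length + 0.5 * tr, tr)
    peak = sps.gamma.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    under = sps.gamma.pdf(t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion)
    h = peak - under / p.ratio
    h = h / np.max(h)
    h[0] = 0.0  # gamma pdf with shape > 1 is already 0 at t = 0
    return HrfKernel(samples=h, tr=tr, params=p)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """volumes x predictors matrix with one label per column.

    Labels are tuples: ``("cond", c, k)`` for FIR bin ``k`` of condition
    ``c``, ``("trial", i, c)`` for single-trial predictors, ``("cond", c)``
    for condition-level predictors and ``("confound", name)`` for confounds.
    """

    matrix: np.ndarray
    column_labels: list[tuple]
    tr: float = 1.0
    row_blocks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.matrix.shape[1] != len(self.column_labels):
            raise ValueError("column label count does not match matrix")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.matrix.shape[1]

    def columns(self, kind: str | None = None) -> list[int]:
        """Indices of columns whose label starts with ``kind`` (all if None)."""
        if kind is None:
            return list(range(self.n_predictors))
        return [i for i, lab in enumerate(self.column_labels) if lab[0] == kind]

    def contrast_vector(self, weights_by_label: dict) -> np.ndarray:
        """Expand a {label: weight} mapping to a dense contrast vector."""
        w = np.zeros(self.n_predictors)
        index = {lab: i for i, lab in enumerate(self.column_labels)}
        for lab, weight in weights_by_label.items():
            if lab not in index:
                raise KeyError(f"no design column labelled {lab!r}")
            w[index[lab]] = weight
        return w

    def to_frame(self) -> pd.DataFrame:
        cols = ["/".join(str(x) for x in lab) for lab in self.column_labels]
        return pd.DataFrame(self.matrix, columns=cols)


def _onset_volume(onset: float, tr: float) -> int:
    return int(round(onset / tr))


def build_fir_design(
    events: pd.DataFrame,
    n_bins: int = 20,
    tr: float = 1.0,
    n_volumes: int | None = None,
    confounds: tuple[str, ...] = ("mean",),
    by: str = "trial_type",
    conditions: list | None = None,
) -> DesignMatrix:
    """Finite-impulse-response (deconvolution) design.

    One stick predictor per ``(condition, bin)``: predictor ``(c, k)`` has a 1
    at volume ``v + k`` for every event of condition ``c`` whose onset rounds
    to volume ``v``; sticks beyond the run end are truncated.  Conditions
    default to the sorted unique values of ``events[by]`` — pass a table with
    baseline rows removed to reproduce the "n predictors per condition
    excluding baseline" convention; an explicitly listed condition with no
    events yields all-zero stimulus columns.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_volumes is None:
        raise ValueError("n_volumes is required")
    if conditions is None:
        conditions = sorted(pd.unique(events[by]))
    labels: list[tuple] = []
    cols = []
    for c in conditions:
        onsets = events.loc[events[by] == c, "onset"].to_numpy(dtype=float)
        vols = [_onset_volume(o, tr) for o in onsets]
        if any(v >= n_volumes or v < 0 for v in vols):
            raise ValueError(f"event of condition {c!r} falls outside the run")
        for k in range(n_bins):
            col = np.zeros(n_volumes)
            for v in vols:
                if v + k < n_volumes:
                    col[v + k] = 1.0
            cols.append(col)
            labels.append(("cond", c, k))
    for name in confounds:
        if name == "mean":
            cols.append(np.ones(n_volumes))
            labels.append(("confound", "mean"))
        else:
            raise ValueError(f"unknown confound {name!r}")
    X = np.column_stack(cols) if cols else np.zeros((n_volumes, 0))
    return DesignMatrix(matrix=X, column_labels=labels, tr=tr)


def _convolved_boxcar(onset_vol: int, dur_vols: int, kernel: np.ndarray, n_volumes: int) -> np.ndarray:
    box = np.zeros(n_volumes)
    box[onset_vol : min(onset_vol + dur_vols, n_volumes)] = 1.0
    return np.convolve(box, kernel)[:n_volumes]


def build_single_trial_design(
    events: pd.DataFrame,
    hrf: HrfKernel,
    n_volumes: int,
    tr: float = 1.0,
) -> DesignMatrix:
    """One HRF-convolved boxcar column per trial plus an all-ones mean confound.

    This is the beta-series design used for pattern analysis: as many stimulus
    predictors as trials, so each fitted coefficient is that trial's response
    amplitude estimate.
    """
    onsets = events["onset"].to_numpy(dtype=float)
    if len(np.unique(np.round(onsets / tr))) != len(onsets):
        raise ValueError("overlapping identical onsets in single-trial design")
    cols = []
    labels: list[tuple] = []
    for i, (_, ev) in enumerate(events.iterrows()):
        v = _onset_volume(float(ev["onset"]), tr)
        if v >= n_volumes or v < 0:
            raise ValueError("trial onset outside the run")
        dur = max(1, int(round(float(ev.get("duration", tr)) / tr)))
        cols.append(_convolved_boxcar(v, dur, hrf.samples, n_volumes))
        labels.append(("trial", i, str(ev.get("trial_type", ""))))
    cols.append(np.ones(n_volumes))
    labels.append(("confound", "mean"))
    return DesignMatrix(matrix=np.column_stack(cols), column_labels=labels, tr=tr)


def build_condition_design(
    events: pd.DataFrame,
    hrf: HrfKernel | None,
    n_volumes: int,
    tr: float = 1.0,
    by: str = "trial_type",
    confounds: tuple[str, ...] = ("mean",),
) -> DesignMatrix:
    """One predictor per condition (boxcar, optionally HRF-convolved)."""
    conditions = sorted(pd.unique(events[by]))
    cols = []
    labels: list[tuple] = []
    kernel = hrf.samples if hrf is not None else np.array([1.0])
    for c in conditions:
        col = np.zeros(n_volumes)
        for _, ev in events.loc[events[by] == c].iterrows():
            v = _onset_volume(float(ev["onset"]), tr)
            if v >= n_volumes or v < 0:
                raise ValueError(f"event of condition {c!r} falls outside the run")
            dur = max(1, int(round(float(ev.get("duration", tr)) / tr)))
            col[v : min(v + dur, n_volumes)] = 1.0
        cols.append(np.convolve(col, kernel)[:n_volumes])
        labels.append(("cond", c))
    for name in confounds:
        if name != "mean":
            raise ValueError(f"unknown confound {name!r}")
        cols.append(np.ones(n_volumes))
        labels.append(("confound", "mean"))
    return DesignMatrix(matrix=np.column_stack(cols), column_labels=labels, tr=tr)


def fixed_effects_design(
    events: pd.DataFrame,
    n_volumes_per_run: dict,
    tr: float = 1.0,
    hrf: HrfKernel | None = None,
    by: str = "trial_type",
) -> DesignMatrix:
    """Concatenated-run group design: one predictor per condition, one
    intercept confound per (subject, run).

    ``events`` must carry ``subject`` and ``run`` columns; ``n_volumes_per_run``
    maps ``(subject, run)`` to the run's volume count.  Condition predictors
    are raw boxcars by default (each row sums to at most 1 for non-overlapping
    events) or HRF-convolved boxcars when ``hrf`` is given.
    """
    for col in ("subject", "run"):
        if col not in events.columns:
            raise ValueError(f"events table lacks required column {col!r}")
    blocks = sorted(n_volumes_per_run)
    offsets = {}
    total = 0
    for b in blocks:
        offsets[b] = total
        total += int(n_volumes_per_run[b])
    conditions = sorted(pd.unique(events[by]))
    kernel = hrf.samples if hrf is not None else np.array([1.0])
    cols = []
    labels: list[tuple] = []
    for c in conditions:
        col = np.zeros(total)
        for _, ev in events.loc[events[by] == c].iterrows():
            key = (ev["subject"], ev["run"])
            if key not in offsets:
                raise ValueError(f"event references unknown (subject, run) {key!r}")
            n_vol = int(n_volumes_per_run[key])
            v = _onset_volume(float(ev["onset"]), tr)
            if v >= n_vol or v < 0:
                raise ValueError(f"event of condition {c!r} falls outside its run")
            dur = max(1, int(round(float(ev.get("duration", tr)) / tr)))
            local = np.zeros(n_vol)
            local[v : min(v + dur, n_vol)] = 1.0
            local = np.convolve(local, kernel)[:n_vol]
            off = offsets[key]
            col[off : off + n_vol] += local
        cols.append(col)
        labels.append(("cond", c))
    for b in blocks:
        col = np.zeros(total)
        off = offsets[b]
        col[off : off + int(n_volumes_per_run[b])] = 1.0
        cols.append(col)
        labels.append(("confound", f"{b[0]}_{b[1]}"))
    row_blocks = {b: (offsets[b], offsets[b] + int(n_volumes_per_run[b])) for b in blocks}
    return DesignMatrix(matrix=np.column_stack(cols), column_labels=labels, tr=tr, row_blocks=row_blocks)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


@dataclass
class BetaEstimates:
    """OLS coefficients (predictors x voxels) with residual variance and dof."""

    betas: np.ndarray
    residual_variance: np.ndarray
    dof: int
    column_labels: list[tuple]

    def for_labels(self, labels: list[tuple]) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.column_labels)}
        return self.betas[[index[lab] for lab in labels]]


@dataclass
class TMap:
    t: np.ndarray
    dof: int
    contrast_label: str = ""

    def p_values(self, tail: str = "two-sided") -> np.ndarray:
        if tail == "two-sided":
            return 2.0 * sps.t.sf(np.abs(self.t), self.dof)
        if tail == "greater":
            return sps.t.sf(self.t, self.dof)
        raise ValueError("tail must be 'two-sided' or 'greater'")


def fit_ols(X: DesignMatrix, Y) -> BetaEstimates:
    """Voxel-wise ordinary least squares.

    ``Y`` is a BoldRun or a voxels x volumes array.  Rank-deficient designs
    fall back to the minimum-norm pseudo-inverse solution with a warning.
    """
    data = getattr(Y, "data", Y)
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] != X.n_volumes:
        raise ValueError(
            f"volume mismatch: design has {X.n_volumes}, data has {data.shape[1]}"
        )
    M = X.matrix
    rank = int(np.linalg.matrix_rank(M)) if M.size else 0
    if rank < X.n_predictors:
        warnings.warn("rank-deficient design: using minimum-norm pseudo-inverse", stacklevel=2)
    pinv = np.linalg.pinv(M)
    betas = pinv @ data.T  # predictors x voxels
    resid = data.T - M @ betas
    dof = X.n_volumes - rank
    rss = np.sum(resid**2, axis=0)
    residual_variance = rss / dof if dof > 0 else np.full(data.shape[0], np.nan)
    return BetaEstimates(
        betas=betas,
        residual_variance=residual_variance,
        dof=dof,
        column_labels=list(X.column_labels),
    )


def t_contrast(est: BetaEstimates, X: DesignMatrix, weights, label: str = "") -> TMap:
    """t statistic ``w'b / sqrt(s^2 w'(X'X)^+ w)`` per voxel.

    Voxels with zero residual variance (or a zero-variance contrast) get
    ``t = 0`` rather than a division error.
    """
    w = np.asarray(weights, dtype=float)
    if w.size != X.n_predictors:
        raise ValueError("contrast length does not match predictor count")
    xtx_inv = np.linalg.pinv(X.matrix.T @ X.matrix)
    scale = float(w @ xtx_inv @ w)
    effect = w @ est.betas
    denom2 = est.residual_variance * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom2 > 0, effect / np.sqrt(np.where(denom2 > 0, denom2, 1.0)), 0.0)
    return TMap(t=t, dof=est.dof, contrast_label=label)


@dataclass
class PeakWindowSummary:
    peak_value: np.ndarray
    window_mean: np.ndarray
    peak_time: float
    peak_bin: int


def peak_and_window(
    betas_by_bin: np.ndarray,
    bin_times: np.ndarray,
    peak_window: tuple[float, float] = (5.0, 7.0),
    avg_window: tuple[float, float] = (3.0, 9.0),
) -> PeakWindowSummary:
    """Peak and window summaries of a deconvolved (FIR) response.

    ``betas_by_bin`` is ``(n_bins,)`` or ``(n_bins, n_series)``.  The peak bin
    is chosen where the grand mean across series is maximal within
    ``peak_window`` (inclusive) — using the grand mean avoids biasing the
    comparison toward any one condition — and per-series values at that bin
    are returned.  ``window_mean`` is the per-series mean over all bins inside
    ``avg_window`` (inclusive).
    """
    B = np.asarray(betas_by_bin, dtype=float)
    squeeze = B.ndim == 1
    if squeeze:
        B = B[:, None]
    times = np.asarray(bin_times, dtype=float)
    if times.size != B.shape[0]:
        raise ValueError("bin_times length does not match betas")
    peak_mask = (times >= peak_window[0]) & (times <= peak_window[1])
    avg_mask = (times >= avg_window[0]) & (times <= avg_window[1])
    if not peak_mask.any() or not avg_mask.any():
        raise ValueError("summary window falls outside the modelled bins")
    grand = B.mean(axis=1)
    idx_in = np.flatnonzero(peak_mask)
    peak_bin = int(idx_in[np.argmax(grand[idx_in])])
    peak_value = B[peak_bin]
    window_mean = B[avg_mask].mean(axis=0)
    if squeeze:
        peak_value = peak_value[0]
        window_mean = window_mean[0]
    return PeakWindowSummary(
        peak_value=np.asarray(peak_value),
        window_mean=np.asarray(window_mean),
        peak_time=float(times[peak_bin]),
        peak_bin=peak_bin,
    )
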