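"""Synthetic event-related fMRI experiments with full ground truth.

This module is the forward model for the whole pipeline: it generates rapid
event-related designs (six conditions: happy / fearful / neutral face,
eye- and mouth-checkerboard mapping, fixation baseline; 1 s stimulus +
3 s fixation; tasks alternating between expression and gender categorization
across runs), voxel populations with ground-truth region labels (eye patch,
mouth patch, rest of V1, outside V1) and polar-angle preferences,
phase-encoded rotating-wedge runs, and gaze traces with injected saccades.

BOLD signal is linear in the injected amplitudes:
``signal = (trial boxcars (*) HRF) @ amplitudes + drift + noise``,
so every downstream estimator can be checked against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .glm import HrfKernel

__all__ = [
    "FACE_CONDITIONS",
    "MAPPING_CONDITIONS",
    "BASELINE_CONDITION",
    "DEFAULT_CONDITIONS",
    "TASKS",
    "GENDERS",
    "REGION_LABELS",
    "ExperimentDesign",
    "RegionTruth",
    "PatternTruth",
    "NoiseModel",
    "BoldRun",
    "GazeTrace",
    "SaccadeSpec",
    "CheckerboardGeometry",
    "make_design",
    "make_region_truth",
    "make_pattern_truth",
    "simulate_run",
    "simulate_wedge_run",
    "checkerboard_geometry",
    "simulate_gaze",
    "write_events",
    "read_events",
    "bold_to_nifti",
    "bold_from_nifti",
]

FACE_CONDITIONS = ("happy", "fearful", "neutral")
MAPPING_CONDITIONS = ("eyes_map", "mouth_map")
BASELINE_CONDITION = "fixation"
DEFAULT_CONDITIONS = FACE_CONDITIONS + MAPPING_CONDITIONS + (BASELINE_CONDITION,)
TASKS = ("expression", "gender")
GENDERS = ("female", "male")
REGION_LABELS = ("eye", "mouth", "rest_v1", "outside")

EVENT_COLUMNS = ["onset", "duration", "trial_type", "run", "task", "gender"]


def _derive_seed(*keys) -> int:
    """Deterministic 31-bit seed from a tuple of integer keys."""
    return int(np.random.SeedSequence([int(k) for k in keys]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------


@dataclass
class ExperimentDesign:
    """Event table plus timing metadata for a multi-run experiment.

    ``trials`` is a BIDS-style table (onset, duration, trial_type, run, task,
    gender) with onsets in seconds relative to the first retained volume of
    each run.  Trials sit on a fixed SOA grid (stimulus + fixation gap), and
    tasks alternate between runs.
    """

    trials: pd.DataFrame
    n_runs: int
    tr: float
    conditions: tuple
    stim_duration: float
    fixation_gap: float
    lead_in_volumes: int
    lead_out_volumes: int
    task_per_run: tuple
    seed: int

    def __post_init__(self) -> None:
        for run in range(self.n_runs):
            onsets = self.run_events(run)["onset"].to_numpy()
            if onsets.size and (np.any(onsets < 0) or np.any(np.diff(onsets) <= 0)):
                raise ValueError("onsets must be non-negative and strictly increasing per run")

    @property
    def soa(self) -> float:
        return self.stim_duration + self.fixation_gap

    def run_events(self, run: int) -> pd.DataFrame:
        return self.trials.loc[self.trials["run"] == run].reset_index(drop=True)

    def n_volumes(self, run: int | None = None) -> int:
        """Volumes per run: lead-in + trial block + lead-out."""
        per_run = len(self.trials) // self.n_runs if self.n_runs else 0
        block = int(round(per_run * self.soa / self.tr))
        return self.lead_in_volumes + block + self.lead_out_volumes


def make_design(
    n_runs: int = 6,
    trials_per_condition: int = 120,
    conditions: tuple = DEFAULT_CONDITIONS,
    tr: float = 1.0,
    stim_duration: float = 1.0,
    fixation_gap: float = 3.0,
    seed: int = 0,
    lead_in_volumes: int = 10,
    lead_out_volumes: int = 10,
    tasks: tuple = TASKS,
) -> ExperimentDesign:
    """Randomly ordered trials on a fixed SOA grid, balanced per condition.

    ``trials_per_condition`` is the total count per condition across all runs
    (120 by default, i.e. 720 trials over six runs) and must divide evenly
    across runs.  Face trials additionally get a gender attribute, balanced
    within each (run, condition) cell.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if trials_per_condition < 0:
        raise ValueError("trials_per_condition must be >= 0")
    conditions = tuple(conditions)
    if not conditions:
        raise ValueError("at least one condition label is required")
    for c in conditions:
        if not isinstance(c, str) or not c:
            raise ValueError(f"unknown condition label {c!r}: labels must be non-empty strings")
    if len(set(conditions)) != len(conditions):
        raise ValueError("condition labels must be unique")
    if trials_per_condition % n_runs:
        raise ValueError("trials_per_condition must divide evenly across runs")
    per_run = trials_per_condition // n_runs
    rng = np.random.default_rng(seed)
    soa = stim_duration + fixation_gap
    rows = []
    gendered = [c for c in conditions if c in FACE_CONDITIONS]
    for run in range(n_runs):
        labels = np.repeat(conditions, per_run)
        rng.shuffle(labels)
        genders = {}
        for c in gendered:
            g = np.repeat(GENDERS, per_run // 2)
            if per_run % 2:
                g = np.append(g, rng.choice(GENDERS))
            rng.shuffle(g)
            genders[c] = list(g)
        task = tasks[run % len(tasks)]
        for i, c in enumerate(labels):
            rows.append(
                {
                    "onset": lead_in_volumes * tr + i * soa,
                    "duration": stim_duration,
                    "trial_type": c,
                    "run": run,
                    "task": task,
                    "gender": genders[c].pop() if c in genders else "n/a",
                }
            )
    trials = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return ExperimentDesign(
        trials=trials,
        n_runs=n_runs,
        tr=tr,
        conditions=conditions,
        stim_duration=stim_duration,
        fixation_gap=fixation_gap,
        lead_in_volumes=lead_in_volumes,
        lead_out_volumes=lead_out_volumes,
        task_per_run=tuple(tasks[r % len(tasks)] for r in range(n_runs)),
        seed=seed,
    )


def write_events(design_or_table, path) -> None:
    table = getattr(design_or_table, "trials", design_or_table)
    table.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class RegionTruth:
    """Ground-truth voxel labels and polar-angle preferences.

    ``labels`` partitions the voxel set into eye / mouth / rest_v1 / outside;
    ``preferred_angle`` is the polar angle (degrees in [0, 360)) at which a
    voxel responds during wedge mapping.
    """

    labels: np.ndarray
    preferred_angle: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.preferred_angle = np.asarray(self.preferred_angle, dtype=float)
        if self.labels.shape != self.preferred_angle.shape:
            raise ValueError("labels and preferred_angle must align")
        unknown = set(self.labels) - set(REGION_LABELS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")
        if np.any(self.preferred_angle < 0) or np.any(self.preferred_angle >= 360):
            raise ValueError("preferred angles must lie in [0, 360)")

    @property
    def n_voxels(self) -> int:
        return self.labels.size

    def indices(self, *labels: str) -> np.ndarray:
        return np.flatnonzero(np.isin(self.labels, labels))

    @property
    def v1_mask(self) -> np.ndarray:
        return self.indices("eye", "mouth", "rest_v1")


def make_region_truth(
    n_eye: int = 160,
    n_mouth: int = 160,
    n_rest: int = 400,
    n_outside: int = 80,
    seed: int = 0,
    banded_angles: bool = True,
) -> RegionTruth:
    """Assign region labels and preferred angles.

    With ``banded_angles`` the eye patch sits in the upper-field (ventral V1)
    wedge around 270 deg and the mouth patch in the lower-field (dorsal) wedge
    around 90 deg, echoing the retinotopy of faces viewed at fixation; rest and
    outside voxels get uniform angles.
    """
    rng = np.random.default_rng(seed)
    labels = np.array(
        ["eye"] * n_eye + ["mouth"] * n_mouth + ["rest_v1"] * n_rest + ["outside"] * n_outside,
        dtype=object,
    )
    n = labels.size
    angle = rng.uniform(0, 360, size=n)
    if banded_angles:
        angle[labels == "eye"] = (270 + rng.uniform(-22.5, 22.5, n_eye)) % 360
        angle[labels == "mouth"] = (90 + rng.uniform(-22.5, 22.5, n_mouth)) % 360
    return RegionTruth(labels=labels, preferred_angle=angle)


@dataclass
class PatternTruth:
    """Ground-truth response amplitudes per (condition, task, voxel).

    ``amplitudes[c, t, v]`` is the BOLD response amplitude of voxel ``v`` to
    condition ``c`` under task ``t``; ``gender_map[g, v]`` is an additive
    amplitude for the gender attribute of face trials (zero by default).
    ``cnr`` records the ratio of the injected pattern spread to the noise
    standard deviation, for bookkeeping.
    """

    conditions: tuple
    tasks: tuple
    amplitudes: np.ndarray
    gender_map: np.ndarray | None = None
    cnr: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        expected = (len(self.conditions), len(self.tasks))
        if self.amplitudes.shape[:2] != expected:
            raise ValueError("amplitudes must be (conditions, tasks, voxels)")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if self.gender_map is None:
            self.gender_map = np.zeros((len(GENDERS), self.n_voxels))
        self.gender_map = np.asarray(self.gender_map, dtype=float)

    @property
    def n_voxels(self) -> int:
        return self.amplitudes.shape[2]

    def trial_amplitudes(self, events: pd.DataFrame, task: str) -> np.ndarray:
        """(n_trials, n_voxels) amplitude matrix for one run's events."""
        if task not in self.tasks:
            raise ValueError(f"unknown task {task!r}")
        t = self.tasks.index(task)
        out = np.zeros((len(events), self.n_voxels))
        for i, (_, ev) in enumerate(events.iterrows()):
            c = ev["trial_type"]
            if c not in self.conditions:
                raise ValueError(f"unknown condition label {c!r} not covered by amplitude map")
            a = self.amplitudes[self.conditions.index(c), t].copy()
            g = ev.get("gender", "n/a")
            if g in GENDERS:
                a = a + self.gender_map[GENDERS.index(g)]
            out[i] = a
        return out


def make_pattern_truth(
    region_truth: RegionTruth,
    conditions: tuple = DEFAULT_CONDITIONS,
    tasks: tuple = TASKS,
    base_response: float = 1.0,
    mapping_response: float = 2.0,
    noise_sigma: float = 1.0,
    expression_cnr: float = 0.5,
    gender_cnr: float = 0.5,
    signal_regions: tuple = ("eye", "mouth", "rest_v1"),
    task_modulation: dict | None = None,
    seed: int = 0,
) -> PatternTruth:
    """Build an amplitude map with mapping, face and class-pattern components.

    Face conditions drive all V1 voxels at ``base_response``; eye/mouth
    mapping conditions drive their ground-truth patches at ``mapping_response``;
    fixation drives nothing.  Class information is injected as zero-mean
    Gaussian multivoxel patterns with per-voxel spread ``cnr * noise_sigma``,
    drawn independently per expression condition (and per gender level) over
    ``signal_regions``.  With both CNRs at 0 the amplitudes are identical
    across the to-be-decoded class labels — the null construction.
    ``task_modulation`` optionally maps (condition, task) to a multiplicative
    factor (default 1.0 everywhere, i.e. task effects are opt-in).
    """
    rng = np.random.default_rng(seed)
    n_vox = region_truth.n_voxels
    v1 = region_truth.v1_mask
    sig = region_truth.indices(*signal_regions)
    amplitudes = np.zeros((len(conditions), len(tasks), n_vox))
    expr_sd = expression_cnr * noise_sigma
    for ci, c in enumerate(conditions):
        base = np.zeros(n_vox)
        if c in FACE_CONDITIONS:
            base[v1] = base_response
            if expr_sd > 0:
                delta = np.zeros(n_vox)
                delta[sig] = rng.normal(0.0, expr_sd, sig.size)
                base = base + delta
        elif c == "eyes_map":
            base[region_truth.indices("eye")] = mapping_response
        elif c == "mouth_map":
            base[region_truth.indices("mouth")] = mapping_response
        for ti, t in enumerate(tasks):
            factor = 1.0 if task_modulation is None else float(task_modulation.get((c, t), 1.0))
            amplitudes[ci, ti] = base * factor
    gender_sd = gender_cnr * noise_sigma
    gender_map = np.zeros((len(GENDERS), n_vox))
    if gender_sd > 0:
        gender_map[:, sig] = rng.normal(0.0, gender_sd, (len(GENDERS), sig.size))
    return PatternTruth(
        conditions=tuple(conditions),
        tasks=tuple(tasks),
        amplitudes=amplitudes,
        gender_map=gender_map,
        cnr=max(expression_cnr, gender_cnr),
    )


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise and drift: white (or AR(1)) Gaussian noise of innovation
    standard deviation ``sigma`` plus a linear drift of ``drift_slope`` BOLD
    units per volume.  Bit-reproducible for a fixed seed."""

    sigma: float = 1.0
    ar1_coefficient: float = 0.0
    drift_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.ar1_coefficient < 1):
            raise ValueError("ar1_coefficient must lie in [0, 1)")

    def sample(self, n_voxels: int, n_volumes: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        noise = rng.normal(0.0, self.sigma, (n_voxels, n_volumes)) if self.sigma > 0 else np.zeros((n_voxels, n_volumes))
        if self.ar1_coefficient > 0:
            noise = lfilter([1.0], [1.0, -self.ar1_coefficient], noise, axis=1)
        drift = self.drift_slope * np.arange(n_volumes)
        return noise + drift

    def reseeded(self, *keys) -> "NoiseModel":
        return replace(self, seed=_derive_seed(self.seed, *keys))


@dataclass
class BoldRun:
    """voxels x volumes BOLD matrix with TR metadata."""

    data: np.ndarray
    tr: float
    run_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be voxels x volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


def _kernel_samples(hrf_kernel) -> np.ndarray:
    return np.asarray(getattr(hrf_kernel, "samples", hrf_kernel), dtype=float)


def simulate_run(
    design: ExperimentDesign,
    run: int,
    region_truth: RegionTruth,
    pattern_truth: PatternTruth,
    noise_model: NoiseModel,
    hrf_kernel,
) -> BoldRun:
    """Forward model for one run: trial boxcars convolved with the HRF,
    weighted by the ground-truth amplitudes, plus drift and noise.

    The signal is exactly linear in ``pattern_truth.amplitudes``.
    """
    if pattern_truth.n_voxels != region_truth.n_voxels:
        raise ValueError("pattern truth voxel count does not match region truth")
    events = design.run_events(run)
    n_vol = design.n_volumes(run)
    kernel = _kernel_samples(hrf_kernel)
    task = design.task_per_run[run]
    amps = pattern_truth.trial_amplitudes(events, task)  # trials x voxels
    R = np.zeros((n_vol, len(events)))
    dur_vols = max(1, int(round(design.stim_duration / design.tr)))
    for i, onset in enumerate(events["onset"].to_numpy(dtype=float)):
        v = int(round(onset / design.tr))
        if v < 0 or v >= n_vol:
            raise ValueError("trial onset outside the run")
        box = np.zeros(n_vol)
        box[v : min(v + dur_vols, n_vol)] = 1.0
        R[:, i] = np.convolve(box, kernel)[:n_vol]
    signal = (R @ amps).T
    data = signal + noise_model.sample(region_truth.n_voxels, n_vol)
    return BoldRun(data=data, tr=design.tr, run_id=f"run-{run}")


def _circular_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular convolution with the kernel aliased onto the period of x."""
    n = x.size
    if kernel.size == 1:  # delta kernel: avoid FFT round-off
        return x * kernel[0]
    k = np.zeros(n)
    for i, v in enumerate(kernel):
        k[i % n] += v
    return np.real(np.fft.ifft(np.fft.fft(x) * np.fft.fft(k)))


def simulate_wedge_run(
    region_truth: RegionTruth,
    cycle_volumes: int = 32,
    n_cycles: int = 8,
    noise_model: NoiseModel | None = None,
    hrf_kernel=None,
    response_amplitude: float = 1.0,
) -> BoldRun:
    """Phase-encoded rotating-wedge run.

    The wedge sweeps 360 deg per cycle of ``cycle_volumes`` volumes; a voxel
    with preferred angle theta is driven for the 1/8-cycle (45 deg) window
    whose start volume is ``round(theta / 360 * cycle_volumes)``.  The neural
    boxcar is circularly convolved with the HRF so the response is exactly
    periodic.  Voxels labelled ``outside`` are silent (noise only).
    """
    if cycle_volumes % 8:
        raise ValueError("cycle_volumes must be divisible by 8 (45-degree bins)")
    kernel = _kernel_samples(hrf_kernel) if hrf_kernel is not None else np.array([1.0])
    noise_model = noise_model or NoiseModel(sigma=0.0)
    width = cycle_volumes // 8
    base = np.zeros(cycle_volumes)
    base[:width] = 1.0
    base = _circular_convolve(base, kernel)
    n_vol = cycle_volumes * n_cycles
    data = np.zeros((region_truth.n_voxels, n_vol))
    for v in range(region_truth.n_voxels):
        if region_truth.labels[v] == "outside":
            continue
        start = int(round(region_truth.preferred_angle[v] / 360.0 * cycle_volumes)) % cycle_volumes
        data[v] = response_amplitude * np.tile(np.roll(base, start), n_cycles)
    data += noise_model.sample(region_truth.n_voxels, n_vol)
    return BoldRun(data=data, tr=1.0, run_id="wedge")


# ---------------------------------------------------------------------------
# stimulus geometry and gaze
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CheckerboardGeometry:
    """Feature-mapping checkerboard extents in degrees of visual angle."""

    mouth_width: float
    mouth_height: float
    eye_width: float
    eye_height: float
    eye_mouth_gap: float

    @property
    def mouth_area(self) -> float:
        return self.mouth_width * self.mouth_height

    @property
    def eye_area_total(self) -> float:
        return 2 * self.eye_width * self.eye_height


def checkerboard_geometry(scale: float = 1.0) -> CheckerboardGeometry:
    """Default geometry: mouth 2.8 x 7.2 deg, two eye boxes 2.8 x 3.6 deg
    (areas equal by construction), vertical eye-to-mouth separation 4.9 deg."""
    return CheckerboardGeometry(
        mouth_width=7.2 * scale,
        mouth_height=2.8 * scale,
        eye_width=3.6 * scale,
        eye_height=2.8 * scale,
        eye_mouth_gap=4.9 * scale,
    )


@dataclass(frozen=True)
class SaccadeSpec:
    onset_s: float
    amplitude_deg: float
    duration_ms: float
    direction_deg: float = 0.0


@dataclass
class GazeTrace:
    """(x, y) gaze samples in degrees of visual angle at a fixed rate."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must be (n, 2)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("gaze samples must be finite")

    @property
    def x(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.samples[:, 1]

    def to_tsv(self, path) -> None:
        t = np.arange(len(self.samples)) / self.rate
        pd.DataFrame({"time_s": t, "x_deg": self.x, "y_deg": self.y}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GazeTrace":
        df = pd.read_csv(path, sep="\t")
        dt = np.diff(df["time_s"].to_numpy())
        rate = 1.0 / float(np.median(dt)) if dt.size else 1.0
        return cls(samples=df[["x_deg", "y_deg"]].to_numpy(), rate=rate)


def simulate_gaze(
    duration_s: float,
    rate: float = 60.0,
    fixation_noise_sd: float = 0.05,
    saccade_events: tuple = (),
    seed: int = 0,
) -> GazeTrace:
    """Fixation jitter plus injected square-pulse gaze excursions.

    Each :class:`SaccadeSpec` displaces gaze by ``amplitude_deg`` along
    ``direction_deg`` for ``duration_ms``; with no events and zero noise the
    trace is constant at the origin.
    """
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    n = int(round(duration_s * rate))
    rng = np.random.default_rng(seed)
    xy = rng.normal(0.0, fixation_noise_sd, (n, 2)) if fixation_noise_sd > 0 else np.zeros((n, 2))
    for ev in saccade_events:
        i0 = int(round(ev.onset_s * rate))
        ns = int(round(ev.duration_ms / 1000.0 * rate))
        theta = np.deg2rad(ev.direction_deg)
        xy[i0 : i0 + ns, 0] += ev.amplitude_deg * np.cos(theta)
        xy[i0 : i0 + ns, 1] += ev.amplitude_deg * np.sin(theta)
    return GazeTrace(samples=xy, rate=rate)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def bold_to_nifti(run: BoldRun, path, region_truth: RegionTruth | None = None) -> None:
    """Write a run as NIfTI-1 4D (voxels along x) with a JSON sidecar."""
    import nibabel as nib

    img = nib.Nifti1Image(run.data[:, None, None, :].astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    nib.save(img, str(path))
    sidecar = {"tr": run.tr, "run_id": run.run_id}
    if region_truth is not None:
        sidecar["region_labels"] = list(map(str, region_truth.labels))
    with open(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json", "w") as fh:
        json.dump(sidecar, fh)


def bold_from_nifti(path) -> BoldRun:
    """Read a 4D NIfTI, flattening x*y*z to the voxel axis."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    n_vol = data.shape[-1]
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return BoldRun(data=data.reshape(-1, n_vol), tr=tr or 1.0)
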