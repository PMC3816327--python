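"""End-to-end orchestration: simulate a cohort, run retinotopic mapping,
patch definition, GLM estimation, decoding and group statistics, and emit a
report mirroring the study's result surfaces (the region x task x
classification decoding table with averaged and single-trial rows, POI time
courses with peak/window summaries, accuracy-vs-set-size curves, eye-movement
screening).

Every simulated subject is an independent dataset sharing the configuration;
all randomness derives deterministically from a single master seed, so a
rerun with the same seed reproduces the report bit-for-bit.  No analysis
stage reads ground truth except the generator itself, the V1 mask (which
stands in for the study's manual surface-based delineation) and the final
evaluation summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import eyetrack, mvpa, poi as poimod, preprocess, retinotopy, stats
from .glm import (
    HrfKernel,
    HrfParams,
    build_fir_design,
    build_single_trial_design,
    double_gamma_hrf,
    fit_ols,
    fixed_effects_design,
    peak_and_window,
    t_contrast,
)
from .synthkit import (
    FACE_CONDITIONS,
    GENDERS,
    TASKS,
    BoldRun,
    ExperimentDesign,
    NoiseModel,
    PatternTruth,
    RegionTruth,
    _derive_seed,
    make_design,
    make_pattern_truth,
    make_region_truth,
    simulate_gaze,
    simulate_run,
    simulate_wedge_run,
)

__all__ = ["PipelineConfig", "SubjectData", "SubjectResult", "Report", "simulate_subject", "analyze_subject", "run_experiment", "write_report"]

REGIONS = ("eye", "mouth", "rest_v1")
CLASSIFICATIONS = {
    "happy_fear": ("happy", "fearful"),
    "male_female": GENDERS,
    "happy_fear_neutral": FACE_CONDITIONS,
}


@dataclass
class DesignConfig:
    n_runs: int = 6
    trials_per_condition: int = 120
    tr: float = 1.0
    stim_duration: float = 1.0
    fixation_gap: float = 3.0
    lead_in_volumes: int = 10
    lead_out_volumes: int = 10


@dataclass
class RegionConfig:
    n_eye: int = 160
    n_mouth: int = 160
    n_rest: int = 400
    n_outside: int = 80


@dataclass
class SignalConfig:
    base_response: float = 1.0
    mapping_response: float = 2.0
    expression_cnr: float = 0.5
    gender_cnr: float = 0.5
    signal_regions: tuple = ("eye", "mouth", "rest_v1")


@dataclass
class NoiseConfig:
    sigma: float = 1.0
    ar1_coefficient: float = 0.0
    drift_slope: float = 0.01


@dataclass
class PoiConfig:
    strict_threshold: float = 3.2
    lowered_threshold: float = 1.5
    responsive_p: float = 1e-4


@dataclass
class MvpaConfig:
    cost: float = 1.0
    n_draws: int = 30
    max_set_size: int = 160
    set_size_curves: bool = False
    curve_sizes: int = 15


@dataclass
class WedgeConfig:
    enabled: bool = True
    cycle_volumes: int = 32
    n_cycles: int = 8
    response_amplitude: float = 1.0


@dataclass
class GazeConfig:
    enabled: bool = True
    rate: float = 60.0
    fixation_noise_sd: float = 0.1


@dataclass
class PipelineConfig:
    """Full study configuration; defaults reproduce the study conditions
    (nine subjects, six alternating-task runs, 120 trials per condition)."""

    n_subjects: int = 9
    design: DesignConfig = field(default_factory=DesignConfig)
    regions: RegionConfig = field(default_factory=RegionConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    poi: PoiConfig = field(default_factory=PoiConfig)
    mvpa: MvpaConfig = field(default_factory=MvpaConfig)
    wedge: WedgeConfig = field(default_factory=WedgeConfig)
    gaze: GazeConfig = field(default_factory=GazeConfig)
    hrf: HrfParams = field(default_factory=HrfParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key, sub in (
            ("design", DesignConfig),
            ("regions", RegionConfig),
            ("signal", SignalConfig),
            ("noise", NoiseConfig),
            ("poi", PoiConfig),
            ("mvpa", MvpaConfig),
            ("wedge", WedgeConfig),
            ("gaze", GazeConfig),
            ("hrf", HrfParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def null(cls, **overrides) -> "PipelineConfig":
        """Study configuration with no class-dependent signal anywhere."""
        cfg = cls(**overrides)
        cfg.signal = dataclasses.replace(cfg.signal, expression_cnr=0.0, gender_cnr=0.0)
        return cfg

    @classmethod
    def smoke(cls, null: bool = False) -> "PipelineConfig":
        """Scaled-down cohort for fast end-to-end runs: same six-run
        alternating-task structure, fewer subjects, trials and voxels."""
        cfg = cls.null() if null else cls()
        cfg.n_subjects = 6
        cfg.design = dataclasses.replace(cfg.design, trials_per_condition=24)
        cfg.regions = RegionConfig(n_eye=24, n_mouth=24, n_rest=48, n_outside=24)
        cfg.signal = dataclasses.replace(cfg.signal, mapping_response=2.5)
        cfg.wedge = dataclasses.replace(cfg.wedge, n_cycles=2)
        cfg.mvpa = dataclasses.replace(cfg.mvpa, set_size_curves=False)
        return cfg


# ---------------------------------------------------------------------------
# per-subject simulation and analysis
# ---------------------------------------------------------------------------

_TAG_DESIGN, _TAG_REGION, _TAG_PATTERN, _TAG_RUN, _TAG_WEDGE, _TAG_GAZE = range(6)


@dataclass
class SubjectData:
    """One simulated subject: design, BOLD runs and the generating truth."""

    subject: int
    design: ExperimentDesign
    runs: list
    region_truth: RegionTruth
    pattern_truth: PatternTruth
    wedge_run: BoldRun | None
    gaze: list
    hrf: HrfKernel


def simulate_subject(config: PipelineConfig, master_seed: int, subject: int) -> SubjectData:
    d = config.design
    hrf = double_gamma_hrf(tr=d.tr, params=config.hrf)
    design = make_design(
        n_runs=d.n_runs,
        trials_per_condition=d.trials_per_condition,
        tr=d.tr,
        stim_duration=d.stim_duration,
        fixation_gap=d.fixation_gap,
        lead_in_volumes=d.lead_in_volumes,
        lead_out_volumes=d.lead_out_volumes,
        seed=_derive_seed(master_seed, subject, _TAG_DESIGN),
    )
    region_truth = make_region_truth(
        n_eye=config.regions.n_eye,
        n_mouth=config.regions.n_mouth,
        n_rest=config.regions.n_rest,
        n_outside=config.regions.n_outside,
        seed=_derive_seed(master_seed, subject, _TAG_REGION),
    )
    pattern_truth = make_pattern_truth(
        region_truth,
        base_response=config.signal.base_response,
        mapping_response=config.signal.mapping_response,
        noise_sigma=config.noise.sigma,
        expression_cnr=config.signal.expression_cnr,
        gender_cnr=config.signal.gender_cnr,
        signal_regions=tuple(config.signal.signal_regions),
        seed=_derive_seed(master_seed, subject, _TAG_PATTERN),
    )
    runs = []
    for r in range(d.n_runs):
        noise = NoiseModel(
            sigma=config.noise.sigma,
            ar1_coefficient=config.noise.ar1_coefficient,
            drift_slope=config.noise.drift_slope,
            seed=_derive_seed(master_seed, subject, _TAG_RUN, r),
        )
        runs.append(simulate_run(design, r, region_truth, pattern_truth, noise, hrf))
    wedge = None
    if config.wedge.enabled:
        wedge = simulate_wedge_run(
            region_truth,
            cycle_volumes=config.wedge.cycle_volumes,
            n_cycles=config.wedge.n_cycles,
            noise_model=NoiseModel(
                sigma=config.noise.sigma,
                drift_slope=config.noise.drift_slope,
                seed=_derive_seed(master_seed, subject, _TAG_WEDGE),
            ),
            hrf_kernel=hrf,
            response_amplitude=config.wedge.response_amplitude,
        )
    gaze = []
    if config.gaze.enabled:
        run_len = design.n_volumes() * d.tr
        for r in range(d.n_runs):
            gaze.append(
                simulate_gaze(
                    duration_s=run_len,
                    rate=config.gaze.rate,
                    fixation_noise_sd=config.gaze.fixation_noise_sd,
                    seed=_derive_seed(master_seed, subject, _TAG_GAZE, r),
                )
            )
    return SubjectData(
        subject=subject,
        design=design,
        runs=runs,
        region_truth=region_truth,
        pattern_truth=pattern_truth,
        wedge_run=wedge,
        gaze=gaze,
        hrf=hrf,
    )


@dataclass
class SubjectResult:
    subject: int
    pois: dict
    accuracies: pd.DataFrame
    timecourses: pd.DataFrame
    peaks: pd.DataFrame
    curves: pd.DataFrame | None
    phase_recovery: float | None
    saccade_count: int | None
    fixation_tests: dict | None


def _condition_glm(data_sub: SubjectData, runs: list) -> tuple:
    """Condition-level HRF GLM over concatenated preprocessed runs."""
    design = data_sub.design
    events = design.trials.copy()
    events = events.loc[events["trial_type"] != "fixation"]
    events["subject"] = data_sub.subject
    n_vol = {(data_sub.subject, r): design.n_volumes(r) for r in range(design.n_runs)}
    X = fixed_effects_design(events, n_vol, tr=design.tr, hrf=data_sub.hrf)
    Y = np.concatenate([r.data for r in runs], axis=1)
    est = fit_ols(X, Y)
    return X, est


def _define_pois(data_sub: SubjectData, runs: list, cfg: PoiConfig) -> dict:
    X, est = _condition_glm(data_sub, runs)
    w_em = X.contrast_vector({("cond", "eyes_map"): 1.0, ("cond", "mouth_map"): -1.0})
    tmap_em = t_contrast(est, X, w_em, label="eye-minus-mouth")
    faces = [c for c in FACE_CONDITIONS]
    w_faces = X.contrast_vector({("cond", c): 1.0 / len(faces) for c in faces})
    tmap_faces = t_contrast(est, X, w_faces, label="faces-minus-baseline")
    eye, mouth = poimod.define_feature_pois(tmap_em, cfg.strict_threshold)
    responsive = poimod.responsive_voxels(tmap_faces, p_threshold=cfg.responsive_p)
    rest = poimod.rest_of_v1(
        data_sub.region_truth.v1_mask,
        tmap_em,
        cfg.strict_threshold,
        cfg.lowered_threshold,
        responsive,
    )
    # diagnostic patches restricted to the anatomical V1 mask
    v1 = set(data_sub.region_truth.v1_mask.tolist())
    eye.voxel_indices = np.array(sorted(set(eye.voxel_indices.tolist()) & v1), dtype=int)
    mouth.voxel_indices = np.array(sorted(set(mouth.voxel_indices.tolist()) & v1), dtype=int)
    return {"eye": eye, "mouth": mouth, "rest_v1": rest}


def _single_trial_patterns(data_sub: SubjectData, runs: list) -> pd.DataFrame:
    """Beta-series estimation per run; returns a frame with one row per
    modelled (non-baseline) trial and the beta matrix in ``beta`` column."""
    design = data_sub.design
    rows = []
    for r, run in enumerate(runs):
        events = design.run_events(r)
        modelled = events.loc[events["trial_type"] != "fixation"].reset_index(drop=True)
        X = build_single_trial_design(modelled, data_sub.hrf, n_volumes=design.n_volumes(r), tr=design.tr)
        est = fit_ols(X, run)
        trial_cols = X.columns("trial")
        for i, ci in enumerate(trial_cols):
            ev = modelled.iloc[i]
            rows.append(
                {
                    "run": r,
                    "task": ev["task"],
                    "trial_type": ev["trial_type"],
                    "gender": ev["gender"],
                    "beta": est.betas[ci],
                }
            )
    return pd.DataFrame(rows)


def _pattern_set(trials: pd.DataFrame, task: str, classification: str, features: np.ndarray) -> mvpa.TrialPatternSet | None:
    levels = CLASSIFICATIONS[classification]
    sel = trials["task"] == task
    if classification == "male_female":
        sel &= trials["trial_type"].isin(FACE_CONDITIONS)
        labels = trials.loc[sel, "gender"].to_numpy()
    else:
        sel &= trials["trial_type"].isin(levels)
        labels = trials.loc[sel, "trial_type"].to_numpy()
    if features.size == 0 or sel.sum() == 0:
        return None
    betas = np.stack(trials.loc[sel, "beta"].to_list())[:, features]
    return mvpa.TrialPatternSet(
        betas=betas,
        labels=labels,
        run_ids=trials.loc[sel, "run"].to_numpy(),
        task=task,
        classification=classification,
    )


def _fir_timecourses(data_sub: SubjectData, runs: list, pois: dict, n_bins: int = 20) -> pd.DataFrame:
    """POI-mean deconvolved responses per condition and per gender, by task."""
    design = data_sub.design
    records = []
    for by, levels in (("trial_type", FACE_CONDITIONS), ("gender", GENDERS)):
        for task in TASKS:
            task_runs = [r for r in range(design.n_runs) if design.task_per_run[r] == task]
            per_run = []
            for r in task_runs:
                events = design.run_events(r)
                events = events.loc[events["trial_type"].isin(FACE_CONDITIONS)]
                X = build_fir_design(events, n_bins=n_bins, tr=design.tr, n_volumes=design.n_volumes(r), by=by)
                est = fit_ols(X, runs[r])
                betas = {}
                for lev in levels:
                    cols = [est.column_labels.index(("cond", lev, k)) for k in range(n_bins)]
                    betas[lev] = est.betas[cols]  # bins x voxels
                per_run.append(betas)
            for lev in levels:
                mean_beta = np.mean([b[lev] for b in per_run], axis=0)
                for region, p in pois.items():
                    if p.size == 0:
                        continue
                    tc = mean_beta[:, p.voxel_indices].mean(axis=1)
                    for k in range(n_bins):
                        records.append(
                            {
                                "task": task,
                                "region": region,
                                "level": lev,
                                "family": "expression" if by == "trial_type" else "gender",
                                "bin_s": k * design.tr,
                                "beta": float(tc[k]),
                            }
                        )
    return pd.DataFrame.from_records(records)


def _peak_summaries(timecourses: pd.DataFrame, tr: float) -> pd.DataFrame:
    """Peak (5-7 s) and window (3-9 s) summaries per task x region x level."""
    records = []
    pairs = {"expression": ("happy", "fearful"), "gender": GENDERS}
    for (family, task, region), grp in timecourses.groupby(["family", "task", "region"], observed=True):
        levels = [l for l in pairs[family] if l in set(grp["level"])]
        series = []
        for lev in levels:
            sub = grp.loc[grp["level"] == lev].sort_values("bin_s")
            series.append(sub["beta"].to_numpy())
        if not series:
            continue
        B = np.column_stack(series)
        times = np.sort(grp["bin_s"].unique())
        summ = peak_and_window(B, times)
        for i, lev in enumerate(levels):
            records.append(
                {
                    "family": family,
                    "task": task,
                    "region": region,
                    "level": lev,
                    "peak": float(np.atleast_1d(summ.peak_value)[i]),
                    "window": float(np.atleast_1d(summ.window_mean)[i]),
                }
            )
    return pd.DataFrame.from_records(records)


def analyze_subject(data_sub: SubjectData, config: PipelineConfig, master_seed: int = 0) -> SubjectResult:
    spec = preprocess.FilterSpec()
    runs = [preprocess.preprocess_run(r, spec) for r in data_sub.runs]
    pois = _define_pois(data_sub, runs, config.poi)
    trials = _single_trial_patterns(data_sub, runs)

    acc_rows = []
    curves_frames = []
    class_names = list(CLASSIFICATIONS)
    for region in REGIONS:
        p = pois[region]
        for task in TASKS:
            for classification in CLASSIFICATIONS:
                patterns = _pattern_set(trials, task, classification, p.voxel_indices)
                if patterns is None or np.unique(patterns.labels).size < 2:
                    for mode in ("averaged", "single_trial"):
                        acc_rows.append(
                            {"region": region, "task": task, "classification": classification, "test_mode": mode, "accuracy": np.nan}
                        )
                    continue
                if patterns.n_features > config.mvpa.max_set_size:
                    sub = mvpa.subsample_curve(
                        patterns,
                        sizes=np.array([config.mvpa.max_set_size]),
                        n_draws=config.mvpa.n_draws,
                        cost=config.mvpa.cost,
                        seed=_derive_seed(
                            master_seed,
                            data_sub.subject,
                            REGIONS.index(region),
                            TASKS.index(task),
                            class_names.index(classification),
                        ),
                    )
                    for mode in ("averaged", "single_trial"):
                        acc = float(sub.loc[sub["test_mode"] == mode, "accuracy"].iloc[0])
                        acc_rows.append(
                            {"region": region, "task": task, "classification": classification, "test_mode": mode, "accuracy": acc}
                        )
                else:
                    for mode in ("averaged", "single_trial"):
                        res = mvpa.loro_cv(patterns, cost=config.mvpa.cost, test_mode=mode)
                        acc_rows.append(
                            {"region": region, "task": task, "classification": classification, "test_mode": mode, "accuracy": res.accuracy}
                        )
                if config.mvpa.set_size_curves and classification != "happy_fear_neutral":
                    curve = mvpa.subsample_curve(
                        patterns,
                        sizes=mvpa.subsample_schedule(patterns.n_features, n_sizes=config.mvpa.curve_sizes, cap=config.mvpa.max_set_size),
                        n_draws=config.mvpa.n_draws,
                        cost=config.mvpa.cost,
                        seed=_derive_seed(
                            master_seed,
                            data_sub.subject,
                            100 + REGIONS.index(region),
                            TASKS.index(task),
                            class_names.index(classification),
                        ),
                    )
                    curve["region"] = region
                    curve["task"] = task
                    curve["classification"] = classification
                    curves_frames.append(curve)

    accuracies = pd.DataFrame(acc_rows)
    timecourses = _fir_timecourses(data_sub, runs, pois)
    peaks = _peak_summaries(timecourses, config.design.tr)

    phase_recovery = None
    if data_sub.wedge_run is not None:
        ref = retinotopy.build_phase_reference(
            cycle_volumes=config.wedge.cycle_volumes,
            n_cycles=config.wedge.n_cycles,
            hrf=data_sub.hrf,
        )
        pm = retinotopy.phase_map(
            preprocess.detrend_linear(data_sub.wedge_run),
            ref,
            cycle_volumes=config.wedge.cycle_volumes,
        )
        # a voxel counts as recovered when the mapped angle is within one
        # 45-degree bin of its true (continuous) preferred angle
        diff = np.abs(pm.angle - data_sub.region_truth.preferred_angle)
        circ = np.minimum(diff, 360.0 - diff)
        mapped = data_sub.region_truth.labels != "outside"
        bin_width = 360.0 / pm.n_shifts
        phase_recovery = float(np.mean(circ[mapped] <= bin_width))

    saccade_count = None
    fixation_tests = None
    if data_sub.gaze:
        saccade_count = sum(len(eyetrack.detect_saccades(tr)) for tr in data_sub.gaze)
        expr = [data_sub.gaze[r] for r in range(data_sub.design.n_runs) if data_sub.design.task_per_run[r] == "expression"]
        gend = [data_sub.gaze[r] for r in range(data_sub.design.n_runs) if data_sub.design.task_per_run[r] == "gender"]
        if len(expr) >= 2 and len(gend) >= 2:
            fixation_tests = eyetrack.compare_fixation(expr, gend)

    return SubjectResult(
        subject=data_sub.subject,
        pois=pois,
        accuracies=accuracies,
        timecourses=timecourses,
        peaks=peaks,
        curves=pd.concat(curves_frames, ignore_index=True) if curves_frames else None,
        phase_recovery=phase_recovery,
        saccade_count=saccade_count,
        fixation_tests=fixation_tests,
    )


# ---------------------------------------------------------------------------
# group level
# ---------------------------------------------------------------------------


@dataclass
class Report:
    """Bundle of group-level result tables plus the run manifest."""

    decoding_table: pd.DataFrame
    anovas: pd.DataFrame
    timecourses: pd.DataFrame
    timepoint_tests: pd.DataFrame
    poi_summary: pd.DataFrame
    phase_summary: pd.DataFrame
    gaze_summary: pd.DataFrame
    curves: pd.DataFrame | None
    manifest: dict


def _group_decoding_table(results: list[SubjectResult]) -> pd.DataFrame:
    frames = []
    for res in results:
        df = res.accuracies.copy()
        df["subject"] = res.subject
        frames.append(df)
    allacc = pd.concat(frames, ignore_index=True)
    rows = []
    for (task, classification, region, mode), grp in allacc.groupby(
        ["task", "classification", "region", "test_mode"], observed=True
    ):
        vals = grp["accuracy"].dropna().to_numpy()
        chance = 100.0 / len(CLASSIFICATIONS[classification])
        row = {
            "task": task,
            "classification": classification,
            "region": region,
            "test_mode": mode,
            "n": vals.size,
            "mean_accuracy": float(vals.mean()) if vals.size else np.nan,
            "chance": chance,
        }
        if vals.size >= 2:
            gt = mvpa.group_performance_test(vals, chance)
            row.update({"t": gt.t, "p": gt.p, "dof": gt.dof})
        else:
            row.update({"t": np.nan, "p": np.nan, "dof": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def _group_anovas(results: list[SubjectResult]) -> pd.DataFrame:
    peaks = pd.concat([r.peaks.assign(subject=r.subject) for r in results], ignore_index=True)
    out = []
    for family in ("expression", "gender"):
        for measure in ("peak", "window"):
            sub = peaks.loc[(peaks["family"] == family) & peaks["region"].isin(["eye", "mouth"])]
            data = sub.rename(columns={"level": "classification", measure: "value"})[
                ["subject", "classification", "task", "region", "value"]
            ]
            complete = data.groupby("subject")["value"].count()
            keep = complete[complete == 8].index
            data = data.loc[data["subject"].isin(keep)]
            if data["subject"].nunique() < 2:
                continue
            res = stats.rm_anova(data, dv="value", factors=["classification", "task", "region"])
            tab = res.table.copy()
            tab.insert(0, "analysis", f"{family}_{measure}")
            out.append(tab)
    # three-way ANOVA on averaged-pattern decoding accuracies
    acc = pd.concat([r.accuracies.assign(subject=r.subject) for r in results], ignore_index=True)
    acc = acc.loc[
        (acc["test_mode"] == "averaged") & acc["classification"].isin(["happy_fear", "male_female"])
    ].rename(columns={"accuracy": "value"})
    complete = acc.groupby("subject")["value"].apply(lambda s: s.notna().all() and len(s) == 12)
    acc = acc.loc[acc["subject"].isin(complete[complete].index)]
    if acc["subject"].nunique() >= 2:
        res = stats.rm_anova(acc, dv="value", factors=["task", "region", "classification"])
        tab = res.table.copy()
        tab.insert(0, "analysis", "mvpa_accuracy")
        out.append(tab)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def _timepoint_tests(results: list[SubjectResult], window: tuple[float, float] = (3.0, 9.0)) -> pd.DataFrame:
    """Group t-tests of class contrasts at each deconvolution time point
    (3-9 s), Holm-corrected within each task x region family."""
    tcs = pd.concat([r.timecourses.assign(subject=r.subject) for r in results], ignore_index=True)
    pairs = {"expression": ("happy", "fearful"), "gender": ("female", "male")}
    rows = []
    for (family, task, region), grp in tcs.groupby(["family", "task", "region"], observed=True):
        a, b = pairs[family]
        bins = sorted(t for t in grp["bin_s"].unique() if window[0] <= t <= window[1])
        pvals, stats_rows = [], []
        for t_bin in bins:
            sub = grp.loc[grp["bin_s"] == t_bin]
            piv = sub.pivot_table(index="subject", columns="level", values="beta")
            if a not in piv or b not in piv or len(piv) < 2:
                continue
            diff = (piv[a] - piv[b]).dropna()
            from scipy import stats as sps

            t, p = sps.ttest_1samp(diff, 0.0)
            pvals.append(p)
            stats_rows.append({"family": family, "task": task, "region": region, "bin_s": t_bin, "t": float(t), "p": float(p)})
        if pvals:
            reject = stats.holm_bonferroni(np.array(pvals), alpha=0.05)
            for row, rej in zip(stats_rows, reject):
                row["significant_holm"] = bool(rej)
                rows.append(row)
    return pd.DataFrame(rows)


def run_experiment(config: PipelineConfig, seed: int, out_dir=None) -> Report:
    """Simulate and analyze a full cohort, returning the report bundle."""
    results = []
    poi_rows = []
    phase_rows = []
    gaze_rows = []
    for s in range(config.n_subjects):
        data_sub = simulate_subject(config, seed, s)
        res = analyze_subject(data_sub, config, master_seed=seed)
        results.append(res)
        truth = data_sub.region_truth
        for name, p in res.pois.items():
            truth_idx = set(truth.indices(name if name != "rest_v1" else "rest_v1").tolist())
            got = set(p.voxel_indices.tolist())
            poi_rows.append(
                {
                    "subject": s,
                    "region": name,
                    "size": p.size,
                    "truth_size": len(truth_idx),
                    "jaccard_vs_truth": len(got & truth_idx) / max(1, len(got | truth_idx)),
                }
            )
        if res.phase_recovery is not None:
            phase_rows.append({"subject": s, "angle_recovery": res.phase_recovery})
        if res.saccade_count is not None:
            row = {"subject": s, "saccades": res.saccade_count}
            if res.fixation_tests:
                for axis, (t, p) in res.fixation_tests.items():
                    row[f"{axis}_t"], row[f"{axis}_p"] = t, p
            gaze_rows.append(row)

    report = Report(
        decoding_table=_group_decoding_table(results),
        anovas=_group_anovas(results),
        timecourses=pd.concat([r.timecourses.assign(subject=r.subject) for r in results], ignore_index=True),
        timepoint_tests=_timepoint_tests(results),
        poi_summary=pd.DataFrame(poi_rows),
        phase_summary=pd.DataFrame(phase_rows),
        gaze_summary=pd.DataFrame(gaze_rows),
        curves=(
            pd.concat([r.curves.assign(subject=r.subject) for r in results if r.curves is not None], ignore_index=True)
            if any(r.curves is not None for r in results)
            else None
        ),
        manifest={"seed": seed, "n_subjects": config.n_subjects, "config": config.to_dict()},
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def null_decoding_calibration(
    n_seeds: int = 50,
    seed: int = 0,
    trials_per_class_per_run: int = 20,
    n_runs: int = 6,
    n_voxels: int = 60,
    sigma: float = 1.0,
    test_mode: str = "single_trial",
) -> np.ndarray:
    """Chance-level calibration of the full decoding stage.

    For each of ``n_seeds`` independent datasets: simulate a six-run BOLD
    experiment with two face classes whose amplitudes are identical (labels
    carry no information), estimate single-trial betas, and run the complete
    decoding stage (training-set min-max normalization, linear SVM with
    C = 1, leave-one-run-out).  Returns the per-dataset accuracies (%); their
    mean estimates the empirical chance level, nominally 50%.
    """
    conditions = ("happy", "fearful")
    hrf = double_gamma_hrf()
    accs = []
    for i in range(n_seeds):
        design = make_design(
            n_runs=n_runs,
            trials_per_condition=trials_per_class_per_run * n_runs,
            conditions=conditions,
            seed=_derive_seed(seed, i, 0),
        )
        region = make_region_truth(n_eye=0, n_mouth=0, n_rest=n_voxels, n_outside=0, seed=_derive_seed(seed, i, 1))
        pattern = make_pattern_truth(
            region, conditions=conditions, noise_sigma=sigma,
            expression_cnr=0.0, gender_cnr=0.0, seed=0,
        )
        betas, labels, run_ids = [], [], []
        for r in range(n_runs):
            noise = NoiseModel(sigma=sigma, seed=_derive_seed(seed, i, 2, r))
            run = preprocess.preprocess_run(simulate_run(design, r, region, pattern, noise, hrf))
            events = design.run_events(r)
            X = build_single_trial_design(events, hrf, n_volumes=design.n_volumes(r), tr=design.tr)
            est = fit_ols(X, run)
            betas.append(est.betas[: len(events)])
            labels.append(events["trial_type"].to_numpy())
            run_ids.append(np.full(len(events), r))
        patterns = mvpa.TrialPatternSet(
            betas=np.concatenate(betas),
            labels=np.concatenate(labels),
            run_ids=np.concatenate(run_ids),
        )
        accs.append(mvpa.loro_cv(patterns, cost=1.0, test_mode=test_mode).accuracy)
    return np.asarray(accs)


def write_report(report: Report, out_dir) -> None:
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.decoding_table.to_csv(out / "decoding_table.tsv", sep="\t", index=False)
    report.anovas.to_csv(out / "anovas.tsv", sep="\t", index=False)
    report.timecourses.to_csv(out / "timecourses.tsv", sep="\t", index=False)
    report.timepoint_tests.to_csv(out / "timepoint_tests.tsv", sep="\t", index=False)
    report.poi_summary.to_csv(out / "poi_summary.tsv", sep="\t", index=False)
    report.phase_summary.to_csv(out / "phase_summary.tsv", sep="\t", index=False)
    report.gaze_summary.to_csv(out / "gaze_summary.tsv", sep="\t", index=False)
    if report.curves is not None:
        report.curves.to_csv(out / "set_size_curves.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
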