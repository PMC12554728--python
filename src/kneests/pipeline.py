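"""End-to-end orchestration: synthetic cohort -> four protocol models ->
tracking -> knee angles/moments -> STS segmentation -> normalized curves ->
MAV/MAD/effect-size tables and SPM comparisons.

The default run mirrors the study design: 24 subjects, three STS
repetitions each, analysed bilaterally under the four protocol
configurations (IOR_IK, IOR_6DoF, CAST_IK, CAST_6DoF).  Segmentation is
per-protocol by default (each protocol's own hip kinematics drive the
event rules); a shared-segmentation mode uses one reference protocol's
events for all, isolating modelling effects from event-timing effects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import PROTOCOLS, SubjectModel, build_subject_model
from .dynamics import knee_moment_series
from .errors import InvalidParameterError, KneeStsError
from .events import EventDetectionConfig, STSEvents, average_repetitions, \
    crop_and_normalize, detect_sts_events
from .io import (FilterSpec, MARKER_CUTOFF_HZ, TrialData, butterworth_lowpass,
                 fill_gaps, resample_to_marker_rate)
from .metrics import (ANGLE_VARIABLES, VARIABLES, protocol_pairs,
                      summarize_cohort)
from .pose import joint_angle_series, solve_6dof_trajectory, \
    solve_ik_trajectory
from .spm import SPMConfig, SPMResult, spm_paired_test
from .synthetic import (ArtifactConfig, SyntheticProtocolConfig,
                        generate_cohort)

SIDE_LABELS = ("tka", "contralateral")


@dataclass
class PipelineConfig:
    n_subjects: int = 24
    seed: int = 7
    protocols: tuple[str, ...] = PROTOCOLS
    protocol_config: SyntheticProtocolConfig = field(
        default_factory=SyntheticProtocolConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    event_config: EventDetectionConfig = field(
        default_factory=EventDetectionConfig)
    spm_config: SPMConfig = field(default_factory=SPMConfig)
    shared_segmentation: bool = False
    resolution_frame: str = "proximal"
    max_gap_frames: int = 10
    run_spm: bool = True
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if len(self.protocols) < 2:
            raise InvalidParameterError(
                "need >= 2 protocols for a comparison")
        for p in self.protocols:
            if p not in PROTOCOLS:
                raise InvalidParameterError(f"unknown protocol {p!r}")


@dataclass
class StudyReport:
    """Cohort-level result tables and QC of one pipeline run."""

    mav_table: pd.DataFrame  # variables x sides
    mad_table: pd.DataFrame  # pairs x (variable, side), numeric
    mad_flagged: pd.DataFrame  # same shape, strings with * flags (angles)
    effect_table: pd.DataFrame  # pairs x (variable, side): d [lo, hi]
    spm_table: pd.DataFrame | None
    qc: pd.DataFrame  # per subject/trial/protocol events + fit residuals
    curves: dict  # (subject, protocol, side, variable) -> (101,) mean curve
    spm_results: dict  # (pair, variable, side) -> SPMResult
    config_echo: dict

    def to_json_dict(self) -> dict:
        def df_dict(df: pd.DataFrame | None):
            if df is None:
                return None
            out = df.copy()
            if isinstance(out.columns, pd.MultiIndex):
                out.columns = [" / ".join(map(str, c)) for c in out.columns]
            if isinstance(out.index, pd.MultiIndex):
                out.index = [" / ".join(map(str, i)) for i in out.index]
            return json.loads(out.to_json(orient="index"))

        return {
            "config": self.config_echo,
            "mav": df_dict(self.mav_table),
            "mad": df_dict(self.mad_table),
            "mad_flagged": df_dict(self.mad_flagged),
            "effect_sizes": df_dict(self.effect_table),
            "spm": df_dict(self.spm_table),
            "qc": df_dict(self.qc),
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=1, sort_keys=True),
            encoding="utf-8")
        self.mav_table.to_csv(outdir / "mav.tsv", sep="\t")
        self.mad_flagged.to_csv(outdir / "mad.tsv", sep="\t")
        self.effect_table.to_csv(outdir / "effect_sizes.tsv", sep="\t")
        if self.spm_table is not None:
            self.spm_table.to_csv(outdir / "spm.tsv", sep="\t")


# ---------------------------------------------------------------------------
# single-trial processing


def _filtered_markers(trial: TrialData, max_gap_frames: int) -> TrialData:
    """Gap-fill and low-pass (6 Hz zero-phase) the marker trajectories."""
    pos = trial.marker_positions.copy()
    for m in range(pos.shape[1]):
        filled, unfilled = fill_gaps(pos[:, m, :], max_gap_frames)
        if unfilled:
            raise InvalidParameterError(
                f"marker {trial.marker_labels[m]} has unfillable gaps "
                f"{unfilled}")
        pos[:, m, :] = filled
    spec = FilterSpec(cutoff=MARKER_CUTOFF_HZ)
    pos = butterworth_lowpass(pos, spec, trial.marker_rate, axis=0)
    return TrialData(
        marker_positions=pos, marker_labels=list(trial.marker_labels),
        marker_rate=trial.marker_rate, analog_rate=trial.analog_rate,
        plate_forces=trial.plate_forces, plate_cops=trial.plate_cops,
        plate_free_moments=trial.plate_free_moments,
        body_mass=trial.body_mass, side_map=dict(trial.side_map),
        meta=dict(trial.meta))


def _plates_at_marker_rate(trial: TrialData
                           ) -> dict[str, dict[str, np.ndarray]]:
    """50 Hz-filtered, decimated per-side plate signals."""
    out = {}
    for side, plate in trial.side_map.items():
        out[side] = {
            "force": resample_to_marker_rate(
                trial.plate_forces[plate], trial.analog_rate,
                trial.marker_rate),
            "cop": resample_to_marker_rate(
                trial.plate_cops[plate], trial.analog_rate,
                trial.marker_rate),
            "free_mz": resample_to_marker_rate(
                trial.plate_free_moments[plate], trial.analog_rate,
                trial.marker_rate),
        }
    return out


def process_trial(trial: TrialData, model: SubjectModel,
                  event_config: EventDetectionConfig | None = None,
                  events: STSEvents | None = None,
                  event_side: str = "right",
                  resolution_frame: str = "proximal",
                  max_gap_frames: int = 10,
                  ) -> dict:
    """Run one protocol over one dynamic trial.

    Returns a dict with ``events``, per-side knee ``angles`` (101, 3) and
    ``moments`` (101, 3) normalized curves, and fit QC.  If ``events`` is
    given it is used as-is (shared-segmentation mode).
    """
    event_config = event_config or EventDetectionConfig()
    filtered = _filtered_markers(trial, max_gap_frames)
    if model.joint_model == "ik":
        poses = solve_ik_trajectory(filtered, model)
    else:
        poses = solve_6dof_trajectory(filtered, model)
    plates = _plates_at_marker_rate(trial)
    vgrf = sum(p["force"][:, 2] for p in plates.values())

    if events is None:
        hip = joint_angle_series(poses, "hip", event_side, model)
        hip_height = poses.joint_center(model, "hip", event_side)[:, 2]
        events = detect_sts_events(hip.flexion, vgrf, hip_height,
                                   trial.marker_rate, event_config)

    out = {"events": events, "angles": {}, "moments": {},
           "residual_rms": {name: float(np.nanmean(res)) for name, res
                            in poses.residuals.items()}}
    for side in ("right", "left"):
        knee = joint_angle_series(poses, "knee", side, model)
        out["angles"][side] = crop_and_normalize(knee.angles, events)
        moments = knee_moment_series(
            poses, model, plates[side]["force"], plates[side]["cop"],
            plates[side]["free_mz"], side, resolution_frame)
        out["moments"][side] = crop_and_normalize(moments.moments, events)
    return out


def process_subject(entry: dict, protocols: tuple[str, ...],
                    event_config: EventDetectionConfig,
                    shared_segmentation: bool = False,
                    resolution_frame: str = "proximal",
                    max_gap_frames: int = 10) -> tuple[dict, list[dict]]:
    """All protocols over all repetitions of one cohort entry.

    Returns ``(curves, qc_rows)``: ``curves[(protocol, side_label,
    variable)]`` is the repetition-mean (101,) curve, sides keyed by
    clinical label (``tka`` / ``contralateral``).
    """
    subject = entry["subject"]
    static = entry["static"]
    models = {p: build_subject_model(
        static, p.split("_")[0], "ik" if p.endswith("_IK") else "6dof",
        body_mass=subject.body_mass, stature=subject.stature)
        for p in protocols}
    event_side = subject.side_labels["tka"]

    per_rep: dict[tuple[str, str, str], list[np.ndarray]] = {}
    qc_rows: list[dict] = []
    for rep, (trial, _truth) in enumerate(entry["trials"]):
        shared_events: STSEvents | None = None
        for p in protocols:
            res = process_trial(
                trial, models[p], event_config,
                events=shared_events if shared_segmentation else None,
                event_side=event_side, resolution_frame=resolution_frame,
                max_gap_frames=max_gap_frames)
            if shared_segmentation and shared_events is None:
                shared_events = res["events"]
            for clinical, side in subject.side_labels.items():
                ang = res["angles"][side]
                mom = res["moments"][side]
                for k, var in enumerate(ANGLE_VARIABLES):
                    per_rep.setdefault((p, clinical, var), []).append(
                        ang[:, k])
                for k, var in enumerate(("KFM", "KAM", "KIRM")):
                    per_rep.setdefault((p, clinical, var), []).append(
                        mom[:, k])
            qc_rows.append({
                "subject": subject.subject_id, "repetition": rep,
                "protocol": p, **res["events"].as_dict(),
                "mean_residual_mm": float(np.mean(
                    list(res["residual_rms"].values()))),
            })
    curves = {}
    for key, reps in per_rep.items():
        mean, _sd = average_repetitions(reps) if len(reps) > 1 \
            else (reps[0], np.zeros_like(reps[0]))
        curves[key] = mean
    return curves, qc_rows


# ---------------------------------------------------------------------------
# cohort run


def run_pipeline(config: PipelineConfig | None = None) -> StudyReport:
    """Full synthetic-cohort analysis; deterministic given ``config.seed``."""
    config = config or PipelineConfig()
    cohort = generate_cohort(config.n_subjects, config.protocol_config,
                             config.artifact, seed=config.seed)
    curve_store: dict = {}
    qc_rows: list[dict] = []
    for entry in cohort:
        subj_id = entry["subject"].subject_id
        curves, rows = process_subject(
            entry, config.protocols, config.event_config,
            config.shared_segmentation, config.resolution_frame,
            config.max_gap_frames)
        for (p, side, var), curve in curves.items():
            curve_store[(subj_id, p, side, var)] = curve
        qc_rows.extend(rows)

    report = build_report(curve_store, config)
    report.qc = pd.DataFrame(qc_rows)
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report


def build_report(curve_store: dict, config: PipelineConfig) -> StudyReport:
    """Cohort statistics tables from a populated curve store."""
    variability, pairwise, effects = summarize_cohort(
        curve_store, config.protocols, SIDE_LABELS)
    pairs = protocol_pairs(config.protocols)

    mav_table = pd.DataFrame(
        {f"MAV_{side}": [variability.mav_mean[(v, side)] for v in VARIABLES]
         for side in SIDE_LABELS}, index=list(VARIABLES))

    pair_names = [f"{a} vs {b}" for a, b in pairs]
    cols = pd.MultiIndex.from_product([VARIABLES, SIDE_LABELS])
    mad_table = pd.DataFrame(index=pair_names, columns=cols, dtype=float)
    mad_flagged = pd.DataFrame(index=pair_names, columns=cols, dtype=object)
    effect_table = pd.DataFrame(index=pair_names, columns=cols, dtype=object)
    for (pair, var, side), value in pairwise.mad_mean.items():
        name = f"{pair[0]} vs {pair[1]}"
        mad_table.loc[name, (var, side)] = value
        flag = pairwise.clinical_flags.get((pair, var, side), False)
        mad_flagged.loc[name, (var, side)] = (
            f"{value:.2f}*" if flag else f"{value:.2f}")
    for (pair, var, side), (d, lo, hi) in effects.d.items():
        name = f"{pair[0]} vs {pair[1]}"
        effect_table.loc[name, (var, side)] = f"{d:.2f} [{lo:.2f}, {hi:.2f}]"

    spm_results: dict = {}
    spm_table = None
    if config.run_spm:
        subjects = sorted({k[0] for k in curve_store})
        rows = []
        for pair in pairs:
            for var in VARIABLES:
                for side in SIDE_LABELS:
                    a = np.stack([curve_store[(s, pair[0], side, var)]
                                  for s in subjects])
                    b = np.stack([curve_store[(s, pair[1], side, var)]
                                  for s in subjects])
                    row = {"pair": f"{pair[0]} vs {pair[1]}",
                           "variable": var, "side": side}
                    try:
                        res = spm_paired_test(a, b, config.spm_config)
                    except InvalidParameterError as exc:
                        # tiny cohorts can push the RFT threshold out of
                        # range; report the comparison as not evaluable
                        row.update({"t_star": np.nan, "fwhm": np.nan,
                                    "n_clusters": 0, "significant": False,
                                    "clusters": f"not evaluable: {exc}"})
                        rows.append(row)
                        continue
                    spm_results[(pair, var, side)] = res
                    row.update({
                        "t_star": res.critical_threshold,
                        "fwhm": res.fwhm,
                        "n_clusters": len(res.clusters),
                        "significant": res.significant,
                        "clusters": "; ".join(
                            f"[{c.start:.1f}, {c.end:.1f}]"
                            for c in res.clusters),
                    })
                    rows.append(row)
        spm_table = pd.DataFrame(rows)

    config_echo = {
        "n_subjects": config.n_subjects, "seed": config.seed,
        "protocols": list(config.protocols),
        "shared_segmentation": config.shared_segmentation,
        "resolution_frame": config.resolution_frame,
        "protocol_config": asdict(config.protocol_config),
        "artifact": asdict(config.artifact),
        "event_config": {
            "grf_threshold": config.event_config.grf_threshold,
            "stand_tolerance": config.event_config.stand_tolerance,
            "baseline_mode": config.event_config.baseline_mode},
        "spm": {"alpha": config.spm_config.alpha,
                "two_tailed": config.spm_config.two_tailed,
                "method": config.spm_config.method},
        "note": ("per-comparison SPM results are reported without "
                 "multiple-comparison correction across protocol pairs "
                 "and variables"),
    }
    return StudyReport(
        mav_table=mav_table, mad_table=mad_table, mad_flagged=mad_flagged,
        effect_table=effect_table, spm_table=spm_table,
        qc=pd.DataFrame(), curves=curve_store, spm_results=spm_results,
        config_echo=config_echo)


def stage_error(stage: str, exc: Exception) -> KneeStsError:
    """Wrap an exception with a pipeline stage tag."""
    return KneeStsError(f"[stage: {stage}] {exc}")
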