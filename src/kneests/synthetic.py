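"""Synthetic sit-to-stand (STS) cohort generator with known ground truth.

The generator emulates the study conditions the analysis assumes: a static
T-pose calibration trial and three STS repetitions per subject, recorded
with the combined IOR+CAST marker complement at 100 Hz and two force
plates at 1000 Hz.  Each repetition starts seated at a 43 cm seat with
90 deg knee flexion, rises, holds standing for 2 s, and sits back down.

Motion is built in the sagittal plane from per-subject quintic
(minimum-jerk) keyframe profiles of three generalized angles — shank
pitch, knee flexion and pelvis pitch — with the feet planted on the
plates and the pelvis position closed through the right-leg chain.
Ground-truth segment poses, joint angles, events and whole-body-consistent
plate signals all derive from that construction; in particular the "true"
anatomy is defined operationally, as whatever the calibration conventions
produce from the noise-free T-pose markers, so noise-free calibration
recovers it exactly.

Soft-tissue artifact (STA) is modelled as band-limited Gaussian marker
displacement in the segment frame, with a knee-flexion-coupled component
on the thigh skin markers; cluster plates move rigidly and with smaller
amplitude.  Identical seeds give bit-identical outputs, and artifact
fields are generated at unit amplitude before scaling, so amplitude sweeps
at a fixed seed rescale the same realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .calibration import (TRUNK_LENGTH_FRACTION, SegmentInertia,
                          StaticCalibration, build_segment_frames,
                          compute_inertial_parameters)
from .errors import InvalidParameterError
from .geometry import angular_velocity_from_rotations, central_difference
from .io import GRAVITY, TrialData
from .markersets import SIDE_PREFIX, SIDES, load_marker_set

_CLUSTER_GROUPS = ("TH", "SK")


def _pitch_series(angles_rad: np.ndarray) -> np.ndarray:
    """Rotations about lab -Y ("pitch"): positive tips the distal end of an
    upright segment anteriorly."""
    c, s = np.cos(angles_rad), np.sin(angles_rad)
    out = np.zeros((len(angles_rad), 3, 3))
    out[:, 0, 0] = c
    out[:, 0, 2] = -s
    out[:, 1, 1] = 1.0
    out[:, 2, 0] = s
    out[:, 2, 2] = c
    return out


@dataclass
class AnthropometryParams:
    """Sampling distributions for the synthetic cohort (elderly, high-BMI)."""

    stature_mean: float = 1680.0  # mm
    stature_sd: float = 70.0
    bmi_mean: float = 28.9  # kg m^-2
    bmi_sd: float = 3.8
    placement_jitter_sd: float = 3.0  # mm, marker placement variability

    def __post_init__(self) -> None:
        if self.stature_mean <= 0 or self.bmi_mean <= 0:
            raise InvalidParameterError("stature and BMI means must be positive")
        if min(self.stature_sd, self.bmi_sd, self.placement_jitter_sd) < 0:
            raise InvalidParameterError("spreads must be non-negative")


@dataclass
class SyntheticProtocolConfig:
    """Task and acquisition settings for one STS recording."""

    seat_height: float = 430.0  # mm
    initial_knee_flexion: float = 90.0  # deg
    stand_hold: float = 2.0  # s
    n_repetitions: int = 3
    marker_rate: float = 100.0  # Hz
    analog_rate: float = 1000.0  # Hz
    rng_seed: int = 0
    #: per-foot vertical load while seated (N); near-zero by default so the
    #: literal 10 N seat-off rule is well defined on synthetic data.  Use
    #: :func:`realistic_seated_load` for a shank+foot-weight alternative.
    seated_foot_load: float = 5.0
    #: optional constant anterior shank offset (mm) emulating tibial drawer
    tibial_drawer_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.marker_rate <= 0 or self.analog_rate <= 0:
            raise InvalidParameterError("sampling rates must be positive")
        ratio = self.analog_rate / self.marker_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidParameterError(
                "analog_rate must be an integer multiple of marker_rate")
        if not 0.0 < self.initial_knee_flexion < 160.0:
            raise InvalidParameterError(
                "initial_knee_flexion must lie in (0, 160) deg")
        if self.stand_hold <= 0:
            raise InvalidParameterError("stand_hold must be positive")
        if self.n_repetitions < 1:
            raise InvalidParameterError("n_repetitions must be >= 1")
        if self.seat_height <= 0:
            raise InvalidParameterError("seat_height must be positive")


@dataclass
class ArtifactConfig:
    """Soft-tissue artifact and measurement-noise settings."""

    skin_amplitude: float = 10.0  # mm, random STA on skin markers
    cluster_amplitude: float = 3.0  # mm, rigid plate STA (<= skin)
    flexion_coupled_amplitude: float = 15.0  # mm at 90 deg knee flexion
    sta_bandwidth: float = 2.0  # Hz
    measurement_noise_sd: float = 0.3  # mm
    rng_seed: int = 0
    #: extra multiplier on the thigh skin-marker artifact only (random +
    #: flexion-coupled); the lever for artifact-sensitivity sweeps
    thigh_skin_scale: float = 1.0

    def __post_init__(self) -> None:
        amps = (self.skin_amplitude, self.cluster_amplitude,
                self.flexion_coupled_amplitude, self.measurement_noise_sd)
        if min(amps) < 0:
            raise InvalidParameterError("amplitudes must be >= 0")
        if self.cluster_amplitude > self.skin_amplitude \
                and self.skin_amplitude > 0:
            raise InvalidParameterError("cluster STA must not exceed skin STA")
        if self.sta_bandwidth <= 0:
            raise InvalidParameterError("sta_bandwidth must be positive")

    def scaled(self, factor: float) -> "ArtifactConfig":
        """Same realization seed, STA amplitudes multiplied by ``factor``."""
        return replace(
            self,
            skin_amplitude=self.skin_amplitude * factor,
            cluster_amplitude=self.cluster_amplitude * factor,
            flexion_coupled_amplitude=self.flexion_coupled_amplitude * factor)

    def scaled_skin(self, factor: float) -> "ArtifactConfig":
        """Scale only the thigh skin-marker artifact (cluster, pelvis, shank
        and foot STA unchanged); used for artifact-sensitivity sweeps at a
        fixed realization seed."""
        return replace(self, thigh_skin_scale=self.thigh_skin_scale * factor)


NOISE_FREE = ArtifactConfig(skin_amplitude=0.0, cluster_amplitude=0.0,
                            flexion_coupled_amplitude=0.0,
                            measurement_noise_sd=0.0)


@dataclass
class SyntheticSubject:
    """A ground-truth-known synthetic participant."""

    subject_id: str
    body_mass: float  # kg
    stature: float  # mm
    segment_lengths: dict[str, float]  # mm (includes layout dimensions)
    tpose_positions: dict[str, np.ndarray]  # label -> lab mm, T-pose
    marker_segments: dict[str, str]  # label -> segment name
    true_marker_locals: dict[str, np.ndarray]  # label -> segment-frame mm
    true_frames: dict[str, tuple[np.ndarray, np.ndarray]]  # (R0, origin0)
    true_joint_centers: dict[str, np.ndarray]  # parent-frame mm
    inertia: dict[str, SegmentInertia]
    com_locals: dict[str, np.ndarray]  # segment-frame mm
    hat_com_in_pelvis: np.ndarray
    side_labels: dict[str, str] = field(
        default_factory=lambda: {"tka": "right", "contralateral": "left"})
    motion_params: dict[str, float] = field(default_factory=dict)
    sta_directions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise InvalidParameterError("body_mass must be positive")
        if self.stature <= 0:
            raise InvalidParameterError("stature must be positive")
        for name, value in self.segment_lengths.items():
            if value <= 0:
                raise InvalidParameterError(
                    f"segment length {name!r} must be positive")


@dataclass
class GroundTruth:
    """Generator bookkeeping attached to each dynamic trial."""

    segment_poses: dict[str, tuple[np.ndarray, np.ndarray]]  # (R, origin)
    joint_angle_curves: dict[tuple[str, str], np.ndarray]  # (joint, side)
    event_frames: dict[str, int]
    marker_rate: float
    aux: dict = field(default_factory=dict)


def realistic_seated_load(subject: SyntheticSubject) -> float:
    """Per-foot seated baseline load carrying the shank+foot weight (N)."""
    return (subject.inertia["shank"].mass
            + subject.inertia["foot"].mass) * GRAVITY


# ---------------------------------------------------------------------------
# subject construction


def _nominal_tpose(stature: float) -> tuple[dict[str, np.ndarray],
                                            dict[str, float]]:
    """Nominal T-pose marker layout and key dimensions (mm, lab frame)."""
    h = stature
    d = 0.143 * h  # inter-ASIS distance
    depth = 0.09 * h
    ankle_z = 0.039 * h
    knee_z = ankle_z + 0.246 * h
    hjc_z = 0.530 * h
    asis_z = hjc_z + 0.30 * d  # Bell distal offset puts the HJC at hjc_z
    foot_len = 0.152 * h
    thigh_len = hjc_z - knee_z
    shank_len = knee_z - ankle_z

    pos: dict[str, np.ndarray] = {}
    # mid-ASIS x chosen so the Bell hip centres sit at x = 0 (above ankles)
    pos["RASI"] = np.array([0.19 * d, -d / 2, asis_z])
    pos["LASI"] = np.array([0.19 * d, +d / 2, asis_z])
    pos["RPSI"] = np.array([0.19 * d - depth, -0.25 * d, asis_z])
    pos["LPSI"] = np.array([0.19 * d - depth, +0.25 * d, asis_z])
    for side in SIDES:
        p = SIDE_PREFIX[side]
        sgn = -1.0 if side == "right" else 1.0  # lateral direction in lab Y
        hjc = np.array([0.0, sgn * 0.36 * d, hjc_z])
        knee = np.array([0.0, sgn * 0.36 * d, knee_z])
        ankle = np.array([0.0, sgn * 0.36 * d, ankle_z])
        pos[f"{p}GT"] = hjc + [0.0, sgn * 70.0, 15.0]
        pos[f"{p}LE"] = knee + [0.0, sgn * 55.0, 0.0]
        pos[f"{p}ME"] = knee + [0.0, -sgn * 55.0, 0.0]
        pos[f"{p}FH"] = knee + [-15.0, sgn * 50.0, -70.0]
        pos[f"{p}TT"] = knee + [45.0, sgn * 5.0, -80.0]
        pos[f"{p}LM"] = ankle + [0.0, sgn * 40.0, 0.0]
        pos[f"{p}MM"] = ankle + [0.0, -sgn * 40.0, 0.0]
        heel = ankle + [-60.0, 0.0, 40.0 - ankle_z]
        pos[f"{p}CA"] = heel
        pos[f"{p}SM"] = heel + [0.90 * foot_len, 0.0, 0.0]
        pos[f"{p}FM"] = ankle + [0.55 * foot_len, -sgn * 35.0, 30.0 - ankle_z]
        pos[f"{p}VM"] = ankle + [0.45 * foot_len, sgn * 45.0, 25.0 - ankle_z]
        # rigid cluster plates (131 x 80 mm), markers inside the plate edge
        th_c = knee + np.array([0.0, sgn * 85.0, 0.55 * thigh_len])
        sk_c = ankle + np.array([10.0, sgn * 52.0, 0.55 * shank_len])
        for name, center, dx, dz in (("TH", th_c, 35.0, 60.0),
                                     ("SK", sk_c, 30.0, 55.0)):
            pos[f"{p}{name}1"] = center + [+dx, 0.0, +dz]
            pos[f"{p}{name}2"] = center + [-dx, 0.0, +dz]
            pos[f"{p}{name}3"] = center + [-dx, 0.0, -dz]
            pos[f"{p}{name}4"] = center + [+dx, 0.0, -dz]
    dims = {"inter_asis": d, "ankle_z": ankle_z, "knee_z": knee_z,
            "hjc_z": hjc_z, "foot_length": foot_len,
            "thigh_length": thigh_len, "shank_length": shank_len}
    return pos, dims


def _marker_segment_map() -> dict[str, str]:
    out: dict[str, str] = {}
    for set_name in ("IOR", "CAST"):
        spec = load_marker_set(set_name)
        for seg in spec.segments.values():
            for lab in seg.markers:
                out.setdefault(lab, seg.segment)
    return out


def _rotation_from_rotvec(rotvec: np.ndarray) -> np.ndarray:
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-12:
        return np.eye(3)
    axis = rotvec / angle
    k_mat = np.array([[0.0, -axis[2], axis[1]],
                      [axis[2], 0.0, -axis[0]],
                      [-axis[1], axis[0], 0.0]])
    return np.eye(3) + np.sin(angle) * k_mat \
        + (1.0 - np.cos(angle)) * (k_mat @ k_mat)


def generate_subject(params: AnthropometryParams | None = None,
                     rng_seed: int = 0,
                     subject_id: str | None = None) -> SyntheticSubject:
    """Sample one synthetic subject with the combined IOR+CAST marker set.

    Anatomical markers get independent placement jitter; cluster plates are
    jittered rigidly (common translation + small rotation), preserving
    their coplanarity.  True frames and joint centres are then derived from
    the jittered T-pose with the calibration conventions.
    """
    params = params or AnthropometryParams()
    rng = np.random.default_rng(np.random.SeedSequence([77001, rng_seed]))
    stature = float(np.clip(
        rng.normal(params.stature_mean, params.stature_sd),
        params.stature_mean - 2.5 * params.stature_sd,
        params.stature_mean + 2.5 * params.stature_sd))
    bmi = float(np.clip(rng.normal(params.bmi_mean, params.bmi_sd),
                        params.bmi_mean - 2.5 * params.bmi_sd,
                        params.bmi_mean + 2.5 * params.bmi_sd))
    body_mass = bmi * (stature / 1000.0) ** 2
    if body_mass <= 0 or stature <= 0:
        raise InvalidParameterError("sampled non-positive anthropometry")

    pos, dims = _nominal_tpose(stature)
    seg_of = _marker_segment_map()
    jit = params.placement_jitter_sd
    for lab in pos:
        if lab[1:3] not in _CLUSTER_GROUPS:
            pos[lab] = pos[lab] + rng.normal(0.0, jit, 3)
    for side in SIDES:
        p = SIDE_PREFIX[side]
        for grp in _CLUSTER_GROUPS:
            labs = [f"{p}{grp}{i}" for i in range(1, 5)]
            center = np.mean([pos[lab] for lab in labs], axis=0)
            shift = rng.normal(0.0, jit, 3)
            rot = _rotation_from_rotvec(rng.normal(0.0, 0.02, 3))
            for lab in labs:
                pos[lab] = center + shift + rot @ (pos[lab] - center)

    calib = StaticCalibration(
        mean_positions={k: v.copy() for k, v in pos.items()},
        residual_sd={k: 0.0 for k in pos}, n_frames_used=1)
    skel = build_segment_frames(calib)

    locals_: dict[str, np.ndarray] = {}
    for lab, point in pos.items():
        rot, org = skel.frames[seg_of[lab]]
        locals_[lab] = rot.T @ (point - org)

    joint_centers: dict[str, np.ndarray] = {}
    lengths = dict(dims)
    for side in SIDES:
        p = SIDE_PREFIX[side]
        hjc = skel.joint_centers_lab[f"hip_{side}"]
        knee = skel.joint_centers_lab[f"knee_{side}"]
        ankle = skel.joint_centers_lab[f"ankle_{side}"]
        joint_centers[f"hip_{side}"] = skel.hip_centers_local[side]
        rot_t, org_t = skel.frames[f"thigh_{side}"]
        joint_centers[f"knee_{side}"] = rot_t.T @ (knee - org_t)
        rot_s, org_s = skel.frames[f"shank_{side}"]
        joint_centers[f"ankle_{side}"] = rot_s.T @ (ankle - org_s)
        rot_f, org_f = skel.frames[f"foot_{side}"]
        joint_centers[f"ankle_in_foot_{side}"] = rot_f.T @ (ankle - org_f)
        lengths[f"thigh_{side}"] = float(np.linalg.norm(hjc - knee))
        lengths[f"shank_{side}"] = float(np.linalg.norm(knee - ankle))
        lengths[f"foot_{side}"] = float(
            np.linalg.norm(pos[f"{p}SM"] - pos[f"{p}CA"]))

    type_lengths = {
        "thigh": 0.5 * (lengths["thigh_right"] + lengths["thigh_left"]),
        "shank": 0.5 * (lengths["shank_right"] + lengths["shank_left"]),
        "foot": 0.5 * (lengths["foot_right"] + lengths["foot_left"]),
        "hat": TRUNK_LENGTH_FRACTION * stature,
    }
    inertia = compute_inertial_parameters(body_mass, type_lengths)

    com_locals: dict[str, np.ndarray] = {"pelvis": np.zeros(3)}
    for side in SIDES:
        p = SIDE_PREFIX[side]
        for base in ("thigh", "shank"):
            com_locals[f"{base}_{side}"] = np.array(
                [0.0, 0.0, -inertia[base].com_fraction * inertia[base].length])
        rot_f, org_f = skel.frames[f"foot_{side}"]
        com_locals[f"foot_{side}"] = rot_f.T @ (
            0.5 * (pos[f"{p}CA"] + pos[f"{p}SM"]) - org_f)
    hat_com = np.array([0.0, 0.0,
                        inertia["hat"].com_fraction * type_lengths["hat"]])

    motion = {
        "lean_deg": float(np.clip(rng.normal(27.0, 4.0), 15.0, 40.0)),
        "stand_knee_deg": float(np.clip(rng.normal(3.0, 1.5), 0.0, 8.0)),
        "sway_deg": float(np.clip(rng.normal(2.0, 0.5), 0.8, 4.0)),
        "rise_duration": float(np.clip(rng.normal(1.2, 0.12), 0.8, 1.8)),
        "descend_duration": float(np.clip(rng.normal(1.5, 0.15), 1.0, 2.2)),
        "shank_pitch_deg": float(np.clip(rng.normal(11.0, 2.0), 5.0, 18.0)),
    }
    # fixed per-subject/per-marker direction of the flexion-coupled thigh
    # STA; anterior-dominant, since skin slides mostly antero-posteriorly
    # as the knee flexes
    sta_dirs: dict[str, np.ndarray] = {}
    for side in SIDES:
        p = SIDE_PREFIX[side]
        for lab in (f"{p}GT", f"{p}LE", f"{p}ME"):
            raw = rng.normal(0.0, 1.0, 3) * np.array([0.35, 1.0, 0.35])
            sta_dirs[lab] = raw / np.linalg.norm(raw)

    return SyntheticSubject(
        subject_id=subject_id or f"S{rng_seed:03d}",
        body_mass=body_mass, stature=stature,
        segment_lengths=lengths,
        tpose_positions=pos, marker_segments=seg_of,
        true_marker_locals=locals_,
        true_frames=dict(skel.frames),
        true_joint_centers=joint_centers,
        inertia=inertia, com_locals=com_locals,
        hat_com_in_pelvis=hat_com,
        motion_params=motion, sta_directions=sta_dirs,
    )


# ---------------------------------------------------------------------------
# quintic keyframe machinery


def _smoothstep5(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 + u * (-15.0 + 6.0 * u))


def _profile(t: np.ndarray, base: float,
             transitions: list[tuple[float, float, float]]) -> np.ndarray:
    """``base`` plus a sum of quintic transitions ``(t0, t1, delta)``."""
    out = np.full_like(t, base, dtype=float)
    for t0, t1, delta in transitions:
        out += delta * _smoothstep5((t - t0) / (t1 - t0))
    return out


# ---------------------------------------------------------------------------
# trial generation


def _make_plate_signals(feet_force: dict[str, np.ndarray],
                        cops: dict[str, np.ndarray],
                        free_mz: dict[str, np.ndarray],
                        n_frames: int, ratio: int
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-interpolate marker-rate plate signals onto the analog base."""
    n_analog = n_frames * ratio
    t_m = np.arange(n_frames, dtype=float)
    t_a = np.arange(n_analog, dtype=float) / ratio
    forces = np.zeros((2, n_analog, 3))
    copsa = np.zeros((2, n_analog, 3))
    freea = np.zeros((2, n_analog))
    for plate, side in enumerate(("right", "left")):
        for k in range(3):
            forces[plate, :, k] = np.interp(t_a, t_m, feet_force[side][:, k])
            copsa[plate, :, k] = np.interp(t_a, t_m, cops[side][:, k])
        freea[plate, :] = np.interp(t_a, t_m, free_mz[side])
    return forces, copsa, freea


def generate_static_trial(subject: SyntheticSubject, duration_s: float = 2.0,
                          config: SyntheticProtocolConfig | None = None,
                          artifact: ArtifactConfig | None = None
                          ) -> TrialData:
    """Static T-pose calibration trial (measurement noise only, no STA).

    Plate signals carry the body weight split evenly over the two plates.
    """
    config = config or SyntheticProtocolConfig()
    artifact = artifact or ArtifactConfig()
    if duration_s < 1.0:
        raise InvalidParameterError("static trial must last >= 1 s")
    n = int(round(duration_s * config.marker_rate))
    labels = list(subject.tpose_positions)
    base = np.stack([subject.tpose_positions[lab] for lab in labels])
    rng = np.random.default_rng(
        np.random.SeedSequence([77002, artifact.rng_seed]))
    positions = base[None, :, :] + rng.normal(
        0.0, 1.0, (n, len(labels), 3)) * artifact.measurement_noise_sd

    ratio = int(round(config.analog_rate / config.marker_rate))
    half_weight = 0.5 * subject.body_mass * GRAVITY
    feet, cops, free = {}, {}, {}
    for side in SIDES:
        p = SIDE_PREFIX[side]
        feet[side] = np.column_stack(
            [np.zeros(n), np.zeros(n), np.full(n, half_weight)])
        under_foot = 0.5 * (subject.tpose_positions[f"{p}CA"]
                            + subject.tpose_positions[f"{p}SM"])
        cops[side] = np.tile([under_foot[0], under_foot[1], 0.0], (n, 1))
        free[side] = np.zeros(n)
    forces, copsa, freea = _make_plate_signals(feet, cops, free, n, ratio)
    return TrialData(
        marker_positions=positions, marker_labels=labels,
        marker_rate=config.marker_rate, analog_rate=config.analog_rate,
        plate_forces=forces, plate_cops=copsa, plate_free_moments=freea,
        body_mass=subject.body_mass, side_map={"right": 0, "left": 1},
        meta={"kind": "static", "subject_id": subject.subject_id,
              "stature": subject.stature},
    )


def _unit_lowpass_noise(rng: np.random.Generator, n: int,
                        bandwidth: float, rate: float) -> np.ndarray:
    """Unit-SD low-pass-filtered Gaussian field of shape (n, 3)."""
    white = rng.normal(0.0, 1.0, (n, 3))
    b, a = sps.butter(2, min(bandwidth / (rate / 2.0), 0.99), btype="low")
    smooth = sps.filtfilt(b, a, white, axis=0)
    sd = smooth.std(axis=0, keepdims=True)
    sd[sd <= 0] = 1.0
    return smooth / sd


_DYNAMIC_LABELS_CACHE: set[str] | None = None


def _dynamic_label_set() -> set[str]:
    global _DYNAMIC_LABELS_CACHE
    if _DYNAMIC_LABELS_CACHE is None:
        out: set[str] = set()
        for name in ("IOR", "CAST"):
            out.update(load_marker_set(name).dynamic_labels)
        _DYNAMIC_LABELS_CACHE = out
    return _DYNAMIC_LABELS_CACHE


def _sta_amplitude(label: str, segment: str, artifact: ArtifactConfig) -> float:
    if segment == "pelvis":
        return 0.5 * artifact.skin_amplitude
    if segment.startswith("foot"):
        return 0.3 * artifact.skin_amplitude
    if segment.startswith("thigh"):
        return artifact.skin_amplitude * artifact.thigh_skin_scale
    return artifact.skin_amplitude


def _truth_events(hip_flex_deg: np.ndarray, vgrf: np.ndarray,
                  hip_z: np.ndarray, rate: float, threshold: float = 10.0,
                  tolerance_mm: float = 30.0) -> dict[str, int]:
    """Literal event rules applied to the noise-free truth signals."""
    vel = central_difference(hip_flex_deg, rate)

    def next_crossing(start: int, direction: int | None) -> int:
        last = 0.0
        for i in range(start, len(vel)):
            s = float(np.sign(vel[i]))
            if s == 0.0:
                continue
            if last != 0.0 and s != last and (direction is None
                                              or s == direction):
                return i
            last = s
        raise InvalidParameterError("truth signals contain no zero crossing")

    onset = next_crossing(1, +1)
    baseline = float(np.median(vgrf[:onset]))
    above = np.nonzero(vgrf[onset:] - baseline > threshold)[0]
    seat_off = onset + int(above[0])
    zmax = float(hip_z[seat_off:].max())
    plateau = hip_z >= zmax - tolerance_mm
    plateau[:seat_off] = False
    start = int(np.argmax(plateau))
    stop = start
    while stop + 1 < len(plateau) and plateau[stop + 1]:
        stop += 1
    below = np.nonzero(vgrf[stop + 1:] - baseline < threshold)[0]
    seat_on = stop + 1 + int(below[0])
    end = next_crossing(seat_on + 1, None)
    return {"onset": onset, "seat_off": seat_off, "stand_start": start,
            "stand_end": stop, "seat_on": seat_on, "end": end}


def _synthesize_grf(subject: SyntheticSubject,
                    poses: dict[str, tuple[np.ndarray, np.ndarray]],
                    t: np.ndarray, rate: float,
                    config: SyntheticProtocolConfig,
                    t_rise0: float, t_sit1: float):
    """Plate signals consistent with the whole-body dynamics.

    The total external wrench required by the generated kinematics
    (Dempster masses/inertias, central-difference derivatives at the marker
    rate) is split between the two plates and the seat with a smooth
    seat-unloading profile ``w``; the feet COP and free moment close the
    moment balance wherever the feet carry the load (w >= 0.5), the seat
    wrench closes it while seated.
    """
    n = len(t)
    g_vec = np.array([0.0, 0.0, -GRAVITY])
    masses: dict[str, float] = {}
    com_lab: dict[str, np.ndarray] = {}
    inert: dict[str, np.ndarray] = {}
    rots: dict[str, np.ndarray] = {}
    for side in SIDES:
        for base in ("thigh", "shank", "foot"):
            seg = f"{base}_{side}"
            rot, org = poses[seg]
            masses[seg] = subject.inertia[base].mass
            com_lab[seg] = org + np.einsum("fij,j->fi", rot,
                                           subject.com_locals[seg])
            inert[seg] = subject.inertia[base].inertia_tensor
            rots[seg] = rot
    rot_p, org_p = poses["pelvis"]
    masses["hat"] = subject.inertia["hat"].mass
    com_lab["hat"] = org_p + np.einsum("fij,j->fi", rot_p,
                                       subject.hat_com_in_pelvis)
    inert["hat"] = subject.inertia["hat"].inertia_tensor
    rots["hat"] = rot_p

    total_mass = sum(masses.values())
    force_req = np.zeros((n, 3))
    moment_req = np.zeros((n, 3))  # about the lab origin, N m
    com_total = np.zeros((n, 3))
    for seg, m in masses.items():
        c_m = com_lab[seg] / 1000.0
        acc = np.stack([central_difference(c_m[:, k], rate, order=2)
                        for k in range(3)], axis=1)
        force_req += m * (acc - g_vec)
        moment_req += np.cross(c_m, m * (acc - g_vec))
        com_total += m * com_lab[seg] / total_mass
        rot = rots[seg]
        omega = angular_velocity_from_rotations(rot, rate)
        i_lab = np.einsum("fij,jk,flk->fil", rot, inert[seg], rot)
        ang_mom = np.einsum("fij,fj->fi", i_lab, omega)
        moment_req += np.stack(
            [central_difference(ang_mom[:, k], rate) for k in range(3)],
            axis=1)

    w = (_smoothstep5((t - (t_rise0 - 0.2)) / 0.35)
         - _smoothstep5((t - (t_sit1 - 0.55)) / 0.35))
    baseline = 2.0 * config.seated_foot_load

    feet_total = np.column_stack([
        force_req[:, 0] * w,
        force_req[:, 1] * w,
        baseline + (force_req[:, 2] - baseline) * w])
    seat_force = force_req - feet_total

    # seat contact point (m): slightly posterior of the pelvis origin,
    # at seat height
    seat_point = np.column_stack([
        org_p[:, 0] / 1000.0 - 0.06,
        org_p[:, 1] / 1000.0,
        np.full(n, config.seat_height / 1000.0)])

    ankle = {}
    for side in SIDES:
        rot_s, org_s = poses[f"shank_{side}"]
        ankle[side] = org_s + np.einsum(
            "fij,j->fi", rot_s, subject.true_joint_centers[f"ankle_{side}"])
    foot_center_x = (0.5 * (ankle["right"][:, 0] + ankle["left"][:, 0])
                     / 1000.0 + 0.03)
    y_half = 0.5 * np.abs(ankle["right"][:, 1] - ankle["left"][:, 1]) / 1000.0

    m_contact = moment_req - np.cross(seat_point, seat_force)
    use_feet = w >= 0.5
    fz_safe = np.where(np.abs(feet_total[:, 2]) < 1.0, 1.0, feet_total[:, 2])
    cop_x = np.where(use_feet, -m_contact[:, 1] / fz_safe, foot_center_x)
    cop_dy = np.where(use_feet, m_contact[:, 0] / fz_safe, 0.0)
    mz_feet = cop_x * feet_total[:, 1] - cop_dy * feet_total[:, 0]
    free_mz_total = np.where(use_feet, m_contact[:, 2] - mz_feet, 0.0)

    plate_moment = np.column_stack([
        cop_dy * feet_total[:, 2],
        -cop_x * feet_total[:, 2],
        mz_feet + free_mz_total])
    seat_moment = m_contact - plate_moment  # residual carried by the seat

    feet_force, cops, free = {}, {}, {}
    for side in SIDES:
        y_sign = -1.0 if side == "right" else 1.0
        feet_force[side] = 0.5 * feet_total
        cops[side] = np.column_stack([
            cop_x * 1000.0,
            (cop_dy + y_sign * y_half) * 1000.0,
            np.zeros(n)])
        free[side] = 0.5 * free_mz_total * 1e3  # N m -> N mm
    aux = {"seat_force": seat_force, "seat_moment": seat_moment,
           "com_total_mm": com_total, "unload_profile": w,
           "total_mass": total_mass}
    return feet_force, cops, free, aux


def generate_sts_trial(subject: SyntheticSubject,
                       config: SyntheticProtocolConfig | None = None,
                       artifact: ArtifactConfig | None = None
                       ) -> tuple[TrialData, GroundTruth]:
    """One STS repetition: dynamic markers + plate signals + ground truth.

    Ground-truth events are obtained by applying the literal detection
    rules (hip angular-velocity zero crossings, 10 N baseline-subtracted
    vertical GRF threshold, +/-3 cm hip-height plateau) to the noise-free
    truth signals, independently of the event-detection module.
    """
    config = config or SyntheticProtocolConfig()
    artifact = artifact or ArtifactConfig()
    rate = config.marker_rate
    mp = subject.motion_params

    stand_hip_z = (subject.segment_lengths["ankle_z"]
                   + subject.segment_lengths["shank_length"]
                   + subject.segment_lengths["thigh_length"])
    if config.seat_height >= stand_hip_z:
        raise InvalidParameterError("seat higher than the hip in standing")

    # --- keyframe timeline (s) --------------------------------------------
    # the backward sway overlaps the start of the forward lean (and the
    # final settle overlaps the end of the descent) so the hip angular
    # velocity crosses zero transversally, not tangentially
    t_sway0, t_onset = 0.15, 0.45
    t_sway1 = t_onset + 0.10
    t_lean1 = t_onset + 0.8
    t_r0 = t_lean1 - 0.1
    t_r1 = t_r0 + mp["rise_duration"]
    t_h1 = t_r1 + 0.1 + config.stand_hold
    t_d1 = t_h1 + mp["descend_duration"]
    t_end = t_d1 + 0.9
    n = int(round(t_end * rate)) + 1
    t = np.arange(n) / rate

    k0 = config.initial_knee_flexion
    k_stand = mp["stand_knee_deg"]
    phi_sit, phi_stand = -8.0, -3.0  # pelvis pitch; negative = forward lean
    sway = mp["sway_deg"]
    lean_extra = mp["lean_deg"]  # forward lean beyond the seated posture
    psi_mid = -mp["shank_pitch_deg"]

    knee_deg = _profile(t, k0, [
        (t_r0, t_r1, k_stand - k0),
        (t_h1, t_d1, k0 - k_stand),
    ])
    phi_deg = _profile(t, phi_sit, [
        (t_sway0, t_sway1, +sway),                    # backward sway
        (t_onset, t_lean1, -(lean_extra + sway)),     # forward lean
        (t_r0, t_r1 + 0.1, lean_extra + (phi_stand - phi_sit)),
        (t_h1, t_d1, -10.0),                          # lean during descent
        (t_d1 - 0.1, t_d1 + 0.35, +5.0),              # settle back upright
    ])
    t_mid = 0.5 * (t_lean1 + t_r1)
    psi_deg = _profile(t, -3.0, [
        (t_lean1 - 0.2, t_mid, psi_mid + 3.0),
        (t_mid, t_r1, -2.0 - psi_mid),
        (t_h1, t_h1 + 0.6 * mp["descend_duration"], psi_mid + 2.0),
        (t_h1 + 0.6 * mp["descend_duration"], t_d1, -3.0 - psi_mid),
    ])

    psi = np.deg2rad(psi_deg)
    tau = psi + np.deg2rad(knee_deg)  # target thigh pitch
    phi = np.deg2rad(phi_deg)
    hip_rad = tau - phi  # hip flexion generalized coordinate
    knee_rad = np.deg2rad(knee_deg)

    # --- forward kinematics -------------------------------------------------
    # Joint rotations act in the calibrated (anatomical) frames, so the
    # commanded hip/knee profiles ARE the Cardan ground-truth angles; the
    # pelvis position is then closed so the right ankle stays planted.
    def _rotx_series(angles: np.ndarray) -> np.ndarray:
        c, s = np.cos(angles), np.sin(angles)
        out = np.zeros((len(angles), 3, 3))
        out[:, 0, 0] = 1.0
        out[:, 1, 1] = c
        out[:, 1, 2] = -s
        out[:, 2, 1] = s
        out[:, 2, 2] = c
        return out

    poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    r0_pelvis = subject.true_frames["pelvis"][0]
    rot_pelvis = _pitch_series(phi) @ r0_pelvis
    rot_hip = _rotx_series(hip_rad)
    rot_knee = _rotx_series(-knee_rad)
    # joint rotations act relative to the calibration pose: the constant
    # inter-segment offsets of the jittered anatomy are preserved, so the
    # commanded profiles are exactly the calibration-referenced angles and
    # the static pose stays the zero of every joint
    offset_hip = {s: r0_pelvis.T @ subject.true_frames[f"thigh_{s}"][0]
                  for s in SIDES}
    offset_knee = {s: subject.true_frames[f"thigh_{s}"][0].T
                   @ subject.true_frames[f"shank_{s}"][0] for s in SIDES}
    rot_thigh = {s: rot_pelvis @ rot_hip @ offset_hip[s] for s in SIDES}
    rot_shank = {s: rot_thigh[s] @ rot_knee @ offset_knee[s] for s in SIDES}
    rot_foot = {s: np.tile(subject.true_frames[f"foot_{s}"][0], (n, 1, 1))
                for s in SIDES}

    # pelvis position closed through the right leg (right ankle planted)
    ankle_fixed = (subject.true_frames["shank_right"][1]
                   + subject.true_frames["shank_right"][0]
                   @ subject.true_joint_centers["ankle_right"])
    chain_offset = (
        np.einsum("fij,j->fi", rot_pelvis,
                  subject.true_joint_centers["hip_right"])
        + np.einsum("fij,j->fi", rot_thigh["right"],
                    subject.true_joint_centers["knee_right"])
        + np.einsum("fij,j->fi", rot_shank["right"],
                    subject.true_joint_centers["ankle_right"]))
    org_pelvis = ankle_fixed[None, :] - chain_offset
    poses["pelvis"] = (rot_pelvis, org_pelvis)
    drawer_local = np.array([0.0, config.tibial_drawer_mm, 0.0])
    for side in SIDES:
        hjc = org_pelvis + np.einsum(
            "fij,j->fi", rot_pelvis, subject.true_joint_centers[f"hip_{side}"])
        poses[f"thigh_{side}"] = (rot_thigh[side], hjc)
        knee = hjc + np.einsum("fij,j->fi", rot_thigh[side],
                               subject.true_joint_centers[f"knee_{side}"])
        if config.tibial_drawer_mm:
            knee = knee + np.einsum("fij,j->fi", rot_thigh[side],
                                    drawer_local)
        poses[f"shank_{side}"] = (rot_shank[side], knee)
        ankle = knee + np.einsum("fij,j->fi", rot_shank[side],
                                 subject.true_joint_centers[f"ankle_{side}"])
        org_foot = ankle - np.einsum(
            "fij,j->fi", rot_foot[side],
            subject.true_joint_centers[f"ankle_in_foot_{side}"])
        poses[f"foot_{side}"] = (rot_foot[side], org_foot)

    # --- marker trajectories -------------------------------------------------
    dyn_labels = [lab for lab in subject.tpose_positions
                  if lab in _dynamic_label_set()]
    seg_of = subject.marker_segments
    markers = np.empty((n, len(dyn_labels), 3))
    for m, lab in enumerate(dyn_labels):
        rot, org = poses[seg_of[lab]]
        markers[:, m, :] = org + np.einsum(
            "fij,j->fi", rot, subject.true_marker_locals[lab])

    # --- soft-tissue artifact + measurement noise ----------------------------
    # random STA is modulated by a motion-intensity envelope: soft tissue
    # wobbles with movement, so a quietly seated subject shows almost none
    rng = np.random.default_rng(
        np.random.SeedSequence([77003, artifact.rng_seed]))
    flex_scale = knee_deg / 90.0
    speed = (np.abs(central_difference(knee_deg, rate))
             + np.abs(central_difference(phi_deg, rate))
             + np.abs(central_difference(psi_deg, rate)))
    b_env, a_env = sps.butter(2, 1.0 / (rate / 2.0), btype="low")
    envelope = sps.filtfilt(b_env, a_env, speed)
    peak = max(float(envelope.max()), 1e-9)
    envelope = (0.15 + 0.85 * np.clip(envelope / peak, 0.0, 1.0))[:, None]
    for side in SIDES:  # rigid cluster-plate STA
        p = SIDE_PREFIX[side]
        for grp in _CLUSTER_GROUPS:
            labs = [f"{p}{grp}{i}" for i in range(1, 5)]
            rot, _ = poses[seg_of[labs[0]]]
            trans = _unit_lowpass_noise(rng, n, artifact.sta_bandwidth,
                                        rate) * artifact.cluster_amplitude
            rotvec = _unit_lowpass_noise(rng, n, artifact.sta_bandwidth,
                                         rate) * (artifact.cluster_amplitude
                                                  / 65.0)
            center_local = np.mean(
                [subject.true_marker_locals[lab] for lab in labs], axis=0)
            for lab in labs:
                m = dyn_labels.index(lab)
                arm = subject.true_marker_locals[lab] - center_local
                disp_local = (trans + np.cross(rotvec, arm)) * envelope
                markers[:, m, :] += np.einsum("fij,fj->fi", rot, disp_local)
    for m, lab in enumerate(dyn_labels):  # skin-marker STA
        if lab[1:3] in _CLUSTER_GROUPS:
            continue
        seg = seg_of[lab]
        rot, _ = poses[seg]
        amp = _sta_amplitude(lab, seg, artifact)
        disp_local = _unit_lowpass_noise(rng, n, artifact.sta_bandwidth,
                                         rate) * amp * envelope
        if lab in subject.sta_directions:
            disp_local = disp_local + (
                artifact.flexion_coupled_amplitude
                * artifact.thigh_skin_scale * flex_scale[:, None]
                * subject.sta_directions[lab][None, :])
        if amp > 0 or artifact.flexion_coupled_amplitude > 0:
            markers[:, m, :] += np.einsum("fij,fj->fi", rot, disp_local)
    noise = rng.normal(0.0, 1.0, markers.shape)
    if artifact.measurement_noise_sd > 0:
        markers += artifact.measurement_noise_sd * noise

    # --- plate signals --------------------------------------------------------
    feet_force, cops, free_mz, aux_forces = _synthesize_grf(
        subject, poses, t, rate, config, t_r0, t_d1)
    ratio = int(round(config.analog_rate / rate))
    forces, copsa, freea = _make_plate_signals(feet_force, cops, free_mz,
                                               n, ratio)

    # --- ground truth ----------------------------------------------------------
    from .pose import joint_angles_from_rotations  # deferred: no import cycle

    angle_curves: dict[tuple[str, str], np.ndarray] = {}
    for side in SIDES:
        angle_curves[("knee", side)] = joint_angles_from_rotations(
            poses[f"thigh_{side}"][0], poses[f"shank_{side}"][0],
            joint="knee", side=side, r_offset=offset_knee[side])
        angle_curves[("hip", side)] = joint_angles_from_rotations(
            poses["pelvis"][0], poses[f"thigh_{side}"][0],
            joint="hip", side=side, r_offset=offset_hip[side])

    hip_flex = angle_curves[("hip", "right")][:, 0]
    vgrf = feet_force["right"][:, 2] + feet_force["left"][:, 2]
    hip_z = poses["thigh_right"][1][:, 2]
    events = _truth_events(hip_flex, vgrf, hip_z, rate)

    trial = TrialData(
        marker_positions=markers, marker_labels=dyn_labels,
        marker_rate=rate, analog_rate=config.analog_rate,
        plate_forces=forces, plate_cops=copsa, plate_free_moments=freea,
        body_mass=subject.body_mass, side_map={"right": 0, "left": 1},
        meta={"kind": "sts", "subject_id": subject.subject_id,
              "stature": subject.stature},
    )
    truth = GroundTruth(
        segment_poses=poses, joint_angle_curves=angle_curves,
        event_frames=events, marker_rate=rate,
        aux={"feet_force": feet_force, "cops": cops, "free_mz": free_mz,
             "knee_flexion_deg": knee_deg, "hip_flexion_deg": hip_flex,
             "hip_height_mm": hip_z, "time_s": t, **aux_forces},
    )
    return trial, truth


def generate_cohort(n_subjects: int = 24,
                    config: SyntheticProtocolConfig | None = None,
                    artifact: ArtifactConfig | None = None,
                    seed: int = 7,
                    anthropometry: AnthropometryParams | None = None
                    ) -> list[dict]:
    """Generate a cohort: per subject, one static trial and the STS
    repetitions.

    Per-subject protocol sensitivity is induced by (a) marker-placement
    jitter inside :func:`generate_subject` and (b) a log-normal per-subject
    scaling of the STA amplitudes, so inter-protocol differences vary
    across subjects.  Returns a list of dicts with keys ``subject``,
    ``static`` and ``trials`` (list of ``(TrialData, GroundTruth)``).
    """
    if n_subjects < 2:
        raise InvalidParameterError("need >= 2 subjects for paired statistics")
    config = config or SyntheticProtocolConfig()
    artifact = artifact or ArtifactConfig()
    out = []
    for i in range(n_subjects):
        sub_rng = np.random.default_rng(
            np.random.SeedSequence([77000, seed, i]))
        subject = generate_subject(anthropometry,
                                   rng_seed=int(sub_rng.integers(2**31)),
                                   subject_id=f"S{i + 1:03d}")
        sta_scale = float(np.exp(sub_rng.normal(0.0, 0.25)))
        art_i = artifact.scaled(sta_scale)
        static = generate_static_trial(
            subject, config=config,
            artifact=replace(art_i, rng_seed=int(sub_rng.integers(2**31))))
        trials = [
            generate_sts_trial(
                subject, config,
                replace(art_i, rng_seed=int(sub_rng.integers(2**31))))
            for _ in range(config.n_repetitions)]
        out.append({"subject": subject, "static": static, "trials": trials})
    return out
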