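"""Subject-specific model building from a static T-pose trial.

Four models are built per subject — ``IOR_IK``, ``IOR_6DoF``, ``CAST_IK``
and ``CAST_6DoF`` — combining the two marker sets with the two
joint-constraint strategies.  All four share the same joint-centre
conventions: the hip centre from the Bell regression on the pelvis
landmarks, and knee/ankle centres as the epicondyle/malleolus midpoints.

Anatomical segment frames are computed once from the static trial; every
dynamic tracking target (and each joint centre) is stored as a constant
local vector in its segment's anatomical frame, so a rigid fit of the
tracking targets directly reconstructs the anatomical frame during motion.
Inertial parameters are fixed fractions of body mass (Dempster table,
shipped as editable YAML data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import (DegenerateGeometryError, InvalidParameterError,
                     MissingMarkerError)
from .geometry import fit_rigid, orthonormal_frame
from .io import TrialData
from .markersets import SIDE_PREFIX, SIDES, MarkerSetSpec, load_marker_set

PROTOCOLS = ("IOR_IK", "IOR_6DoF", "CAST_IK", "CAST_6DoF")

#: Bell et al. hip-joint-centre regression: offsets from the inter-ASIS
#: midpoint as fractions of the inter-ASIS distance (lateral, posterior,
#: distal).
BELL_COEFFICIENTS = (0.36, 0.19, 0.30)

#: head+arms+trunk lumped-segment length as a fraction of stature, used to
#: place the HAT centre of mass above the hip level
TRUNK_LENGTH_FRACTION = 0.288


@dataclass
class StaticCalibration:
    """Per-label mean position (mm) and residual SD over static frames."""

    mean_positions: dict[str, np.ndarray]
    residual_sd: dict[str, float]
    n_frames_used: int

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.mean_positions[label]
        except KeyError:
            raise MissingMarkerError(label, "static calibration") from None


@dataclass
class SegmentInertia:
    """Dempster-style inertial parameters for one segment."""

    mass_fraction: float
    com_fraction: float
    gyration_fractions: np.ndarray  # (3,) per segment axis
    mass: float  # kg
    length: float  # mm
    gyration_radii: np.ndarray  # (3,) mm

    @property
    def inertia_tensor(self) -> np.ndarray:
        """Principal inertia tensor about the COM, kg m^2, segment axes."""
        radii_m = self.gyration_radii / 1000.0
        return np.diag(self.mass * radii_m**2)


@dataclass
class SegmentModel:
    """One segment of a calibrated subject model."""

    name: str
    rotation0: np.ndarray  # (3,3) lab<-segment at calibration
    origin0: np.ndarray  # (3,) mm, lab, at calibration
    tracking_labels: list[str]
    tracking_locals: np.ndarray  # (k,3) mm in the anatomical frame
    com_local: np.ndarray  # (3,) mm
    side: str | None = None
    augment_hip_center: bool = False


@dataclass
class SubjectModel:
    """Calibrated per-protocol skeleton."""

    protocol: str
    marker_set: str
    joint_model: str  # "ik" | "6dof"
    body_mass: float
    segments: dict[str, SegmentModel]
    joint_centers_local: dict[str, np.ndarray]  # e.g. "hip_right" in pelvis
    joint_centers_lab0: dict[str, np.ndarray]  # at calibration
    segment_lengths: dict[str, float]  # mm
    inertia: dict[str, SegmentInertia]
    hat_com_in_pelvis: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise InvalidParameterError(f"unknown protocol {self.protocol!r}")
        for seg in self.segments.values():
            r = seg.rotation0
            if np.linalg.norm(r.T @ r - np.eye(3)) > 1e-8:
                raise InvalidParameterError(
                    f"segment {seg.name} calibration frame not orthonormal")

    # -- JSON serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def arr(a):
            return np.asarray(a).tolist()

        return {
            "protocol": self.protocol,
            "marker_set": self.marker_set,
            "joint_model": self.joint_model,
            "body_mass": self.body_mass,
            "segments": {
                name: {
                    "rotation0": arr(s.rotation0),
                    "origin0": arr(s.origin0),
                    "tracking_labels": s.tracking_labels,
                    "tracking_locals": arr(s.tracking_locals),
                    "com_local": arr(s.com_local),
                    "side": s.side,
                    "augment_hip_center": s.augment_hip_center,
                } for name, s in self.segments.items()},
            "joint_centers_local": {k: arr(v) for k, v in
                                    self.joint_centers_local.items()},
            "joint_centers_lab0": {k: arr(v) for k, v in
                                   self.joint_centers_lab0.items()},
            "segment_lengths": self.segment_lengths,
            "inertia": {
                name: {
                    "mass_fraction": i.mass_fraction,
                    "com_fraction": i.com_fraction,
                    "gyration_fractions": arr(i.gyration_fractions),
                    "mass": i.mass,
                    "length": i.length,
                    "gyration_radii": arr(i.gyration_radii),
                } for name, i in self.inertia.items()},
            "hat_com_in_pelvis": None if self.hat_com_in_pelvis is None
            else arr(self.hat_com_in_pelvis),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectModel":
        segments = {
            name: SegmentModel(
                name=name,
                rotation0=np.array(s["rotation0"]),
                origin0=np.array(s["origin0"]),
                tracking_labels=list(s["tracking_labels"]),
                tracking_locals=np.array(s["tracking_locals"]),
                com_local=np.array(s["com_local"]),
                side=s["side"],
                augment_hip_center=bool(s["augment_hip_center"]),
            ) for name, s in d["segments"].items()}
        inertia = {
            name: SegmentInertia(
                mass_fraction=i["mass_fraction"],
                com_fraction=i["com_fraction"],
                gyration_fractions=np.array(i["gyration_fractions"]),
                mass=i["mass"], length=i["length"],
                gyration_radii=np.array(i["gyration_radii"]),
            ) for name, i in d["inertia"].items()}
        return cls(
            protocol=d["protocol"], marker_set=d["marker_set"],
            joint_model=d["joint_model"], body_mass=d["body_mass"],
            segments=segments,
            joint_centers_local={k: np.array(v) for k, v in
                                 d["joint_centers_local"].items()},
            joint_centers_lab0={k: np.array(v) for k, v in
                                d["joint_centers_lab0"].items()},
            segment_lengths=dict(d["segment_lengths"]),
            inertia=inertia,
            hat_com_in_pelvis=None if d.get("hat_com_in_pelvis") is None
            else np.array(d["hat_com_in_pelvis"]),
            meta=d.get("meta", {}),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1),
                              encoding="utf-8")

    @classmethod
    def load_json(cls, path: str | Path) -> "SubjectModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------


def compute_static_pose(trial: TrialData,
                        required_labels: list[str] | None = None,
                        min_usable_frames: int = 10) -> StaticCalibration:
    """Average a static trial into per-label mean positions.

    Frames with a gap in any required label are excluded entirely, so the
    means describe one common pose.
    """
    labels = required_labels if required_labels is not None \
        else trial.marker_labels
    for label in labels:
        if label not in trial.marker_labels:
            raise MissingMarkerError(label, "static trial")
    cols = [trial.index(label) for label in labels]
    pos = trial.marker_positions[:, cols, :]
    usable = np.all(np.isfinite(pos), axis=(1, 2))
    if usable.sum() < min_usable_frames:
        raise InvalidParameterError(
            f"only {int(usable.sum())} usable static frames "
            f"(need >= {min_usable_frames})")
    pos = pos[usable]
    mean = pos.mean(axis=0)
    sd = pos.std(axis=0, ddof=1) if pos.shape[0] > 1 else np.zeros_like(mean)
    return StaticCalibration(
        mean_positions={lab: mean[i] for i, lab in enumerate(labels)},
        residual_sd={lab: float(np.sqrt(np.mean(sd[i] ** 2)))
                     for i, lab in enumerate(labels)},
        n_frames_used=int(pos.shape[0]),
    )


def pelvis_frame(rasis: np.ndarray, lasis: np.ndarray, rpsis: np.ndarray,
                 lpsis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pelvis anatomical frame: origin mid-ASIS, X through the ASIS pair
    (to the subject's right), Y anterior via the mid-PSIS point."""
    origin = 0.5 * (np.asarray(rasis, float) + np.asarray(lasis, float))
    x_dir = np.asarray(rasis, float) - np.asarray(lasis, float)
    anterior = origin - 0.5 * (np.asarray(rpsis, float) +
                               np.asarray(lpsis, float))
    rotation = orthonormal_frame(x_dir, anterior, order=("x", "y"))
    return rotation, origin


def bell_hip_joint_center(lasis: np.ndarray, rasis: np.ndarray,
                          lpsis: np.ndarray, rpsis: np.ndarray,
                          coefficients: tuple[float, float, float]
                          = BELL_COEFFICIENTS) -> dict[str, np.ndarray]:
    """Hip joint centres (per side) in the pelvis anatomical frame (mm).

    Offsets from the inter-ASIS midpoint scale linearly with the inter-ASIS
    distance ``d``: ``lateral = c0*d``, ``posterior = c1*d``,
    ``distal = c2*d``.
    """
    rasis = np.asarray(rasis, float)
    lasis = np.asarray(lasis, float)
    d = float(np.linalg.norm(rasis - lasis))
    if d <= 1e-9:
        raise DegenerateGeometryError("inter-ASIS distance is zero")
    c_lat, c_post, c_dist = coefficients
    return {
        "right": np.array([+c_lat * d, -c_post * d, -c_dist * d]),
        "left": np.array([-c_lat * d, -c_post * d, -c_dist * d]),
    }


def _midpoint(calib: StaticCalibration, a: str, b: str) -> np.ndarray:
    return 0.5 * (calib[a] + calib[b])


@dataclass
class SkeletonGeometry:
    """Static-pose anatomical frames and joint centres (lab coordinates)."""

    frames: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (R, origin)
    joint_centers_lab: dict[str, np.ndarray]
    hip_centers_local: dict[str, np.ndarray]  # in pelvis frame


def build_segment_frames(calib: StaticCalibration,
                         bell_coefficients: tuple[float, float, float]
                         = BELL_COEFFICIENTS) -> SkeletonGeometry:
    """Anatomical frames for pelvis, thighs, shanks and feet.

    * pelvis — origin mid-ASIS, X through the ASIS pair, plane via mid-PSIS;
    * thigh — origin at the hip centre, Z from knee centre to hip centre,
      frontal plane via the femoral epicondyles;
    * shank — origin at the knee centre, Z from ankle to knee centre,
      frontal plane via the malleoli;
    * foot — origin at the calcaneus marker, long (anterior) axis to the
      2nd metatarsal head, sole plane via the 1st/5th metatarsal heads.

    All frames are right-handed with X mediolateral (to the subject's
    right), Y anterior, Z longitudinal.
    """
    r_pelvis, o_pelvis = pelvis_frame(calib["RASI"], calib["LASI"],
                                      calib["RPSI"], calib["LPSI"])
    hjc_local = bell_hip_joint_center(calib["LASI"], calib["RASI"],
                                      calib["LPSI"], calib["RPSI"],
                                      bell_coefficients)
    frames = {"pelvis": (r_pelvis, o_pelvis)}
    centers: dict[str, np.ndarray] = {}
    for side in SIDES:
        p = SIDE_PREFIX[side]
        sgn = 1.0 if side == "right" else -1.0
        hjc = o_pelvis + r_pelvis @ hjc_local[side]
        knee = _midpoint(calib, f"{p}LE", f"{p}ME")
        ankle = _midpoint(calib, f"{p}LM", f"{p}MM")
        centers[f"hip_{side}"] = hjc
        centers[f"knee_{side}"] = knee
        centers[f"ankle_{side}"] = ankle

        x_knee = sgn * (calib[f"{p}LE"] - calib[f"{p}ME"])
        r_thigh = orthonormal_frame(hjc - knee, x_knee, order=("z", "x"))
        frames[f"thigh_{side}"] = (r_thigh, hjc)

        x_ankle = sgn * (calib[f"{p}LM"] - calib[f"{p}MM"])
        r_shank = orthonormal_frame(knee - ankle, x_ankle, order=("z", "x"))
        frames[f"shank_{side}"] = (r_shank, knee)

        y_foot = calib[f"{p}SM"] - calib[f"{p}CA"]
        x_foot = sgn * (calib[f"{p}VM"] - calib[f"{p}FM"])
        r_foot = orthonormal_frame(y_foot, x_foot, order=("y", "x"))
        frames[f"foot_{side}"] = (r_foot, calib[f"{p}CA"])
    return SkeletonGeometry(frames=frames, joint_centers_lab=centers,
                            hip_centers_local=hjc_local)


def calibrate_cluster(calib: StaticCalibration, cluster_labels: list[str],
                      anatomical_labels: list[str]
                      ) -> dict[str, np.ndarray]:
    """Express anatomical landmarks in a cluster's technical frame.

    The technical frame has its origin at the cluster centroid, X toward
    the first cluster marker and its XY plane through the second; during
    dynamic tracking, rigidly fitting the cluster reconstructs each
    landmark as a constant local vector.
    """
    if len(cluster_labels) < 3:
        raise DegenerateGeometryError("cluster needs >= 3 markers")
    pts = np.stack([calib[lab] for lab in cluster_labels])
    centroid = pts.mean(axis=0)
    rotation = orthonormal_frame(pts[0] - centroid, pts[1] - centroid,
                                 order=("x", "y"))
    return {lab: rotation.T @ (calib[lab] - centroid)
            for lab in anatomical_labels}


def load_anthropometric_table(path: str | Path | None = None
                              ) -> dict[str, dict]:
    """Dempster segment-parameter table (bundled YAML by default)."""
    if path is None:
        text = (resources.files("kneests.data") / "dempster.yaml"
                ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    table = yaml.safe_load(text)
    for name, row in table.items():
        for key in ("mass_fraction", "com_fraction"):
            if not 0.0 < row[key] < 1.0:
                raise InvalidParameterError(
                    f"{name}.{key} must lie in (0, 1)")
    return table


def compute_inertial_parameters(body_mass: float,
                                segment_lengths: dict[str, float],
                                table: dict | None = None
                                ) -> dict[str, SegmentInertia]:
    """Per-segment inertia from body mass and segment lengths (mm).

    ``segment_lengths`` maps table keys (``thigh``, ``shank``, ``foot``,
    optionally ``hat``) to lengths; masses are fixed fractions of body mass.
    """
    if body_mass <= 0:
        raise InvalidParameterError("body_mass must be positive")
    if table is None:
        table = load_anthropometric_table()
    out: dict[str, SegmentInertia] = {}
    for name, row in table.items():
        if name not in segment_lengths:
            continue
        length = float(segment_lengths[name])
        if length <= 0:
            raise InvalidParameterError(f"segment length {name} must be > 0")
        gyr = np.array([row["gyration_fractions"][ax] for ax in "xyz"])
        out[name] = SegmentInertia(
            mass_fraction=row["mass_fraction"],
            com_fraction=row["com_fraction"],
            gyration_fractions=gyr,
            mass=row["mass_fraction"] * body_mass,
            length=length,
            gyration_radii=gyr * length,
        )
    return out


def build_subject_model(static_trial: TrialData, marker_set: str | MarkerSetSpec,
                        joint_model: str,
                        body_mass: float | None = None,
                        stature: float | None = None,
                        bell_coefficients: tuple[float, float, float]
                        = BELL_COEFFICIENTS,
                        anthropometric_table: dict | None = None
                        ) -> SubjectModel:
    """Calibrate one protocol's subject model from a static T-pose trial.

    ``joint_model`` is ``"ik"`` (3-rotational-DoF joints, chain solve) or
    ``"6dof"`` (independent segment fits).  ``stature`` (mm), when given,
    places the lumped head-arms-trunk COM used for whole-body bookkeeping.
    """
    spec = marker_set if isinstance(marker_set, MarkerSetSpec) \
        else load_marker_set(marker_set)
    joint_model = joint_model.lower()
    if joint_model not in ("ik", "6dof"):
        raise InvalidParameterError("joint_model must be 'ik' or '6dof'")
    mass = body_mass if body_mass is not None else static_trial.body_mass
    if mass is None or mass <= 0:
        raise InvalidParameterError("positive body mass required")

    calib = compute_static_pose(static_trial,
                                required_labels=spec.static_labels)
    skel = build_segment_frames(calib, bell_coefficients)

    to_local = {}
    for name, (rot, org) in skel.frames.items():
        to_local[name] = (rot, org)

    def local(seg: str, point_lab: np.ndarray) -> np.ndarray:
        rot, org = to_local[seg]
        return rot.T @ (point_lab - org)

    segments: dict[str, SegmentModel] = {}
    lengths: dict[str, float] = {}
    jc_local: dict[str, np.ndarray] = {}
    for side in SIDES:
        hjc = skel.joint_centers_lab[f"hip_{side}"]
        knee = skel.joint_centers_lab[f"knee_{side}"]
        ankle = skel.joint_centers_lab[f"ankle_{side}"]
        p = SIDE_PREFIX[side]
        lengths[f"thigh_{side}"] = float(np.linalg.norm(hjc - knee))
        lengths[f"shank_{side}"] = float(np.linalg.norm(knee - ankle))
        lengths[f"foot_{side}"] = float(
            np.linalg.norm(calib[f"{p}SM"] - calib[f"{p}CA"]))
        jc_local[f"hip_{side}"] = skel.hip_centers_local[side]
        jc_local[f"knee_{side}"] = local(f"thigh_{side}", knee)
        jc_local[f"ankle_{side}"] = local(f"shank_{side}", ankle)
        jc_local[f"ankle_in_foot_{side}"] = local(f"foot_{side}", ankle)

    type_lengths = {
        "thigh": 0.5 * (lengths["thigh_right"] + lengths["thigh_left"]),
        "shank": 0.5 * (lengths["shank_right"] + lengths["shank_left"]),
        "foot": 0.5 * (lengths["foot_right"] + lengths["foot_left"]),
    }
    if stature is not None:
        type_lengths["hat"] = TRUNK_LENGTH_FRACTION * stature
    inertia = compute_inertial_parameters(mass, type_lengths,
                                          anthropometric_table)

    for name, seg_spec in spec.segments.items():
        rot, org = skel.frames[name]
        locals_ = np.stack([local(name, calib[lab])
                            for lab in seg_spec.tracking])
        if name == "pelvis":
            com_local = np.zeros(3)
        else:
            base = name.split("_")[0]
            com_local = np.array(
                [0.0, 0.0, -inertia[base].com_fraction * inertia[base].length])
            if base == "foot":
                # foot COM halfway along the heel-toe line, at sole level
                side = seg_spec.side
                p = SIDE_PREFIX[side]
                com_local = 0.5 * (local(name, calib[f"{p}CA"]) +
                                   local(name, calib[f"{p}SM"]))
        segments[name] = SegmentModel(
            name=name, rotation0=rot, origin0=org,
            tracking_labels=list(seg_spec.tracking),
            tracking_locals=locals_,
            com_local=com_local,
            side=seg_spec.side,
            augment_hip_center=seg_spec.augment_hip_center,
        )
        if seg_spec.augment_hip_center and seg_spec.side is not None:
            hjc = skel.joint_centers_lab[f"hip_{seg_spec.side}"]
            segments[name].tracking_labels.append(f"HJC_{seg_spec.side}")
            segments[name].tracking_locals = np.vstack(
                [segments[name].tracking_locals, local(name, hjc)])

    hat_com = None
    if stature is not None:
        hat_len = type_lengths["hat"]
        hat_com = np.array([0.0, 0.0,
                            inertia["hat"].com_fraction * hat_len])

    protocol = f"{spec.name}_{'IK' if joint_model == 'ik' else '6DoF'}"
    return SubjectModel(
        protocol=protocol, marker_set=spec.name, joint_model=joint_model,
        body_mass=float(mass), segments=segments,
        joint_centers_local=jc_local,
        joint_centers_lab0=dict(skel.joint_centers_lab),
        segment_lengths=lengths, inertia=inertia,
        hat_com_in_pelvis=hat_com,
        meta={"n_static_frames": calib.n_frames_used,
              "bell_coefficients": list(bell_coefficients)},
    )
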