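"""Bottom-up Newton-Euler inverse dynamics for the knee chain.

Per side, the recursion runs foot -> shank using the per-foot plate
wrench, segment kinematics (COM accelerations, angular velocities and
accelerations differentiated from the pose series) and Dempster inertial
parameters.  Joint loads are solved as internal wrenches and reported as
*net external* moments (the negative of the internal moment), resolved in
the proximal-segment frame by default and normalized to body mass
(Nm/kg), with component signs matched to the joint-angle conventions
(flexion-positive parallels flexion-angle-positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import SubjectModel
from .errors import InvalidParameterError
from .geometry import angular_velocity_from_rotations, central_difference
from .io import GRAVITY
from .pose import SegmentPoseSeries

_G_VEC = np.array([0.0, 0.0, -GRAVITY])


@dataclass
class SegmentKinematics:
    """SI kinematics of one segment: COM in m, derivatives in SI units."""

    com: np.ndarray  # (F, 3) m
    com_acc: np.ndarray  # (F, 3) m s^-2
    omega: np.ndarray  # (F, 3) rad s^-1, lab frame
    alpha: np.ndarray  # (F, 3) rad s^-2
    rotation: np.ndarray  # (F, 3, 3)


@dataclass
class JointMomentSeries:
    """Net external joint moments, Nm/kg, components [KFM, KAM, KIRM]."""

    moments: np.ndarray  # (F, 3)
    joint: str
    side: str
    rate: float
    resolution_frame: str = "proximal"
    valid: np.ndarray | None = None

    @property
    def flexion(self) -> np.ndarray:
        return self.moments[:, 0]


def segment_kinematics(poses: SegmentPoseSeries, model: SubjectModel,
                       segments: list[str] | None = None,
                       frame_range: tuple[int, int] | None = None
                       ) -> dict[str, SegmentKinematics]:
    """COM accelerations and angular kinematics for the requested segments.

    Raises if the window contains invalid (gap) frames: inverse dynamics
    needs continuous poses.
    """
    if segments is None:
        segments = list(model.segments)
    lo, hi = frame_range if frame_range is not None else (0, poses.n_frames)
    rate = poses.rate
    out: dict[str, SegmentKinematics] = {}
    for name in segments:
        ok = poses.valid[name][lo:hi]
        if not ok.all():
            bad = np.nonzero(~ok)[0][:10] + lo
            raise InvalidParameterError(
                f"segment {name} has invalid pose frames in the analysis "
                f"window (e.g. {bad.tolist()})")
        rot = poses.rotations[name][lo:hi]
        org = poses.origins[name][lo:hi]
        com_local = model.segments[name].com_local
        com = (org + np.einsum("fij,j->fi", rot, com_local)) / 1000.0
        acc = np.stack([central_difference(com[:, k], rate, order=2)
                        for k in range(3)], axis=1)
        omega = angular_velocity_from_rotations(rot, rate)
        alpha = np.stack([central_difference(omega[:, k], rate)
                          for k in range(3)], axis=1)
        out[name] = SegmentKinematics(com=com, com_acc=acc, omega=omega,
                                      alpha=alpha, rotation=rot)
    return out


def _rate_of_angular_momentum(kin: SegmentKinematics,
                              inertia_tensor: np.ndarray) -> np.ndarray:
    """I*alpha + omega x I*omega with I expressed in the lab frame."""
    i_lab = np.einsum("fij,jk,flk->fil", kin.rotation, inertia_tensor,
                      kin.rotation)
    i_omega = np.einsum("fij,fj->fi", i_lab, kin.omega)
    i_alpha = np.einsum("fij,fj->fi", i_lab, kin.alpha)
    return i_alpha + np.cross(kin.omega, i_omega)


def newton_euler_chain(poses: SegmentPoseSeries, model: SubjectModel,
                       plate_force: np.ndarray, plate_cop: np.ndarray,
                       plate_free_mz: np.ndarray, side: str,
                       frame_range: tuple[int, int] | None = None
                       ) -> dict[str, dict[str, np.ndarray]]:
    """Ankle, knee and hip internal wrenches for one side (SI units).

    ``plate_force`` (F, 3) N, ``plate_cop`` (F, 3) mm and
    ``plate_free_mz`` (F,) N mm must already be at the marker rate and
    belong to the plate under this side's foot.  Where the plate is
    (near) unloaded (|Fz| < 10 N) the COP is undefined and its
    contribution is zeroed, flagged in the output.

    Returns ``{"ankle": {...}, "knee": {...}, "hip": {...}}`` with
    ``force`` (N, on the distal segment from the proximal), ``moment``
    (N m, about the joint centre) and ``point`` (m) arrays.
    """
    lo, hi = frame_range if frame_range is not None else (0, poses.n_frames)
    segs = [f"foot_{side}", f"shank_{side}", f"thigh_{side}"]
    kin = segment_kinematics(poses, model, segs, (lo, hi))

    force = np.asarray(plate_force, dtype=float)[lo:hi]
    cop = np.asarray(plate_cop, dtype=float)[lo:hi] / 1000.0
    free_mz = np.asarray(plate_free_mz, dtype=float)[lo:hi] / 1000.0
    if not np.all(np.isfinite(force)):
        raise InvalidParameterError("plate force contains non-finite values")
    unloaded = np.abs(force[:, 2]) < 10.0
    cop = cop.copy()
    cop[unloaded] = 0.0
    grf_moment = np.cross(cop, force)
    grf_moment[:, 2] += free_mz
    grf_moment[unloaded] = 0.0
    force = force.copy()

    joints = ("ankle", "knee", "hip")
    out: dict[str, dict[str, np.ndarray]] = {}
    dist_force = force
    dist_moment_origin = grf_moment  # moments about the lab origin
    for seg_name, joint in zip(segs, joints):
        base = seg_name.split("_")[0]
        inertia = model.inertia[base]
        k = kin[seg_name]
        if joint == "ankle":
            point = _joint_point(poses, model, "ankle", side, lo, hi)
        elif joint == "knee":
            point = _joint_point(poses, model, "knee", side, lo, hi)
        else:
            point = _joint_point(poses, model, "hip", side, lo, hi)
        # force balance: m a = m g + F_dist + F_prox
        f_prox = inertia.mass * (k.com_acc - _G_VEC) - dist_force
        # moment balance about the lab origin
        dl_com = _rate_of_angular_momentum(k, inertia.inertia_tensor)
        m_prox_origin = (np.cross(k.com, inertia.mass * (k.com_acc - _G_VEC))
                         + dl_com - dist_moment_origin)
        m_prox_joint = m_prox_origin - np.cross(point, f_prox)
        out[joint] = {"force": f_prox, "moment": m_prox_joint,
                      "point": point, "cop_undefined": unloaded}
        # reaction on the next segment up
        dist_force = -f_prox
        dist_moment_origin = -m_prox_origin
    return out


def _joint_point(poses: SegmentPoseSeries, model: SubjectModel, joint: str,
                 side: str, lo: int, hi: int) -> np.ndarray:
    parent = {"hip": "pelvis", "knee": f"thigh_{side}",
              "ankle": f"shank_{side}"}[joint]
    if parent in poses.rotations and poses.valid[parent][lo:hi].all():
        rot = poses.rotations[parent][lo:hi]
        org = poses.origins[parent][lo:hi]
        local = model.joint_centers_local[f"{joint}_{side}"]
        return (org + np.einsum("fij,j->fi", rot, local)) / 1000.0
    # fall back to the distal segment's origin (shank origin == knee centre,
    # and the ankle centre expressed in the foot)
    if joint == "knee":
        return poses.origins[f"shank_{side}"][lo:hi] / 1000.0
    if joint == "ankle":
        rot = poses.rotations[f"foot_{side}"][lo:hi]
        org = poses.origins[f"foot_{side}"][lo:hi]
        local = model.joint_centers_local[f"ankle_in_foot_{side}"]
        return (org + np.einsum("fij,j->fi", rot, local)) / 1000.0
    raise InvalidParameterError(f"cannot locate joint {joint} ({side})")


def normalize_and_resolve(moment: np.ndarray, body_mass: float,
                          poses: SegmentPoseSeries | None, joint: str,
                          side: str, rate: float,
                          resolution_frame: str = "proximal",
                          frame_range: tuple[int, int] | None = None
                          ) -> JointMomentSeries:
    """Convert an internal joint moment (N m, lab) into the reported series.

    Steps: negate to the net-external convention, resolve the components
    in the requested frame (proximal segment by default; ``"lab"`` and
    ``"distal"`` also supported), map to clinical components with the same
    side-dependent signs as the joint angles, divide by body mass.
    """
    if body_mass <= 0:
        raise InvalidParameterError("body_mass must be positive")
    moment = np.asarray(moment, dtype=float)
    external = -moment
    if resolution_frame == "lab" or poses is None:
        comp = external
    else:
        proximal = {"hip": "pelvis", "knee": f"thigh_{side}",
                    "ankle": f"shank_{side}"}[joint]
        distal = {"hip": f"thigh_{side}", "knee": f"shank_{side}",
                  "ankle": f"foot_{side}"}[joint]
        seg = proximal if resolution_frame == "proximal" else distal
        lo, hi = frame_range if frame_range is not None \
            else (0, poses.n_frames)
        rot = poses.rotations[seg][lo:hi]
        comp = np.einsum("fji,fj->fi", rot, external)
    yz_sign = 1.0 if side == "right" else -1.0
    flexion_sign = -1.0 if joint in ("knee", "ankle") else 1.0
    out = np.empty_like(comp)
    out[:, 0] = flexion_sign * comp[:, 0]
    out[:, 1] = yz_sign * comp[:, 1]
    out[:, 2] = yz_sign * comp[:, 2]
    return JointMomentSeries(moments=out / body_mass, joint=joint, side=side,
                             rate=rate, resolution_frame=resolution_frame)


def knee_moment_series(poses: SegmentPoseSeries, model: SubjectModel,
                       plate_force: np.ndarray, plate_cop: np.ndarray,
                       plate_free_mz: np.ndarray, side: str,
                       resolution_frame: str = "proximal",
                       frame_range: tuple[int, int] | None = None
                       ) -> JointMomentSeries:
    """Convenience wrapper: full chain then normalized knee moments."""
    chain = newton_euler_chain(poses, model, plate_force, plate_cop,
                               plate_free_mz, side, frame_range)
    return normalize_and_resolve(chain["knee"]["moment"], model.body_mass,
                                 poses, "knee", side, poses.rate,
                                 resolution_frame, frame_range)
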