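"""Segment pose estimation and Cardan joint angles.

Two tracking strategies are implemented over the same calibrated models:

* **6DoF** — every segment is fitted independently per frame by a
  weighted least-squares rigid transform of its tracking targets, so
  joints are free to translate as well as rotate;
* **IK** — a whole-chain inverse-kinematics fit per frame over
  generalized coordinates (pelvis pose, 6 DoF) plus three rotational DoF
  at each hip, knee and ankle; adjacent segments share their joint centre
  by construction.  The solver is a damped Gauss-Newton
  (Levenberg-Marquardt) iteration with an analytic Jacobian, warm-started
  from the previous frame.

Knee angles follow the Cardan X-Y-Z convention: flexion/extension about
X, ab/adduction about Y, internal/external rotation about Z, with
left-side Y/Z angles negated so adduction and internal rotation are
positive on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import SubjectModel
from .errors import (ConvergenceError, DegenerateGeometryError,
                     InvalidParameterError)
from .geometry import cardan_xyz_decompose, central_difference, fit_rigid
from .io import TrialData

VARIABLE_ORDER = ("flexion", "adduction", "internal_rotation")

#: sign conventions mapping raw Cardan angles to clinical angles.
#: flexion sign is joint-specific (the knee flexes by rotating the shank
#: posteriorly, i.e. negatively about the common mediolateral axis);
#: Y/Z signs flip on the left so adduction / internal rotation are
#: positive on both sides.
_FLEXION_SIGN = {"hip": +1.0, "knee": -1.0, "ankle": -1.0}


def fit_rigid_pose(local_coords: np.ndarray, observed: np.ndarray,
                   weights: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares rigid pose (proper rotation enforced)."""
    return fit_rigid(local_coords, observed, weights)


@dataclass
class SegmentPoseSeries:
    """Per-frame rigid poses for a set of segments."""

    rotations: dict[str, np.ndarray]  # (F, 3, 3) lab <- segment
    origins: dict[str, np.ndarray]  # (F, 3) mm
    residuals: dict[str, np.ndarray]  # (F,) mm RMS
    valid: dict[str, np.ndarray]  # (F,) bool
    rate: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        first = next(iter(self.rotations.values()))
        return first.shape[0]

    def joint_center(self, model: SubjectModel, joint: str, side: str
                     ) -> np.ndarray:
        """Lab-frame trajectory of a model joint centre (from its parent)."""
        parent = {"hip": "pelvis", "knee": f"thigh_{side}",
                  "ankle": f"shank_{side}"}[joint]
        local = model.joint_centers_local[f"{joint}_{side}"]
        return self.origins[parent] + np.einsum(
            "fij,j->fi", self.rotations[parent], local)


@dataclass
class JointAngleSeries:
    """Clinical joint angles in degrees: flexion, adduction, internal rot."""

    angles: np.ndarray  # (F, 3)
    joint: str
    side: str
    rate: float
    valid: np.ndarray | None = None

    @property
    def flexion(self) -> np.ndarray:
        return self.angles[:, 0]


def _cardan_decompose_series(r_rel: np.ndarray) -> np.ndarray:
    """Vectorized Cardan X-Y-Z decomposition, degrees, (F, 3)."""
    s_y = np.clip(r_rel[:, 0, 2], -1.0, 1.0)
    theta_y = np.arcsin(s_y)
    theta_x = np.arctan2(-r_rel[:, 1, 2], r_rel[:, 2, 2])
    theta_z = np.arctan2(-r_rel[:, 0, 1], r_rel[:, 0, 0])
    return np.rad2deg(np.stack([theta_x, theta_y, theta_z], axis=1))


def joint_angles_from_rotations(r_proximal: np.ndarray, r_distal: np.ndarray,
                                joint: str, side: str,
                                r_offset: np.ndarray | None = None
                                ) -> np.ndarray:
    """Clinical angles (deg, (F, 3)) from proximal/distal rotation series.

    ``r_offset`` is the calibration-pose relative rotation
    ``R0_prox.T @ R0_dist``; when given, angles are measured relative to
    the calibration pose (all zero in the static trial).
    """
    r_rel = np.einsum("fji,fjk->fik", r_proximal, r_distal)
    if r_offset is not None:
        r_rel = r_rel @ r_offset.T
    raw = _cardan_decompose_series(r_rel)
    y_max = np.nanmax(np.abs(raw[:, 1])) if raw.size else 0.0
    if y_max >= 89.0:
        raise InvalidParameterError(
            f"{joint} Y-angle reaches {y_max:.1f} deg: Cardan X-Y-Z "
            "decomposition is near its singularity")
    yz_sign = 1.0 if side == "right" else -1.0
    out = np.empty_like(raw)
    out[:, 0] = _FLEXION_SIGN[joint] * raw[:, 0]
    out[:, 1] = yz_sign * raw[:, 1]
    out[:, 2] = yz_sign * raw[:, 2]
    return out


def joint_angle_series(poses: SegmentPoseSeries, joint: str, side: str,
                       model: SubjectModel | None = None) -> JointAngleSeries:
    """Joint angles for one joint/side from a segment pose series.

    With ``model`` the angles are calibration-referenced (zero in the
    static pose); without it they are raw anatomical-frame Cardan angles.
    """
    proximal = {"hip": "pelvis", "knee": f"thigh_{side}",
                "ankle": f"shank_{side}"}[joint]
    distal = {"hip": f"thigh_{side}", "knee": f"shank_{side}",
              "ankle": f"foot_{side}"}[joint]
    offset = None
    if model is not None:
        offset = (model.segments[proximal].rotation0.T
                  @ model.segments[distal].rotation0)
    angles = joint_angles_from_rotations(poses.rotations[proximal],
                                         poses.rotations[distal], joint,
                                         side, offset)
    valid = poses.valid[proximal] & poses.valid[distal]
    angles = angles.copy()
    angles[~valid] = np.nan
    return JointAngleSeries(angles=angles, joint=joint, side=side,
                            rate=poses.rate, valid=valid)


def angular_velocity(series: JointAngleSeries | np.ndarray,
                     rate: float | None = None) -> np.ndarray:
    """Flexion angular velocity (deg/s) by central differences."""
    if isinstance(series, JointAngleSeries):
        signal, rate = series.flexion, series.rate
    else:
        signal = np.asarray(series, dtype=float)
        if rate is None:
            raise InvalidParameterError("rate required for a bare array")
    if signal.shape[0] < 5:
        raise InvalidParameterError("need >= 5 frames for angular velocity")
    return central_difference(signal, rate)


def knee_translation(poses: SegmentPoseSeries, model: SubjectModel,
                     side: str) -> np.ndarray:
    """Knee translation (mm, thigh frame): shank origin relative to the
    thigh-predicted knee centre.  Identically zero for chain IK."""
    knee_from_thigh = poses.joint_center(model, "knee", side)
    delta = poses.origins[f"shank_{side}"] - knee_from_thigh
    return np.einsum("fji,fj->fi", poses.rotations[f"thigh_{side}"], delta)


# ---------------------------------------------------------------------------
# 6DoF tracking


def _observed_tracking(trial: TrialData, labels: list[str],
                       extra: dict[str, np.ndarray] | None = None
                       ) -> np.ndarray:
    cols = []
    for lab in labels:
        if extra is not None and lab in extra:
            cols.append(extra[lab])
        else:
            cols.append(trial.marker(lab))
    return np.stack(cols, axis=1)  # (F, k, 3)


def solve_6dof_trajectory(trial: TrialData, model: SubjectModel
                          ) -> SegmentPoseSeries:
    """Independent per-frame rigid fit of every segment.

    Segments with an augmented hip-centre target use the pelvis fit of the
    same frame to reconstruct that target, so the pelvis is solved first.
    Frames with fewer than 3 usable targets are flagged invalid.
    """
    if model.joint_model != "6dof":
        raise InvalidParameterError(
            f"model {model.protocol} is not a 6DoF variant")
    n = trial.n_frames
    names = ["pelvis"] + [s for s in model.segments if s != "pelvis"]
    rotations = {s: np.full((n, 3, 3), np.nan) for s in names}
    origins = {s: np.full((n, 3), np.nan) for s in names}
    residuals = {s: np.full(n, np.nan) for s in names}
    valid = {s: np.zeros(n, dtype=bool) for s in names}

    hjc_lab: dict[str, np.ndarray] = {}
    for name in names:
        seg = model.segments[name]
        extra = None
        if seg.augment_hip_center and seg.side is not None:
            extra = {f"HJC_{seg.side}": hjc_lab[seg.side]}
        observed = _observed_tracking(trial, seg.tracking_labels, extra)
        locals_ = seg.tracking_locals
        for f in range(n):
            obs = observed[f]
            ok = np.all(np.isfinite(obs), axis=1)
            if ok.sum() < 3:
                continue
            try:
                rot, org, rms = fit_rigid(locals_[ok], obs[ok])
            except DegenerateGeometryError:
                continue
            rotations[name][f] = rot
            origins[name][f] = org
            residuals[name][f] = rms
            valid[name][f] = True
        if name == "pelvis":
            for side in ("right", "left"):
                key = f"hip_{side}"
                if key in model.joint_centers_local:
                    hjc_lab[side] = origins["pelvis"] + np.einsum(
                        "fij,j->fi", rotations["pelvis"],
                        model.joint_centers_local[key])
    return SegmentPoseSeries(rotations=rotations, origins=origins,
                             residuals=residuals, valid=valid,
                             rate=trial.marker_rate)


# ---------------------------------------------------------------------------
# chain IK


class _Chain:
    """Kinematic chain bookkeeping for the IK solver.

    Generalized coordinates ``q`` (24,): pelvis translation (mm, 3) and
    Cardan rotation (rad, 3), then per side (right, left) three Cardan
    angles at hip, knee and ankle.
    """

    JOINTS = ("hip", "knee", "ankle")

    def __init__(self, model: SubjectModel, labels_by_segment: dict[str, list[str]]):
        self.model = model
        self.sides = ("right", "left")
        layout: list[tuple[int, int]] = []  # (side_idx, depth)
        self.marker_labels: list[str] = []
        locals_: list[np.ndarray] = []
        for name, labs in labels_by_segment.items():
            seg = model.segments[name]
            if name == "pelvis":
                side_idx, depth = -1, 0
            else:
                base, side = name.rsplit("_", 1)
                side_idx = self.sides.index(side)
                depth = {"thigh": 1, "shank": 2, "foot": 3}[base]
            for i, lab in enumerate(seg.tracking_labels):
                if lab not in labs:
                    continue
                self.marker_labels.append(lab)
                local = seg.tracking_locals[i]
                if depth == 3:
                    # express foot markers about the ankle centre, the point
                    # the chain propagates
                    local = local - model.joint_centers_local[
                        f"ankle_in_foot_{self.sides[side_idx]}"]
                locals_.append(local)
                layout.append((side_idx, depth))
        self.locals_arr = np.stack(locals_)
        self.layout = np.array(layout)
        # marker index groups: per (side, depth>=j) for Jacobian blocks
        self.group_idx: dict[tuple[int, int], np.ndarray] = {}
        for s in (0, 1):
            for j in (1, 2, 3):
                mask = (self.layout[:, 0] == s) & (self.layout[:, 1] >= j)
                self.group_idx[(s, j)] = np.nonzero(mask)[0]
        self.pred_groups = [
            (s, d, np.nonzero((self.layout[:, 0] == s)
                              & (self.layout[:, 1] == d))[0])
            for s in (-1, 0, 1) for d in (0, 1, 2, 3)
            if ((self.layout[:, 0] == s) & (self.layout[:, 1] == d)).any()]
        self.offsets = {
            s: [model.joint_centers_local[f"hip_{side}"],
                model.joint_centers_local[f"knee_{side}"],
                model.joint_centers_local[f"ankle_{side}"]]
            for s, side in enumerate(self.sides)}

    @staticmethod
    def _triples_vec(angles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Rotations (k,3,3) and partials (k,3,3,3) of Cardan X-Y-Z triples."""
        k = angles.shape[0]
        c = np.cos(angles)
        s = np.sin(angles)
        rx = np.zeros((k, 3, 3))
        ry = np.zeros((k, 3, 3))
        rz = np.zeros((k, 3, 3))
        dx = np.zeros((k, 3, 3))
        dy = np.zeros((k, 3, 3))
        dz = np.zeros((k, 3, 3))
        rx[:, 0, 0] = 1.0
        rx[:, 1, 1] = c[:, 0]
        rx[:, 1, 2] = -s[:, 0]
        rx[:, 2, 1] = s[:, 0]
        rx[:, 2, 2] = c[:, 0]
        dx[:, 1, 1] = -s[:, 0]
        dx[:, 1, 2] = -c[:, 0]
        dx[:, 2, 1] = c[:, 0]
        dx[:, 2, 2] = -s[:, 0]
        ry[:, 0, 0] = c[:, 1]
        ry[:, 0, 2] = s[:, 1]
        ry[:, 1, 1] = 1.0
        ry[:, 2, 0] = -s[:, 1]
        ry[:, 2, 2] = c[:, 1]
        dy[:, 0, 0] = -s[:, 1]
        dy[:, 0, 2] = c[:, 1]
        dy[:, 2, 0] = -c[:, 1]
        dy[:, 2, 2] = -s[:, 1]
        rz[:, 0, 0] = c[:, 2]
        rz[:, 0, 1] = -s[:, 2]
        rz[:, 1, 0] = s[:, 2]
        rz[:, 1, 1] = c[:, 2]
        rz[:, 2, 2] = 1.0
        dz[:, 0, 0] = -s[:, 2]
        dz[:, 0, 1] = -c[:, 2]
        dz[:, 1, 0] = c[:, 2]
        dz[:, 1, 1] = -s[:, 2]
        ryrz = ry @ rz
        rots = rx @ ryrz
        partials = np.stack([dx @ ryrz, (rx @ dy) @ rz, (rx @ ry) @ dz],
                            axis=1)
        return rots, partials

    def forward(self, q: np.ndarray, want_jacobian: bool = True):
        t_p = q[0:3]
        rots7, parts7 = self._triples_vec(q[3:].reshape(7, 3))
        r_p = rots7[0]
        # cumulative rotations A[s][j] (j=0 pelvis .. 3 ankle) and joint
        # origins per side
        cum: list[list[np.ndarray]] = []
        orgs: list[list[np.ndarray]] = []
        for s in (0, 1):
            rots = [r_p]
            org_list = []
            org = t_p + r_p @ self.offsets[s][0]
            for j in range(3):
                rots.append(rots[-1] @ rots7[1 + 3 * s + j])
                org_list.append(org)
                if j < 2:
                    org = org + rots[-1] @ self.offsets[s][j + 1]
            cum.append(rots)
            orgs.append(org_list)

        n_m = self.locals_arr.shape[0]
        pred = np.empty((n_m, 3))
        for s, d, idx in self.pred_groups:
            if d == 0:
                pred[idx] = t_p + self.locals_arr[idx] @ r_p.T
            else:
                pred[idx] = orgs[s][d - 1] \
                    + self.locals_arr[idx] @ cum[s][d].T
        if not want_jacobian:
            return pred, None

        jac = np.zeros((n_m, 3, 24))
        jac[:, 0, 0] = 1.0
        jac[:, 1, 1] = 1.0
        jac[:, 2, 2] = 1.0
        rel_p = pred - t_p
        for i in range(3):
            b = parts7[0, i] @ r_p.T
            jac[:, :, 3 + i] = rel_p @ b.T
        for s in (0, 1):
            base = 6 + 9 * s
            for j in range(3):
                idx = self.group_idx[(s, j + 1)]
                if idx.size == 0:
                    continue
                rel = pred[idx] - orgs[s][j]
                a_prev = cum[s][j]
                a_post = cum[s][j + 1]
                for i in range(3):
                    b = a_prev @ parts7[1 + 3 * s + j, i] @ a_post.T
                    jac[idx, :, base + 3 * j + i] = rel @ b.T
        return pred, jac

    def q_to_poses(self, q: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        t_p = q[0:3]
        rots7, _ = self._triples_vec(q[3:].reshape(7, 3))
        r_p = rots7[0]
        out = {"pelvis": (r_p, t_p)}
        for s, side in enumerate(self.sides):
            rot = r_p
            org = t_p + r_p @ self.offsets[s][0]
            for j, name in enumerate((f"thigh_{side}", f"shank_{side}",
                                      f"foot_{side}")):
                rot = rot @ rots7[1 + 3 * s + j]
                if j == 2:
                    org_seg = org - rot @ self.model.joint_centers_local[
                        f"ankle_in_foot_{side}"]
                else:
                    org_seg = org
                out[name] = (rot, org_seg)
                if j < 2:
                    org = org + rot @ self.offsets[s][j + 1]
        return out


def _initial_q(trial: TrialData, model: SubjectModel, chain: _Chain,
               frame: int) -> np.ndarray:
    """Initialize generalized coordinates from per-segment rigid fits."""
    q = np.zeros(24)
    fitted: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def fit_segment(name: str, hjc_lab: dict[str, np.ndarray]) -> None:
        seg = model.segments[name]
        rows_obs, rows_loc = [], []
        for i, lab in enumerate(seg.tracking_labels):
            if lab.startswith("HJC_"):
                side = lab.split("_")[1]
                if side in hjc_lab:
                    rows_obs.append(hjc_lab[side])
                    rows_loc.append(seg.tracking_locals[i])
            elif lab in trial.marker_labels:
                rows_obs.append(trial.marker(lab)[frame])
                rows_loc.append(seg.tracking_locals[i])
        if len(rows_obs) < 3:
            return
        obs = np.stack(rows_obs)
        locs = np.stack(rows_loc)
        ok = np.all(np.isfinite(obs), axis=1)
        if ok.sum() >= 3:
            try:
                rot, org, _ = fit_rigid(locs[ok], obs[ok])
                fitted[name] = (rot, org)
            except DegenerateGeometryError:
                pass

    fit_segment("pelvis", {})
    if "pelvis" not in fitted:
        raise ConvergenceError("cannot initialize IK: pelvis untrackable")
    r_p, t_p = fitted["pelvis"]
    hjc_lab = {side: t_p + r_p @ model.joint_centers_local[f"hip_{side}"]
               for side in chain.sides}
    for name in model.segments:
        if name != "pelvis":
            fit_segment(name, hjc_lab)
    q[0:3] = t_p
    q[3:6] = np.deg2rad(cardan_xyz_decompose(r_p))
    for s, side in enumerate(chain.sides):
        base = 6 + 9 * s
        parent_r = r_p
        for j, seg_base in enumerate(("thigh", "shank", "foot")):
            name = f"{seg_base}_{side}"
            if name in fitted:
                r_rel = parent_r.T @ fitted[name][0]
                q[base + 3 * j: base + 3 * j + 3] = np.deg2rad(
                    cardan_xyz_decompose(r_rel))
                parent_r = fitted[name][0]
            # else: keep zeros (calibration pose), parent unchanged
    return q


def solve_ik_trajectory(trial: TrialData, model: SubjectModel,
                        max_iterations: int = 200,
                        gradient_tol: float = 1e-10,
                        step_tol: float = 1e-12,
                        record_diagnostics: bool = False
                        ) -> SegmentPoseSeries:
    """Whole-chain inverse kinematics over all frames of a trial.

    Per frame, minimizes the sum of squared marker residuals over the 24
    generalized coordinates with a damped Gauss-Newton iteration (analytic
    Jacobian, monotone cost by step rejection), warm-started from the
    previous frame.  Non-converged frames are flagged invalid with
    diagnostics rather than raising.
    """
    if model.joint_model != "ik":
        raise InvalidParameterError(
            f"model {model.protocol} is not an IK variant")
    labels_by_segment = {
        name: [lab for lab in seg.tracking_labels
               if not lab.startswith("HJC_") and lab in trial.marker_labels]
        for name, seg in model.segments.items()}
    chain = _Chain(model, labels_by_segment)
    obs_all = _observed_tracking(trial, chain.marker_labels)
    n = trial.n_frames
    names = list(model.segments)
    rotations = {s: np.full((n, 3, 3), np.nan) for s in names}
    origins = {s: np.full((n, 3), np.nan) for s in names}
    residuals = {s: np.full(n, np.nan) for s in names}
    valid = {s: np.zeros(n, dtype=bool) for s in names}
    diag: dict = {"cost_histories": [], "failed_frames": []}

    q = None
    for f in range(n):
        obs = obs_all[f]
        ok = np.all(np.isfinite(obs), axis=1)
        if ok.sum() < 8:  # not enough markers to pin 24 DoF meaningfully
            diag["failed_frames"].append(f)
            continue
        if q is None:
            q = _initial_q(trial, model, chain, f)
        q, cost_hist, converged = _lm_solve(
            chain, obs, ok, q, max_iterations, gradient_tol, step_tol)
        if record_diagnostics:
            diag["cost_histories"].append(np.array(cost_hist))
        if not converged:
            diag["failed_frames"].append(f)
            # a frame that hits the iteration cap while the cost is still
            # creeping below 1e-4 relative per step is practically
            # stationary: keep its pose, leave the frame flagged above
            if len(cost_hist) >= 2:
                rel = (cost_hist[-2] - cost_hist[-1]) \
                    / max(cost_hist[-1], 1e-12)
                converged = rel < 1e-4
        poses_f = chain.q_to_poses(q)
        pred, _ = chain.forward(q, want_jacobian=False)
        rms_all = float(np.sqrt(np.mean(
            np.sum((pred[ok] - obs[ok]) ** 2, axis=1))))
        for name in names:
            rot, org = poses_f[name]
            rotations[name][f] = rot
            origins[name][f] = org
            residuals[name][f] = rms_all
            valid[name][f] = converged
    return SegmentPoseSeries(rotations=rotations, origins=origins,
                             residuals=residuals, valid=valid,
                             rate=trial.marker_rate, diagnostics=diag)


def _lm_solve(chain: _Chain, obs: np.ndarray, ok: np.ndarray, q0: np.ndarray,
              max_iterations: int, gradient_tol: float, step_tol: float
              ) -> tuple[np.ndarray, list[float], bool]:
    q = q0.copy()
    lam = 1e-6  # warm starts are close; start near Gauss-Newton
    pred, jac = chain.forward(q)
    r = (pred[ok] - obs[ok]).ravel()
    jmat = jac[ok].reshape(-1, 24)
    cost = 0.5 * float(r @ r)
    history = [cost]
    converged = False
    for _ in range(max_iterations):
        g = jmat.T @ r
        if np.linalg.norm(g) < gradient_tol:
            converged = True
            break
        h = jmat.T @ jmat
        diag_h = np.diag(h).copy()
        diag_h[diag_h <= 0] = 1.0
        accepted = False
        for _ in range(25):
            try:
                step = np.linalg.solve(h + lam * np.diag(diag_h), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            q_new = q + step
            pred_new, jac_new = chain.forward(q_new)
            r_new = (pred_new[ok] - obs[ok]).ravel()
            cost_new = 0.5 * float(r_new @ r_new)
            if cost_new <= cost:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            converged = True  # cannot improve further at numerical precision
            break
        step_norm = float(np.linalg.norm(step))
        q, r, jmat = q_new, r_new, jac_new[ok].reshape(-1, 24)
        improvement = cost - cost_new
        cost = cost_new
        history.append(cost)
        lam = max(lam / 3.0, 1e-12)
        if step_norm < step_tol or improvement < 1e-12 * max(cost, 1.0):
            converged = True
            break
    return q, history, converged
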