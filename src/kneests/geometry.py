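"""Rotation and rigid-body primitives.

Conventions used throughout the package:

* lab frame: right-handed, ``X`` anterior (subject facing +X), ``Y`` toward
  the subject's left, ``Z`` vertical up;
* segment frames: ``X`` mediolateral pointing to the subject's *right*,
  ``Y`` anterior, ``Z`` longitudinal (up in the calibration pose);
* Cardan sequence: fixed ``X-Y-Z`` order, ``R = Rx(tx) @ Ry(ty) @ Rz(tz)``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateGeometryError, InvalidParameterError

GIMBAL_GUARD_DEG = 89.0


def rot_x(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def drot_x(angle_rad: float) -> np.ndarray:
    """d/da of rot_x."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[0.0, 0.0, 0.0], [0.0, -s, -c], [0.0, c, -s]])


def drot_y(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[-s, 0.0, c], [0.0, 0.0, 0.0], [-c, 0.0, -s]])


def drot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[-s, -c, 0.0], [c, -s, 0.0], [0.0, 0.0, 0.0]])


def cardan_xyz_compose(theta_x_deg: float, theta_y_deg: float,
                       theta_z_deg: float) -> np.ndarray:
    """Compose a rotation matrix from Cardan X-Y-Z angles in degrees."""
    tx, ty, tz = np.deg2rad([theta_x_deg, theta_y_deg, theta_z_deg])
    return rot_x(tx) @ rot_y(ty) @ rot_z(tz)


def cardan_xyz_decompose(rotation: np.ndarray) -> tuple[float, float, float]:
    """Decompose a proper rotation into Cardan X-Y-Z angles in degrees.

    ``R = Rx(tx) @ Ry(ty) @ Rz(tz)``.  The middle angle is taken in
    ``[-90, 90]`` degrees; near the gimbal singularity (|ty| >= 89 deg) a
    warning is emitted and the ``tx`` branch with ``tz = 0`` is returned.
    """
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise InvalidParameterError("rotation must be a 3x3 matrix")
    s_y = float(np.clip(rotation[0, 2], -1.0, 1.0))
    theta_y = np.arcsin(s_y)
    if np.abs(np.rad2deg(theta_y)) >= GIMBAL_GUARD_DEG:
        warnings.warn(
            "Cardan X-Y-Z decomposition near gimbal lock (|theta_y| >= "
            f"{GIMBAL_GUARD_DEG} deg); returning theta_z = 0 branch",
            RuntimeWarning,
            stacklevel=2,
        )
        # cos(ty) ~ 0: only tx +/- tz observable; report it all as tx.
        theta_x = np.arctan2(rotation[2, 1], rotation[1, 1])
        theta_z = 0.0
    else:
        theta_x = np.arctan2(-rotation[1, 2], rotation[2, 2])
        theta_z = np.arctan2(-rotation[0, 1], rotation[0, 0])
    return (float(np.rad2deg(theta_x)), float(np.rad2deg(theta_y)),
            float(np.rad2deg(theta_z)))


def fit_rigid(local_coords: np.ndarray, observed: np.ndarray,
              weights: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares rigid transform ``observed ~ R @ local + t``.

    SVD (Kabsch) solution with the proper-rotation constraint
    ``det(R) = +1`` enforced.  Returns ``(R, t, rms_residual)``.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, or (near-)collinear configuration.
    """
    local_coords = np.asarray(local_coords, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if local_coords.shape != observed.shape or local_coords.ndim != 2 \
            or local_coords.shape[1] != 3:
        raise InvalidParameterError("point arrays must both be (k, 3)")
    k = local_coords.shape[0]
    if k < 3:
        raise DegenerateGeometryError(
            f"rigid fit needs >= 3 points, got {k}")
    if not (np.all(np.isfinite(local_coords)) and np.all(np.isfinite(observed))):
        raise InvalidParameterError("non-finite point coordinates")
    if weights is None:
        w = np.ones(k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k,) or np.any(w < 0) or w.sum() <= 0:
            raise InvalidParameterError("weights must be k non-negative values")
    w = w / w.sum()

    mu_l = w @ local_coords
    mu_o = w @ observed
    pl = local_coords - mu_l
    po = observed - mu_o
    # collinearity check on the local configuration
    sv = np.linalg.svd(pl, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are (near-)collinear")
    h = (pl * w[:, None]).T @ po
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = mu_o - rotation @ mu_l
    misfit = observed - (local_coords @ rotation.T + translation)
    rms = float(np.sqrt(np.mean(np.sum(misfit**2, axis=1))))
    return rotation, translation, rms


def orthonormal_frame(axis_primary: np.ndarray, axis_secondary: np.ndarray,
                      order: tuple[str, str] = ("z", "x")) -> np.ndarray:
    """Build a right-handed rotation matrix (columns = frame axes in lab).

    ``axis_primary`` becomes the exact axis named by ``order[0]``;
    ``axis_secondary`` fixes the plane of the axis named by ``order[1]``.
    """
    names = ("x", "y", "z")
    i = names.index(order[0])
    j = names.index(order[1])
    if i == j:
        raise InvalidParameterError("primary and secondary axes must differ")
    e_i = np.asarray(axis_primary, dtype=float)
    n = np.linalg.norm(e_i)
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length primary axis")
    e_i = e_i / n
    sec = np.asarray(axis_secondary, dtype=float)
    sec = sec - (sec @ e_i) * e_i
    n = np.linalg.norm(sec)
    if n < 1e-9:
        raise DegenerateGeometryError("secondary axis parallel to primary")
    e_j = sec / n
    k = 3 - i - j
    e_k = np.cross(e_i, e_j)
    # sign so that columns (x, y, z) are right-handed: x cross y = z cyclic
    if (j - i) % 3 == 1:  # (i, j, k) is a cyclic permutation
        cols = {i: e_i, j: e_j, k: e_k}
    else:
        cols = {i: e_i, j: e_j, k: -e_k}
    rotation = np.column_stack([cols[0], cols[1], cols[2]])
    if np.linalg.det(rotation) < 0:  # pragma: no cover - defensive
        raise DegenerateGeometryError("frame construction produced a reflection")
    return rotation


def angular_velocity_from_rotations(rotations: np.ndarray, rate: float
                                    ) -> np.ndarray:
    """Angular velocity (rad/s, lab frame) from a series of rotations.

    Central differences of ``R`` with one-sided ends; the skew-symmetric
    part of ``dR/dt @ R.T`` is extracted.
    """
    rotations = np.asarray(rotations, dtype=float)
    n = rotations.shape[0]
    if n < 3:
        raise InvalidParameterError("need >= 3 frames for differentiation")
    drdt = np.empty_like(rotations)
    drdt[1:-1] = (rotations[2:] - rotations[:-2]) * (rate / 2.0)
    drdt[0] = (rotations[1] - rotations[0]) * rate
    drdt[-1] = (rotations[-1] - rotations[-2]) * rate
    omega_hat = np.einsum("fij,fkj->fik", drdt, rotations)
    omega_hat = 0.5 * (omega_hat - np.swapaxes(omega_hat, 1, 2))
    return np.stack([omega_hat[:, 2, 1], omega_hat[:, 0, 2],
                     omega_hat[:, 1, 0]], axis=1)


def central_difference(series: np.ndarray, rate: float, order: int = 1
                       ) -> np.ndarray:
    """First or second time derivative by central differences.

    Endpoints use one-sided first differences (first order) or replicate the
    adjacent interior value (second order).
    """
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 3:
        raise InvalidParameterError("need >= 3 samples for differentiation")
    if order == 1:
        d = np.empty_like(x)
        d[1:-1] = (x[2:] - x[:-2]) * (rate / 2.0)
        d[0] = (x[1] - x[0]) * rate
        d[-1] = (x[-1] - x[-2]) * rate
        return d
    if order == 2:
        d = np.empty_like(x)
        d[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) * rate**2
        d[0] = d[1]
        d[-1] = d[-2]
        return d
    raise InvalidParameterError("order must be 1 or 2")
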