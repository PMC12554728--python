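"""Trial containers, signal conditioning, and plain-text trial I/O.

A recording couples marker trajectories (mm, lab frame, 100 Hz) with
force-plate analog signals (N / N mm, 1000 Hz).  Files are exchanged in a
fixed plain-text dialect: UTF-8, tab-separated, one header row, one row per
frame, ``<marker>_X/_Y/_Z`` columns in mm, 0-based ``frame`` column; analog
channels live in a sibling ``*_analog.tsv`` and scalar metadata in a JSON
sidecar.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import FormatError, InvalidParameterError

GRAVITY = 9.80665  # m s^-2

#: cutoff (Hz) applied to marker trajectories before differentiation
MARKER_CUTOFF_HZ = 6.0
#: cutoff (Hz) applied to force-plate signals
GRF_CUTOFF_HZ = 50.0


@dataclass
class FilterSpec:
    """Low-pass Butterworth specification.

    ``order`` is the *effective* order.  With ``zero_phase`` the signal is
    run forward and backward through an ``order/2`` design, the standard
    movement-analysis reading of an "N-th order zero-lag" filter; set
    ``literal_order_per_pass`` to design the full order per pass instead.
    """

    cutoff: float
    order: int = 4
    zero_phase: bool = True
    literal_order_per_pass: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise InvalidParameterError("cutoff must be positive")
        if self.order < 1:
            raise InvalidParameterError("order must be >= 1")
        if self.zero_phase and not self.literal_order_per_pass \
                and self.order % 2:
            raise InvalidParameterError(
                "effective order must be even for a zero-phase dual pass")

    def design_order(self) -> int:
        if self.zero_phase and not self.literal_order_per_pass:
            return self.order // 2
        return self.order


@dataclass
class TrialData:
    """One synchronized recording (markers + force plates + metadata)."""

    marker_positions: np.ndarray  # (frames, markers, 3) mm; NaN = gap
    marker_labels: list[str]
    marker_rate: float  # Hz
    analog_rate: float  # Hz
    plate_forces: np.ndarray  # (plates, analog_frames, 3) N
    plate_cops: np.ndarray  # (plates, analog_frames, 3) mm
    plate_free_moments: np.ndarray  # (plates, analog_frames) N mm about Z
    body_mass: float  # kg
    side_map: dict[str, int] = field(default_factory=lambda: {"right": 0,
                                                              "left": 1})
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.marker_positions = np.asarray(self.marker_positions, dtype=float)
        if self.marker_positions.ndim != 3 or self.marker_positions.shape[2] != 3:
            raise InvalidParameterError("marker_positions must be (F, M, 3)")
        if len(self.marker_labels) != self.marker_positions.shape[1]:
            raise InvalidParameterError("one label per marker required")
        if len(set(self.marker_labels)) != len(self.marker_labels):
            raise InvalidParameterError("marker labels must be unique")
        if self.marker_rate <= 0 or self.analog_rate <= 0:
            raise InvalidParameterError("rates must be positive")
        ratio = self.analog_rate / self.marker_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidParameterError(
                "analog_rate must be an integer multiple of marker_rate")
        if self.body_mass <= 0:
            raise InvalidParameterError("body_mass must be positive")

    @property
    def n_frames(self) -> int:
        return self.marker_positions.shape[0]

    @property
    def n_plates(self) -> int:
        return self.plate_forces.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.marker_labels.index(label)
        except ValueError:
            raise InvalidParameterError(f"unknown marker label {label!r}") from None

    def marker(self, label: str) -> np.ndarray:
        """Trajectory (frames, 3) of one labelled marker."""
        return self.marker_positions[:, self.index(label), :]


def butterworth_lowpass(signal_in: np.ndarray, spec: FilterSpec | float,
                        rate: float, axis: int = 0) -> np.ndarray:
    """Low-pass Butterworth filter with reflection padding.

    Zero-phase specs run ``scipy.signal.filtfilt`` (odd-reflection padding of
    at least three filter lengths); causal specs run a single forward pass.
    """
    if not isinstance(spec, FilterSpec):
        spec = FilterSpec(cutoff=float(spec))
    x = np.asarray(signal_in, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("signal contains non-finite values")
    nyq = rate / 2.0
    if spec.cutoff >= nyq:
        raise InvalidParameterError(
            f"cutoff {spec.cutoff} Hz >= Nyquist {nyq} Hz")
    b, a = sps.butter(spec.design_order(), spec.cutoff / nyq, btype="low")
    if spec.zero_phase:
        ntaps = max(len(a), len(b))
        padlen = min(x.shape[axis] - 1, 3 * 3 * (ntaps - 1))
        return sps.filtfilt(b, a, x, axis=axis, padtype="odd", padlen=padlen)
    return sps.lfilter(b, a, x, axis=axis)


def dual_pass_gain(spec: FilterSpec, rate: float, freq: float) -> float:
    """Analytic steady-state amplitude gain of the realized filter at ``freq``.

    Evaluates the digital transfer function of the designed pass; squared for
    zero-phase (forward-backward) operation.
    """
    if not isinstance(spec, FilterSpec):
        raise InvalidParameterError("spec must be a FilterSpec")
    b, a = sps.butter(spec.design_order(), spec.cutoff / (rate / 2.0),
                      btype="low")
    _, h = sps.freqz(b, a, worN=[2.0 * np.pi * freq / rate])
    gain = float(np.abs(h[0]))
    return gain**2 if spec.zero_phase else gain


def fill_gaps(trajectory: np.ndarray, max_gap_frames: int = 10
              ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Fill NaN gaps of at most ``max_gap_frames`` by cubic-spline interpolation.

    Returns the filled trajectory and the list of (start, stop) index ranges
    (half-open) of gaps left unfilled because they were too long or touched
    the trial boundary.
    """
    x = np.asarray(trajectory, dtype=float).copy()
    if x.ndim == 1:
        x = x[:, None]
        squeeze = True
    else:
        squeeze = False
    valid = np.all(np.isfinite(x), axis=1)
    if not valid.any():
        raise InvalidParameterError("trajectory contains no valid samples")
    if valid.all():
        out = x[:, 0] if squeeze else x
        return out, []
    idx = np.arange(x.shape[0])
    # enumerate gap runs
    runs: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(valid):
        if not ok and start is None:
            start = i
        elif ok and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(valid)))
    spline = CubicSpline(idx[valid], x[valid], axis=0)
    unfilled: list[tuple[int, int]] = []
    for a, b in runs:
        interior = a > 0 and b < len(valid)
        if interior and (b - a) <= max_gap_frames:
            x[a:b] = spline(idx[a:b])
        else:
            unfilled.append((a, b))
    out = x[:, 0] if squeeze else x
    return out, unfilled


def resample_to_marker_rate(analog_signal: np.ndarray, analog_rate: float,
                            marker_rate: float,
                            prefilter: FilterSpec | None = None,
                            axis: int = 0) -> np.ndarray:
    """Decimate an analog channel onto the kinematic time base.

    The signal is low-pass filtered (default: the 50 Hz zero-phase GRF
    filter) and then sub-sampled so output frame ``i`` falls at time
    ``i / marker_rate``.
    """
    ratio = analog_rate / marker_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise InvalidParameterError(
            "analog rate must be an integer multiple of the marker rate")
    ratio = int(round(ratio))
    if prefilter is None:
        prefilter = FilterSpec(cutoff=GRF_CUTOFF_HZ)
    x = butterworth_lowpass(analog_signal, prefilter, analog_rate, axis=axis)
    slicer = [slice(None)] * x.ndim
    slicer[axis] = slice(None, None, ratio)
    return x[tuple(slicer)]


# ---------------------------------------------------------------------------
# plain-text trial I/O


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_trial_tsv(trial: TrialData, basepath: str | Path) -> dict[str, Path]:
    """Write a trial as ``<base>_markers.tsv``, ``<base>_analog.tsv`` and
    ``<base>_meta.json`` (atomically).  Gap frames are stored as ``NaN``."""
    if not trial.marker_labels:
        raise InvalidParameterError("trial has no markers")
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)

    cols = {"frame": np.arange(trial.n_frames)}
    for m, label in enumerate(trial.marker_labels):
        for k, ax in enumerate("XYZ"):
            cols[f"{label}_{ax}"] = trial.marker_positions[:, m, k]
    markers = pd.DataFrame(cols)

    n_analog = trial.plate_forces.shape[1]
    acols = {"frame": np.arange(n_analog)}
    for p in range(trial.n_plates):
        for k, ax in enumerate("XYZ"):
            acols[f"P{p + 1}_F{ax}"] = trial.plate_forces[p, :, k]
        for k, ax in enumerate("XYZ"):
            acols[f"P{p + 1}_COP{ax}"] = trial.plate_cops[p, :, k]
        acols[f"P{p + 1}_MZ"] = trial.plate_free_moments[p, :]
    analog = pd.DataFrame(acols)

    meta = {
        "marker_rate": trial.marker_rate,
        "analog_rate": trial.analog_rate,
        "body_mass": trial.body_mass,
        "side_map": trial.side_map,
        "n_plates": trial.n_plates,
        "units": {"position": "mm", "force": "N", "free_moment": "N mm"},
        "meta": trial.meta,
    }

    paths = {
        "markers": base.parent / f"{base.name}_markers.tsv",
        "analog": base.parent / f"{base.name}_analog.tsv",
        "meta": base.parent / f"{base.name}_meta.json",
    }
    _atomic_write(paths["markers"],
                  markers.to_csv(sep="\t", index=False, float_format="%.6f"))
    _atomic_write(paths["analog"],
                  analog.to_csv(sep="\t", index=False, float_format="%.6f"))
    _atomic_write(paths["meta"], json.dumps(meta, indent=1, sort_keys=True))
    return paths


def read_trial_tsv(basepath: str | Path) -> TrialData:
    """Inverse of :func:`write_trial_tsv`."""
    base = Path(basepath)
    mpath = base.parent / f"{base.name}_markers.tsv"
    apath = base.parent / f"{base.name}_analog.tsv"
    jpath = base.parent / f"{base.name}_meta.json"
    for p in (mpath, apath, jpath):
        if not p.exists():
            raise FormatError(f"missing trial file {p}")
    try:
        meta = json.loads(jpath.read_text(encoding="utf-8"))
        markers = pd.read_csv(mpath, sep="\t")
        analog = pd.read_csv(apath, sep="\t")
    except (ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed trial file under {base}: {exc}") from exc

    label_cols = [c for c in markers.columns if c.endswith("_X")]
    labels = [c[:-2] for c in label_cols]
    if not labels:
        raise FormatError("marker table contains no <label>_X columns")
    frames = len(markers)
    pos = np.empty((frames, len(labels), 3))
    for m, label in enumerate(labels):
        for k, ax in enumerate("XYZ"):
            col = f"{label}_{ax}"
            if col not in markers.columns:
                raise FormatError(f"marker table missing column {col}")
            pos[:, m, k] = markers[col].to_numpy(dtype=float)

    n_plates = int(meta.get("n_plates", 0))
    n_analog = len(analog)
    forces = np.zeros((n_plates, n_analog, 3))
    cops = np.zeros((n_plates, n_analog, 3))
    free = np.zeros((n_plates, n_analog))
    for p in range(n_plates):
        for k, ax in enumerate("XYZ"):
            fcol, ccol = f"P{p + 1}_F{ax}", f"P{p + 1}_COP{ax}"
            if fcol not in analog.columns or ccol not in analog.columns:
                raise FormatError(f"analog table missing plate {p + 1} columns")
            forces[p, :, k] = analog[fcol].to_numpy(dtype=float)
            cops[p, :, k] = analog[ccol].to_numpy(dtype=float)
        free[p, :] = analog[f"P{p + 1}_MZ"].to_numpy(dtype=float)

    try:
        return TrialData(
            marker_positions=pos,
            marker_labels=labels,
            marker_rate=float(meta["marker_rate"]),
            analog_rate=float(meta["analog_rate"]),
            plate_forces=forces,
            plate_cops=cops,
            plate_free_moments=free,
            body_mass=float(meta["body_mass"]),
            side_map={k: int(v) for k, v in meta["side_map"].items()},
            meta=meta.get("meta", {}),
        )
    except (KeyError, InvalidParameterError) as exc:
        raise FormatError(f"invalid trial metadata under {base}: {exc}") from exc
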