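"""Sit-to-stand event detection, cycle cropping and repetition averaging.

Five events delimit the STS cycle, each found as the *first* frame
satisfying its rule after the previous event:

1. **onset** — hip angular velocity crosses zero from negative to
   positive (initiation of trunk flexion);
2. **seat-off** — summed vertical GRF surpasses a minimal 10 N threshold;
3. **standing** — the hip joint centre reaches and holds its maximum
   height within a +/-3 cm tolerance (``stand_start`` / ``stand_end``
   bound the plateau);
4. **seat-on** — vertical GRF drops back below 10 N;
5. **end** — hip angular velocity crosses zero again.

Feet resting on the plates while seated make the literal 10 N rule
physically ambiguous, so the default mode subtracts the seated-rest
median ("baseline-subtracted") before thresholding; ``"literal"`` applies
the threshold to the raw summed GRF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EventDetectionError, InvalidParameterError
from .io import MARKER_CUTOFF_HZ, FilterSpec, butterworth_lowpass
from .geometry import central_difference

EVENT_NAMES = ("onset", "seat_off", "stand_start", "stand_end", "seat_on",
               "end")


@dataclass
class EventDetectionConfig:
    grf_threshold: float = 10.0  # N
    stand_tolerance: float = 30.0  # mm (+/- 3 cm)
    baseline_mode: str = "baseline-subtracted"  # or "literal"
    velocity_smoothing: FilterSpec = field(
        default_factory=lambda: FilterSpec(cutoff=MARKER_CUTOFF_HZ))
    #: a candidate onset crossing only counts as "initiation of trunk
    #: flexion" if the velocity reaches this speed (deg/s) before
    #: reversing; guards against noise crossings during quiet sitting
    onset_confirm_velocity: float = 15.0

    def __post_init__(self) -> None:
        if self.grf_threshold <= 0 or self.stand_tolerance <= 0:
            raise InvalidParameterError(
                "threshold and tolerance must be positive")
        if self.baseline_mode not in ("baseline-subtracted", "literal"):
            raise InvalidParameterError(
                f"unknown baseline_mode {self.baseline_mode!r}")


@dataclass
class STSEvents:
    """0-based frame indices at the marker rate; strictly increasing."""

    onset: int
    seat_off: int
    stand_start: int
    stand_end: int
    seat_on: int
    end: int

    def __post_init__(self) -> None:
        seq = [getattr(self, name) for name in EVENT_NAMES]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise InvalidParameterError(
                f"event frames must be strictly increasing, got {seq}")

    def as_dict(self) -> dict[str, int]:
        return {name: int(getattr(self, name)) for name in EVENT_NAMES}


def _first_crossing(vel: np.ndarray, start: int,
                    direction: int | None) -> int | None:
    """First index >= start where the sign of ``vel`` flips (zeros skipped);
    ``direction`` restricts the post-crossing sign (+1 or -1)."""
    last = 0.0
    for i in range(start, len(vel)):
        s = float(np.sign(vel[i]))
        if s == 0.0:
            continue
        if last != 0.0 and s != last and (direction is None or s == direction):
            return i
        last = s
    return None


def _detect_onset(vel: np.ndarray, rate: float,
                  confirm_velocity: float, guard: int = 0) -> int | None:
    """Onset = the hip-velocity zero crossing that initiates trunk flexion.

    The first sustained flexion run (velocity above ``confirm_velocity/3``
    for >= 0.2 s, peaking above ``confirm_velocity``) identifies the actual
    movement; the onset is the first positive-velocity frame of the
    crossing immediately preceding it.  On signals whose pre-movement
    velocity never dips below zero (heavy soft-tissue artifact), the
    velocity minimum before the run is used instead.  On clean signals this
    reduces exactly to the first negative-to-positive crossing.
    """
    low = confirm_velocity / 3.0
    min_run = max(int(0.2 * rate), 2)
    above = vel > low
    i = guard
    big = None
    n = len(vel)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if (j - i + 1) >= min_run and np.max(vel[i:j + 1]) >= confirm_velocity:
            big = i
            break
        i = j + 1
    if big is None:
        return None
    nonpos = np.nonzero(vel[guard:big + 1] <= 0.0)[0]
    if nonpos.size:
        return guard + int(nonpos[-1]) + 1
    return guard + int(np.argmin(vel[guard:big + 1]))


def detect_sts_events(hip_flexion_deg: np.ndarray, vertical_grf: np.ndarray,
                      hip_height_mm: np.ndarray, rate: float,
                      config: EventDetectionConfig | None = None
                      ) -> STSEvents:
    """Detect the five STS events from marker-rate aligned signals.

    ``vertical_grf`` is the summed per-foot vertical GRF (N).  The hip
    flexion angle is low-pass filtered before differentiation.
    """
    config = config or EventDetectionConfig()
    hip = np.asarray(hip_flexion_deg, dtype=float)
    grf = np.asarray(vertical_grf, dtype=float)
    height = np.asarray(hip_height_mm, dtype=float)
    if not (len(hip) == len(grf) == len(height)):
        raise InvalidParameterError("signals must share the marker time base")
    if len(hip) < 10:
        raise InvalidParameterError("trial too short for event detection")
    if np.any(~np.isfinite(hip)) or np.any(~np.isfinite(grf)):
        raise InvalidParameterError("non-finite samples in event signals")

    hip_f = butterworth_lowpass(hip, config.velocity_smoothing, rate)
    vel = central_difference(hip_f, rate)

    # a short guard band keeps filter edge transients out of the search
    guard = int(0.25 * rate)
    onset = _detect_onset(vel, rate, config.onset_confirm_velocity, guard)
    if onset is None or onset < 1:
        raise EventDetectionError("onset",
                                  "no hip velocity zero crossing followed "
                                  "by sustained trunk flexion")
    if config.baseline_mode == "baseline-subtracted":
        baseline = float(np.median(grf[:onset])) if onset > 0 else 0.0
    else:
        baseline = 0.0
    adj = grf - baseline

    above = np.nonzero(adj[onset + 1:] > config.grf_threshold)[0]
    if above.size == 0:
        raise EventDetectionError("seat_off",
                                  f"GRF never surpasses "
                                  f"{config.grf_threshold} N")
    seat_off = onset + 1 + int(above[0])

    zmax = float(height[seat_off:].max())
    plateau = height >= zmax - config.stand_tolerance
    plateau[:seat_off + 1] = False
    if not plateau.any():
        raise EventDetectionError("stand_start",
                                  "hip never reaches its maximum height "
                                  "within tolerance")
    stand_start = int(np.argmax(plateau))
    stand_end = stand_start
    while stand_end + 1 < len(plateau) and plateau[stand_end + 1]:
        stand_end += 1
    if stand_end >= len(plateau) - 1:
        raise EventDetectionError("seat_on", "trial ends while standing")

    below = np.nonzero(adj[stand_end + 1:] < config.grf_threshold)[0]
    if below.size == 0:
        raise EventDetectionError("seat_on",
                                  f"GRF never drops below "
                                  f"{config.grf_threshold} N after standing")
    seat_on = stand_end + 1 + int(below[0])

    end = _first_crossing(vel, seat_on + 1, None)
    if end is None:
        raise EventDetectionError("end",
                                  "hip velocity never crosses zero after "
                                  "seat-on")
    return STSEvents(onset=onset, seat_off=seat_off, stand_start=stand_start,
                     stand_end=stand_end, seat_on=seat_on, end=end)


N_NODES = 101


def crop_and_normalize(series: np.ndarray, events: STSEvents,
                       n_nodes: int = N_NODES) -> np.ndarray:
    """Linear interpolation of ``series[onset:end]`` onto 0-100% nodes."""
    x = np.asarray(series, dtype=float)
    if x.shape[0] <= events.end:
        raise InvalidParameterError(
            f"series ({x.shape[0]} frames) shorter than the cycle "
            f"(end = {events.end})")
    frames = np.arange(x.shape[0], dtype=float)
    nodes = events.onset + (events.end - events.onset) \
        * np.arange(n_nodes) / (n_nodes - 1)
    if x.ndim == 1:
        return np.interp(nodes, frames, x)
    return np.stack([np.interp(nodes, frames, x[:, k])
                     for k in range(x.shape[1])], axis=1)


def average_repetitions(curves: list[np.ndarray]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Node-wise mean and sample SD over repetitions (>= 2 curves)."""
    if len(curves) < 2:
        raise InvalidParameterError("need >= 2 repetitions to average")
    arr = np.stack([np.asarray(c, dtype=float) for c in curves])
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("non-finite values in repetition curves")
    return arr.mean(axis=0), arr.std(axis=0, ddof=1)
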