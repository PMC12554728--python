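"""Protocol-variability statistics: MAV, MAD, clinical flags, Cohen's d.

* **MAV** (mean absolute variability): at each of the 101 time-normalized
  nodes, the range (max - min) of the four protocol outputs; averaged
  over nodes.  Computed per subject on the subject's repetition-mean
  curves, then averaged across the cohort.
* **MAD** (mean absolute difference): node-wise |a - b| averaged over
  nodes for one protocol pair; the absolute value prevents
  subject-specific differences of opposite sign from cancelling.
  Kinematic MADs are compared against a 5 deg clinical threshold
  (strictly greater flags as clinically meaningful).
* **Cohen's d** (paired): per protocol pair, from per-subject
  node-averaged curve values, ``d = mean(diff) / SD(diff)`` with the
  normal-approximation 95% CI ``d +/- 1.96 sqrt(1/n + d^2/(2n))``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

ANGLE_VARIABLES = ("KFA", "KAA", "KIRA")
MOMENT_VARIABLES = ("KFM", "KAM", "KIRM")
VARIABLES = ANGLE_VARIABLES + MOMENT_VARIABLES

CLINICAL_THRESHOLD_DEG = 5.0


def protocol_pairs(protocols: tuple[str, ...] | list[str]) -> list[tuple[str, str]]:
    """All unordered protocol pairs (C(4,2) = 6 for the full set)."""
    return list(itertools.combinations(protocols, 2))


def mav(curves: np.ndarray) -> float:
    """Mean absolute variability across exactly four protocol curves.

    ``curves`` is (4, nodes): per node the protocol range (max - min),
    averaged over nodes.
    """
    arr = np.asarray(curves, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 4:
        raise InvalidParameterError(
            f"MAV needs exactly 4 protocol curves, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("non-finite curve values")
    return float(np.mean(arr.max(axis=0) - arr.min(axis=0)))


def mad(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Mean absolute difference between two curves on common nodes."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError(
            f"curve length mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidParameterError("non-finite curve values")
    return float(np.mean(np.abs(a - b)))


def flag_clinical(mad_value: float, variable: str,
                  threshold: float = CLINICAL_THRESHOLD_DEG) -> bool:
    """True iff a kinematic MAD strictly exceeds the clinical threshold.

    The threshold is defined for joint angles only; applying it to moment
    variables is an error.
    """
    if variable in MOMENT_VARIABLES:
        raise InvalidParameterError(
            f"clinical threshold is defined for angles, not {variable}")
    if variable not in ANGLE_VARIABLES:
        raise InvalidParameterError(f"unknown variable {variable!r}")
    return bool(mad_value > threshold)


def cohens_d_paired(values_a: np.ndarray, values_b: np.ndarray
                    ) -> tuple[float, float, float]:
    """Paired Cohen's d with a normal-approximation 95% CI.

    ``d = mean(a - b) / SD(a - b)`` (sample SD);
    ``CI = d +/- 1.96 * sqrt(1/n + d^2 / (2n))``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("paired samples must be equal-length 1-D")
    n = a.shape[0]
    if n < 2:
        raise InvalidParameterError("need n >= 2 pairs")
    diff = a - b
    sd = float(np.std(diff, ddof=1))
    if sd <= 0:
        raise InvalidParameterError(
            "zero difference SD: paired effect size undefined")
    d = float(np.mean(diff)) / sd
    half = 1.96 * np.sqrt(1.0 / n + d**2 / (2.0 * n))
    return d, d - half, d + half


# ---------------------------------------------------------------------------
# cohort-level reports


@dataclass
class VariabilityReport:
    """Cohort MAV per variable/side + the per-subject values behind it."""

    mav_mean: dict[tuple[str, str], float]  # (variable, side_label)
    per_subject: dict[tuple[str, str], np.ndarray]
    aggregation: str = "per-subject mean curves, averaged across subjects"


@dataclass
class PairwiseDifferenceReport:
    """Cohort MAD per pair/variable/side with clinical flags for angles."""

    mad_mean: dict[tuple[tuple[str, str], str, str], float]
    per_subject: dict[tuple[tuple[str, str], str, str], np.ndarray]
    clinical_flags: dict[tuple[tuple[str, str], str, str], bool]
    threshold: float = CLINICAL_THRESHOLD_DEG


@dataclass
class EffectSizeReport:
    """Paired Cohen's d (95% CI) per pair/variable/side."""

    d: dict[tuple[tuple[str, str], str, str], tuple[float, float, float]]
    n: int
    basis: str = "per-subject node-averaged curve values"


def summarize_cohort(curves: dict,
                     protocols: tuple[str, ...],
                     sides: tuple[str, ...] = ("tka", "contralateral"),
                     variables: tuple[str, ...] = VARIABLES,
                     threshold: float = CLINICAL_THRESHOLD_DEG
                     ) -> tuple[VariabilityReport, PairwiseDifferenceReport,
                                EffectSizeReport]:
    """Cohort statistics from per-subject mean curves.

    ``curves[(subject, protocol, side, variable)]`` is a (101,) mean curve.
    Subjects are inferred from the keys; every protocol must be present
    for every subject/side/variable.
    """
    subjects = sorted({k[0] for k in curves})
    if len(subjects) < 2:
        raise InvalidParameterError("need >= 2 subjects")
    pairs = protocol_pairs(protocols)

    mav_mean, mav_sub = {}, {}
    mad_mean, mad_sub, flags = {}, {}, {}
    d_report = {}
    for side in sides:
        for var in variables:
            per_subj_mav = []
            for subj in subjects:
                try:
                    stack = np.stack([curves[(subj, p, side, var)]
                                      for p in protocols])
                except KeyError as exc:
                    raise InvalidParameterError(
                        f"missing protocol curve {exc} for subject {subj}"
                    ) from exc
                per_subj_mav.append(mav(stack) if len(protocols) == 4
                                    else float(np.mean(stack.max(axis=0)
                                                       - stack.min(axis=0))))
            mav_sub[(var, side)] = np.array(per_subj_mav)
            mav_mean[(var, side)] = float(np.mean(per_subj_mav))
            for pair in pairs:
                vals = np.array([
                    mad(curves[(subj, pair[0], side, var)],
                        curves[(subj, pair[1], side, var)])
                    for subj in subjects])
                mad_sub[(pair, var, side)] = vals
                mad_mean[(pair, var, side)] = float(vals.mean())
                if var in ANGLE_VARIABLES:
                    flags[(pair, var, side)] = flag_clinical(
                        float(vals.mean()), var, threshold)
                scalar_a = np.array([
                    float(np.mean(curves[(subj, pair[0], side, var)]))
                    for subj in subjects])
                scalar_b = np.array([
                    float(np.mean(curves[(subj, pair[1], side, var)]))
                    for subj in subjects])
                try:
                    d_report[(pair, var, side)] = cohens_d_paired(scalar_a,
                                                                  scalar_b)
                except InvalidParameterError:
                    d_report[(pair, var, side)] = (np.nan, np.nan, np.nan)
    return (VariabilityReport(mav_mean=mav_mean, per_subject=mav_sub),
            PairwiseDifferenceReport(mad_mean=mad_mean, per_subject=mad_sub,
                                     clinical_flags=flags,
                                     threshold=threshold),
            EffectSizeReport(d=d_report, n=len(subjects)))
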