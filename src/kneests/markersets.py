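"""Marker-set specifications (IOR- and CAST-style protocols).

Specs live in YAML data files so the exact marker complements — in
particular which markers are removed for dynamic trials, something usually
reported only as counts — stay configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import InvalidParameterError

SIDES = ("right", "left")
SIDE_PREFIX = {"right": "R", "left": "L"}
SIDE_SEGMENTS = ("thigh", "shank", "foot")


@dataclass
class SegmentMarkers:
    """Markers attached to one segment."""

    segment: str  # e.g. "thigh_right"
    markers: list[str]  # full (static) complement
    tracking: list[str]  # dynamic tracking targets
    augment_hip_center: bool = False
    side: str | None = None  # None for pelvis


@dataclass
class MarkerSetSpec:
    """A complete protocol marker set, expanded to explicit L/R labels."""

    name: str
    segments: dict[str, SegmentMarkers]
    static_only: list[str] = field(default_factory=list)

    @property
    def static_labels(self) -> list[str]:
        out: list[str] = []
        for seg in self.segments.values():
            out.extend(seg.markers)
        return out

    @property
    def dynamic_labels(self) -> list[str]:
        drop = set(self.static_only)
        return [m for m in self.static_labels if m not in drop]

    def segment_of(self, label: str) -> str:
        for seg in self.segments.values():
            if label in seg.markers:
                return seg.segment
        raise InvalidParameterError(f"label {label!r} not in marker set "
                                    f"{self.name}")


def _expand(template: str, side: str) -> str:
    return template.replace("{S}", SIDE_PREFIX[side])


def load_marker_set(name_or_path: str | Path) -> MarkerSetSpec:
    """Load a marker-set spec by bundled name (``"IOR"``/``"CAST"``) or path."""
    name = str(name_or_path)
    if name.upper() in ("IOR", "CAST"):
        text = (resources.files("kneests.data") / f"{name.lower()}.yaml"
                ).read_text(encoding="utf-8")
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise InvalidParameterError(
                f"unknown marker set {name_or_path!r} (not IOR/CAST or a path)")
        text = path.read_text(encoding="utf-8")
    raw = yaml.safe_load(text)

    segments: dict[str, SegmentMarkers] = {}
    pelvis = raw["pelvis"]
    segments["pelvis"] = SegmentMarkers(
        segment="pelvis", markers=list(pelvis["markers"]),
        tracking=list(pelvis["tracking"]))
    for side in SIDES:
        for seg_name, seg in raw["per_side"].items():
            if seg_name not in SIDE_SEGMENTS:
                raise InvalidParameterError(
                    f"unknown per-side segment {seg_name!r}")
            full = f"{seg_name}_{side}"
            segments[full] = SegmentMarkers(
                segment=full,
                markers=[_expand(m, side) for m in seg["markers"]],
                tracking=[_expand(m, side) for m in seg["tracking"]],
                augment_hip_center=bool(seg.get("augment_hip_center", False)),
                side=side,
            )
    static_only = [_expand(m, side)
                   for side in SIDES for m in raw.get("static_only", [])]
    spec = MarkerSetSpec(name=str(raw["name"]), segments=segments,
                         static_only=static_only)
    labels = spec.static_labels
    if len(set(labels)) != len(labels):
        raise InvalidParameterError(f"duplicate labels in marker set {spec.name}")
    return spec


def combined_static_labels() -> list[str]:
    """Union of the IOR and CAST static complements (shared labels once)."""
    ior = load_marker_set("IOR").static_labels
    cast = load_marker_set("CAST").static_labels
    out = list(ior)
    out.extend(label for label in cast if label not in out)
    return out
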