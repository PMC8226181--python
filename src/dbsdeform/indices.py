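"""Per-electrode scalar indices.

Covers the scalar quantities reported per implanted lead: intracranial
length (chord, not arc), the percentage of that length occupied by the
stiff distal contact block (7.5 mm for non-directional leads, 21.5 mm for
directional ones), the percentage crossing the extracerebral space, the
brain shift index (frontal pneumocephalus volume over hemisphere volume,
in units of 1e-4 %), and the surgical-related inaccuracy (Euclidean
distance between the intraoperatively selected optimal point and the
achieved contact point, at 0.1 mm planning-software resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateCurveError, InvalidArgumentError

#: stiff distal segment length (mm) by electrode type
RIGID_LENGTHS = {"non_directional": 7.5, "directional": 21.5}

#: planning-software geometric resolution (mm)
DISTANCE_RESOLUTION_MM = 0.1


@dataclass(frozen=True)
class AirBubble:
    """Frontal air bubble dimensions (mm) measured against the frontal pole."""

    height: float
    width: float
    thickness: float

    def __post_init__(self):
        for name in ("height", "width", "thickness"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidArgumentError(f"bubble {name} must be finite and >= 0, got {v}")

    def box_volume(self) -> float:
        """Rectangular volume estimate (mm^3); a deliberate overestimate."""
        return self.height * self.width * self.thickness

    def ellipsoid_volume(self) -> float:
        """Ellipsoid alternative (pi/6 of the box), available by config."""
        return np.pi / 6.0 * self.box_volume()


@dataclass
class ElectrodeRecord:
    """One implanted lead's scalar indices and regional summaries."""

    patient: str
    hemisphere: str
    electrode_type: str
    target: str
    chord_length_mm: float
    rigid_pct: float
    extracerebral_pct: float
    brain_shift_index: float
    surgical_inaccuracy_mm: float
    regional: list = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.rigid_pct <= 100.0 and 0.0 <= self.extracerebral_pct <= 100.0):
            raise InvalidArgumentError("percentages must lie in [0, 100]")
        if self.brain_shift_index < 0 or self.surgical_inaccuracy_mm < 0:
            raise InvalidArgumentError("indices must be non-negative")


def electrode_length(curve) -> float:
    """Intracranial lead length: Euclidean distance proximal-to-distal (mm).

    Accepts a skeleton polyline, a fitted curve model, or an (n, 3) array;
    by definition this is the chord, not the arc length.
    """
    if hasattr(curve, "points"):
        pts = np.asarray(curve.points, dtype=float)
        p0, p1 = pts[0], pts[-1]
    elif hasattr(curve, "position"):
        p0, p1 = curve.position(0.0), curve.position(1.0)
    else:
        pts = np.asarray(curve, dtype=float)
        p0, p1 = pts[0], pts[-1]
    d = float(np.linalg.norm(p1 - p0))
    if d <= 1e-12:
        raise DegenerateCurveError("electrode endpoints coincide")
    return d


def rigid_fraction(chord_length: float, electrode_type: str) -> float:
    """Percentage of the lead length occupied by the stiff distal part."""
    if electrode_type not in RIGID_LENGTHS:
        raise InvalidArgumentError(f"unknown electrode type {electrode_type!r}")
    rigid = RIGID_LENGTHS[electrode_type]
    if not chord_length > rigid:
        raise InvalidArgumentError(
            f"chord length {chord_length} mm must exceed the rigid part {rigid} mm"
        )
    return 100.0 * rigid / chord_length


def extracerebral_fraction(cortex_entry: float, chord_length: float) -> float:
    """Percentage of lead length between the proximal point and the cortex."""
    if not (0.0 <= cortex_entry < chord_length):
        raise InvalidArgumentError(
            f"need 0 <= cortex_entry ({cortex_entry}) < chord_length ({chord_length})"
        )
    return 100.0 * cortex_entry / chord_length


def brain_shift_index(
    bubble: AirBubble, hemisphere_volume_mm3: float, ellipsoid: bool = False
) -> float:
    """Pneumocephalus-to-hemisphere volume ratio in units of 1e-4 %.

    The air volume is the rectangular height x width x thickness product (an
    overestimate by construction); ``ellipsoid=True`` applies the pi/6
    factor instead.  The ratio is scaled by 1e6 so the result is a percent
    times 1e4, i.e. reported in units of 1e-4 %.
    """
    if not hemisphere_volume_mm3 > 0:
        raise InvalidArgumentError("hemisphere volume must be positive")
    v_air = bubble.ellipsoid_volume() if ellipsoid else bubble.box_volume()
    return v_air / hemisphere_volume_mm3 * 1e6


def surgical_inaccuracy(planned_point, contact_point) -> float:
    """Euclidean planned-vs-achieved distance (mm), at 0.1 mm resolution."""
    a = np.asarray(planned_point, dtype=float)
    b = np.asarray(contact_point, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidArgumentError("points must be finite")
    d = float(np.linalg.norm(a - b))
    # round half-up to the planning-software grid
    return np.floor(d / DISTANCE_RESOLUTION_MM + 0.5) * DISTANCE_RESOLUTION_MM
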