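"""Multi-segment body geometry and anthropometric bookkeeping.

The body is an assembly of simple axisymmetric segments — a spherical head
and cylinders for neck, trunk sub-regions (back / chest / abdomen), and the
paired limbs — each carrying an ordered stack of tissue layers from the axis
to a 4 mm skin shell at the surface.  Segment dimensions are scaled so that
the assembled body reproduces the reference anthropometry: body surface area
1.7 m², volume 0.057 m³ and, at an average density of 1060 kg/m³, a mass of
about 60.4 kg (height 1.684 m, BMI ≈ 21.3).

Nine skin regions (back, chest, abdomen, arm, thigh, leg, hand, head, foot)
carry the standard weighting coefficients used to form the mean skin
temperature; paired limbs report a single (symmetric) regional temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import fsolve

from .tissues import tissue_properties

__all__ = [
    "SKIN_WEIGHTS",
    "BodySegment",
    "BodyModel",
    "build_default_body",
    "mean_skin_temperature",
    "BODY_DENSITY",
    "DEFAULT_SKIN_THICKNESS",
]

#: average whole-body density, kg/m³
BODY_DENSITY = 1060.0
#: skin shell thickness, m
DEFAULT_SKIN_THICKNESS = 0.004

#: mean-skin-temperature weighting coefficients over the nine regions;
#: they sum to exactly 1.
SKIN_WEIGHTS: dict[str, float] = {
    "back": 0.12,
    "chest": 0.12,
    "abdomen": 0.12,
    "arm": 0.14,
    "thigh": 0.19,
    "leg": 0.13,
    "hand": 0.05,
    "head": 0.07,
    "foot": 0.06,
}


@dataclass(frozen=True)
class BodySegment:
    """One axisymmetric body segment.

    Attributes
    ----------
    name : str
        Segment label; doubles as the skin-region name where weighted.
    shape : str
        ``"cylinder"`` or ``"sphere"``.
    outer_radius : float
        Outer (skin surface) radius, m.
    length : float
        Axial length, m (cylinders; 0 for the head sphere).
    skin_thickness : float
        Thickness of the outermost skin layer, m.
    layers : tuple[tuple[str, float], ...]
        Ordered ``(tissue_name, outer_radius)`` pairs from axis to surface;
        the last entry is always ``("skin", outer_radius)``.
    skin_weight : float
        Mean-skin-temperature coefficient (0 if the region is unweighted).
    count : int
        Number of identical copies (2 for paired limbs).
    """

    name: str
    shape: str
    outer_radius: float
    length: float = 0.0
    skin_thickness: float = DEFAULT_SKIN_THICKNESS
    layers: tuple[tuple[str, float], ...] = ()
    skin_weight: float = 0.0
    count: int = 1

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "sphere"):
            raise ValueError(f"segment {self.name!r}: unknown shape {self.shape!r}")
        if not self.skin_thickness < self.outer_radius:
            raise ValueError(
                f"segment {self.name!r}: skin thickness {self.skin_thickness} m "
                f"must be smaller than the outer radius {self.outer_radius} m"
            )
        if self.shape == "cylinder" and not self.length > 0:
            raise ValueError(f"segment {self.name!r}: cylinder needs length > 0")
        for tissue, r_out in self.layers:
            tissue_properties(tissue)  # raises on unknown tissue
            if not 0 < r_out <= self.outer_radius + 1e-12:
                raise ValueError(
                    f"segment {self.name!r}: layer {tissue!r} outer radius "
                    f"{r_out} m outside (0, {self.outer_radius}]"
                )

    @property
    def surface_area(self) -> float:
        """Exposed lateral surface area of all copies, m²."""
        if self.shape == "sphere":
            a = 4.0 * math.pi * self.outer_radius**2
        else:
            a = 2.0 * math.pi * self.outer_radius * self.length
        return a * self.count

    @property
    def volume(self) -> float:
        """Total volume of all copies, m³."""
        if self.shape == "sphere":
            v = 4.0 / 3.0 * math.pi * self.outer_radius**3
        else:
            v = math.pi * self.outer_radius**2 * self.length
        return v * self.count


@dataclass(frozen=True)
class BodyModel:
    """The assembled body: segment list plus aggregate anthropometry."""

    segments: tuple[BodySegment, ...]
    height: float = 1.684

    def __post_init__(self) -> None:
        total_w = sum(s.skin_weight for s in self.segments)
        if abs(total_w - 1.0) > 1e-9:
            raise ValueError(
                f"segment skin weights must sum to 1.0, got {total_w:.6f}"
            )

    @property
    def bsa(self) -> float:
        """Body surface area, m² (sum of exposed segment areas)."""
        return sum(s.surface_area for s in self.segments)

    @property
    def volume(self) -> float:
        """Body volume, m³."""
        return sum(s.volume for s in self.segments)

    @property
    def mass(self) -> float:
        """Body mass, kg, at the average density of 1060 kg/m³."""
        return self.volume * BODY_DENSITY

    def segment(self, name: str) -> BodySegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"no segment named {name!r}")

    @property
    def skin_regions(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments if s.skin_weight > 0)

    def to_dict(self) -> dict:
        """Serializable plain-dict description (YAML/JSON friendly)."""
        return {
            "height": float(self.height),
            "segments": [
                {
                    "name": s.name,
                    "shape": s.shape,
                    "outer_radius": float(s.outer_radius),
                    "length": float(s.length),
                    "skin_thickness": float(s.skin_thickness),
                    "layers": [[t, float(r)] for t, r in s.layers],
                    "skin_weight": float(s.skin_weight),
                    "count": int(s.count),
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BodyModel":
        segments = tuple(
            BodySegment(
                name=d["name"],
                shape=d["shape"],
                outer_radius=float(d["outer_radius"]),
                length=float(d.get("length", 0.0)),
                skin_thickness=float(d.get("skin_thickness", DEFAULT_SKIN_THICKNESS)),
                layers=tuple((t, float(r)) for t, r in d["layers"]),
                skin_weight=float(d.get("skin_weight", 0.0)),
                count=int(d.get("count", 1)),
            )
            for d in doc["segments"]
        )
        return cls(segments=segments, height=float(doc.get("height", 1.684)))


# Base (pre-scaling) segment dimensioning: name, shape, radius, length,
# count, skin weight, interior composition.  Trunk sub-regions carry an
# internal-organ core (60 % of the radius) under muscle; limbs and neck are
# muscle; the head sphere is head tissue.  A 4 mm skin shell tops every
# segment.  Radii and lengths are representative of an average adult and are
# subsequently scaled to the aggregate BSA/volume targets.
_BASE_SEGMENTS: tuple[tuple[str, str, float, float, int, float, str], ...] = (
    ("head", "sphere", 0.100, 0.0, 1, 0.07, "head"),
    ("neck", "cylinder", 0.055, 0.10, 1, 0.00, "muscle"),
    ("chest", "cylinder", 0.125, 0.20, 1, 0.12, "trunk"),
    ("back", "cylinder", 0.125, 0.20, 1, 0.12, "trunk"),
    ("abdomen", "cylinder", 0.125, 0.20, 1, 0.12, "trunk"),
    ("arm", "cylinder", 0.045, 0.60, 2, 0.14, "muscle"),
    ("hand", "cylinder", 0.035, 0.18, 2, 0.05, "muscle"),
    ("thigh", "cylinder", 0.070, 0.40, 2, 0.19, "muscle"),
    ("leg", "cylinder", 0.050, 0.40, 2, 0.13, "muscle"),
    ("foot", "cylinder", 0.040, 0.22, 2, 0.06, "muscle"),
)

#: fraction of the trunk radius occupied by the internal-organ core
DEFAULT_ORGAN_FRACTION = 0.60

#: reference anthropometric targets
TARGET_BSA = 1.7  # m²
TARGET_VOLUME = 0.057  # m³


def _layers(
    kind: str, outer_radius: float, skin_thickness: float, organ_fraction: float
) -> tuple[tuple[str, float], ...]:
    r_skin_inner = outer_radius - skin_thickness
    if kind == "trunk":
        return (
            ("internal_organs", organ_fraction * outer_radius),
            ("muscle", r_skin_inner),
            ("skin", outer_radius),
        )
    if kind == "head":
        return (("head", r_skin_inner), ("skin", outer_radius))
    return (("muscle", r_skin_inner), ("skin", outer_radius))


def build_default_body(
    *,
    skin_thickness: float = DEFAULT_SKIN_THICKNESS,
    organ_fraction: float = DEFAULT_ORGAN_FRACTION,
    bsa: float = TARGET_BSA,
    volume: float = TARGET_VOLUME,
    height: float = 1.684,
) -> BodyModel:
    """Build the reference average body.

    A uniform radial scale and a uniform length scale are solved for so
    that the assembled segment set reproduces the requested aggregate
    surface area and volume exactly (the base dimensions only fix the
    relative proportions).  The skin shell thickness stays at its absolute
    value (4 mm by default) regardless of scaling.

    Parameters
    ----------
    skin_thickness : float
        Skin layer thickness, m.  Must stay below the smallest scaled
        segment radius.
    organ_fraction : float
        Fraction of the trunk radius occupied by the internal-organ core.
    bsa, volume : float
        Aggregate targets, m² and m³.
    height : float
        Stature, m (bookkeeping only; does not affect the thermal model).

    Raises
    ------
    ValueError
        If an override produces non-physical geometry.
    """
    if not 0 < organ_fraction < 1:
        raise ValueError(f"organ_fraction must be in (0, 1), got {organ_fraction}")
    if bsa <= 0 or volume <= 0:
        raise ValueError("bsa and volume targets must be positive")

    base = _BASE_SEGMENTS

    def aggregates(scales: np.ndarray) -> tuple[float, float]:
        alpha, beta = scales
        area = vol = 0.0
        for _, shape, r, length, count, _, _ in base:
            rr = alpha * r
            if shape == "sphere":
                area += count * 4.0 * math.pi * rr**2
                vol += count * 4.0 / 3.0 * math.pi * rr**3
            else:
                ll = beta * length
                area += count * 2.0 * math.pi * rr * ll
                vol += count * math.pi * rr**2 * ll
        return area, vol

    def residual(scales: np.ndarray) -> np.ndarray:
        area, vol = aggregates(scales)
        return np.array([area - bsa, vol - volume])

    (alpha, beta), info, ok, msg = fsolve(residual, x0=[1.0, 1.0], full_output=True)
    if ok != 1 or alpha <= 0 or beta <= 0:
        raise ValueError(f"could not scale body to requested aggregates: {msg}")

    segments = []
    for name, shape, r, length, count, weight, kind in base:
        rr = alpha * r
        if not skin_thickness < rr:
            raise ValueError(
                f"segment {name!r}: skin thickness {skin_thickness} m is not "
                f"smaller than the scaled radius {rr:.4f} m"
            )
        segments.append(
            BodySegment(
                name=name,
                shape=shape,
                outer_radius=rr,
                length=beta * length if shape == "cylinder" else 0.0,
                skin_thickness=skin_thickness,
                layers=_layers(kind, rr, skin_thickness, organ_fraction),
                skin_weight=weight,
                count=count,
            )
        )
    return BodyModel(segments=tuple(segments), height=height)


def mean_skin_temperature(region_temps: dict[str, float]) -> float:
    """Weighted mean skin temperature over the nine standard regions.

    ``Ts = 0.12·back + 0.12·chest + 0.12·abdomen + 0.14·arm + 0.19·thigh
    + 0.13·leg + 0.05·hand + 0.07·head + 0.06·foot``

    Parameters
    ----------
    region_temps : dict
        Mapping region name → skin temperature (°C).  All nine regions
        must be present; there is no silent renormalization.

    Raises
    ------
    KeyError
        If any weighted region is missing.
    """
    missing = [r for r in SKIN_WEIGHTS if r not in region_temps]
    if missing:
        raise KeyError(f"missing skin region(s): {', '.join(sorted(missing))}")
    return sum(w * float(region_temps[r]) for r, w in SKIN_WEIGHTS.items())
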