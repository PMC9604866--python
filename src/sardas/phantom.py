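"""Hemispherical breast phantom: geometry, tissue dielectrics, coordinate frame.

Coordinate conventions used throughout the package
--------------------------------------------------
Right-handed frame in millimetres. The origin sits at the center of the
hemisphere base; the breast occupies the ``z >= 0`` half-space. Antennas
approach from outside the curved surface. The phantom is a hemisphere of
radius ``breast_radius`` whose outermost ``skin_thickness`` millimetres are
skin; the remainder is homogeneous "interior" (normal breast) tissue, with
zero or more spherical tumors embedded in it.

Tissue dielectrics are carried as ``(relative permittivity, conductivity,
mass density)`` triples. The skin and malignant-tissue values follow the
published phantom (skin εr=37, σ=1.1 S/m; tumor εr=50, σ=1.2 S/m); the
interior defaults to adipose-dominated literature values (εr=9, σ=0.4 S/m),
and mass density defaults to 1000 kg/m³ for every tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError

__all__ = [
    "TissueProperties",
    "Tumor",
    "BreastPhantom",
    "SKIN",
    "TUMOR",
    "INTERIOR",
    "TUMOR_MODELS",
    "LABEL_AIR",
    "LABEL_SKIN",
    "LABEL_INTERIOR",
    "make_default_phantom",
    "contains",
    "label_points",
    "tissue_for_label",
    "phantom_from_dict",
    "phantom_to_dict",
]

# Integer labels used by the vectorized classifier; tumor indices are >= 0.
LABEL_AIR = -1
LABEL_SKIN = -2
LABEL_INTERIOR = -3

_LABEL_NAMES = {LABEL_AIR: "air", LABEL_SKIN: "skin", LABEL_INTERIOR: "interior"}


@dataclass(frozen=True)
class TissueProperties:
    """Dielectric triple of a tissue.

    Parameters
    ----------
    relative_permittivity : float
        Relative permittivity εr (dimensionless), > 0.
    conductivity : float
        Conductivity σ in S/m, > 0.
    mass_density : float
        Mass density ρ in kg/m³, > 0. Defaults to 1000 (water-like); the SAR
        argmax is invariant to a common density scale.
    """

    relative_permittivity: float
    conductivity: float
    mass_density: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("relative_permittivity", "conductivity", "mass_density"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TissueProperties.{name} must be strictly positive")


#: Skin dielectrics of the reference phantom.
SKIN = TissueProperties(relative_permittivity=37.0, conductivity=1.1)
#: Malignant-tissue dielectrics of the reference phantom.
TUMOR = TissueProperties(relative_permittivity=50.0, conductivity=1.2)
#: Normal (adipose-dominated) interior tissue; literature defaults.
INTERIOR = TissueProperties(relative_permittivity=9.0, conductivity=0.4)

#: The four malignant-tissue dielectric models used in the material sweep.
TUMOR_MODELS: dict[str, TissueProperties] = {
    "tumor_1": TissueProperties(50.0, 1.2),
    "tumor_2": TissueProperties(62.77, 1.66),
    "tumor_3": TissueProperties(54.0, 0.7),
    "tumor_4": TissueProperties(55.1, 0.79),
}


@dataclass(frozen=True)
class Tumor:
    """A spherical tumor embedded in the breast interior."""

    center: tuple[float, float, float]
    radius: float
    tissue: TissueProperties = TUMOR

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise GeometryError("tumor radius must be strictly positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class BreastPhantom:
    """Hemisphere + skin shell + embedded spherical tumors."""

    breast_radius: float = 50.0
    skin_thickness: float = 2.0
    skin: TissueProperties = SKIN
    interior: TissueProperties = INTERIOR
    tumors: tuple[Tumor, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.breast_radius > self.skin_thickness > 0:
            raise GeometryError(
                "phantom requires breast_radius > skin_thickness > 0 "
                f"(got {self.breast_radius} mm, {self.skin_thickness} mm)"
            )
        object.__setattr__(self, "tumors", tuple(self.tumors))
        for k, t in enumerate(self.tumors):
            c = np.asarray(t.center, dtype=float)
            if c[2] < 0:
                raise GeometryError(
                    f"tumor {k}: center z={c[2]} mm outside the z >= 0 hemisphere half-space"
                )
            if np.linalg.norm(c) + t.radius > self.interior_radius:
                raise GeometryError(
                    f"tumor {k}: |center| + radius = {np.linalg.norm(c) + t.radius:.2f} mm "
                    f"exceeds the interior radius {self.interior_radius:.2f} mm"
                )

    @property
    def interior_radius(self) -> float:
        """Radius of the interior region (inner face of the skin shell), mm."""
        return self.breast_radius - self.skin_thickness

    def without_tumors(self) -> "BreastPhantom":
        """The matching tumor-free (baseline) phantom."""
        return replace(self, tumors=())


def make_default_phantom(
    tumor_center: tuple[float, float, float] = (20.0, -13.0, 14.0),
    tumor_radius: float = 5.0,
    tumor_tissue: TissueProperties = TUMOR,
    *,
    skin: TissueProperties = SKIN,
    interior: TissueProperties = INTERIOR,
) -> BreastPhantom:
    """Build the reference 50-mm phantom with a single spherical tumor.

    The default tumor sits off-center at (20, −13, 14) mm with a 5 mm radius —
    the limiting size for Stage 1 disease and the design case used throughout
    the evaluation scenarios. Placement violating the geometry invariants
    raises :class:`~sardas.errors.GeometryError`.
    """
    tumor = Tumor(center=tuple(tumor_center), radius=tumor_radius, tissue=tumor_tissue)
    return BreastPhantom(skin=skin, interior=interior, tumors=(tumor,))


def label_points(phantom: BreastPhantom, points: np.ndarray) -> np.ndarray:
    """Classify an ``(n, 3)`` array of points into integer region labels.

    Returns ``LABEL_AIR`` / ``LABEL_SKIN`` / ``LABEL_INTERIOR`` or the tumor
    index (>= 0). Tumors win over interior; later tumors in the list do not
    overwrite earlier ones (first match wins).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    labels = np.full(pts.shape[0], LABEL_AIR, dtype=int)
    inside = (pts[:, 2] >= 0) & (r <= phantom.breast_radius)
    labels[inside & (r > phantom.interior_radius)] = LABEL_SKIN
    core = inside & (r <= phantom.interior_radius)
    labels[core] = LABEL_INTERIOR
    for k, t in enumerate(phantom.tumors):
        d = np.linalg.norm(pts - np.asarray(t.center), axis=1)
        labels[core & (d <= t.radius) & (labels == LABEL_INTERIOR)] = k
    return labels


def contains(phantom: BreastPhantom, point) -> str | int:
    """Classify a single point: ``"air"``, ``"skin"``, ``"interior"`` or a tumor index."""
    label = int(label_points(phantom, np.asarray(point, dtype=float)[None, :])[0])
    return _LABEL_NAMES.get(label, label)


def tissue_for_label(phantom: BreastPhantom, label: int) -> TissueProperties | None:
    """Tissue properties for an integer label; ``None`` for air."""
    if label == LABEL_AIR:
        return None
    if label == LABEL_SKIN:
        return phantom.skin
    if label == LABEL_INTERIOR:
        return phantom.interior
    return phantom.tumors[label].tissue


def phantom_to_dict(phantom: BreastPhantom) -> dict:
    """Serialize a phantom to a plain dict (YAML/JSON friendly)."""

    def tissue(t: TissueProperties) -> dict:
        return {
            "permittivity": t.relative_permittivity,
            "conductivity": t.conductivity,
            "density": t.mass_density,
        }

    return {
        "radius": phantom.breast_radius,
        "skin_thickness": phantom.skin_thickness,
        "skin": tissue(phantom.skin),
        "interior": tissue(phantom.interior),
        "tumors": [
            {"center": list(t.center), "radius": t.radius, "tissue": tissue(t.tissue)}
            for t in phantom.tumors
        ],
    }


def phantom_from_dict(d: dict) -> BreastPhantom:
    """Inverse of :func:`phantom_to_dict`; missing tissue keys fall back to defaults."""

    def tissue(sub: dict | None, default: TissueProperties) -> TissueProperties:
        if sub is None:
            return default
        return TissueProperties(
            relative_permittivity=float(sub["permittivity"]),
            conductivity=float(sub["conductivity"]),
            mass_density=float(sub.get("density", 1000.0)),
        )

    tumors = tuple(
        Tumor(
            center=tuple(t["center"]),
            radius=float(t["radius"]),
            tissue=tissue(t.get("tissue"), TUMOR),
        )
        for t in d.get("tumors", [])
    )
    return BreastPhantom(
        breast_radius=float(d.get("radius", 50.0)),
        skin_thickness=float(d.get("skin_thickness", 2.0)),
        skin=tissue(d.get("skin"), SKIN),
        interior=tissue(d.get("interior"), INTERIOR),
        tumors=tumors,
    )
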