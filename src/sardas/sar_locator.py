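"""SAR computation, tumor localization from its maximum, and aperture planning.

The specific absorption rate at a voxel is SAR = σ·E²/ρ (W/kg) with σ, ρ
taken from the tissue occupying that voxel and E the internal electric
field magnitude. Malignant tissue both conducts more and — in the synthetic
field stand-in — concentrates the field, so the spatial SAR maximum falls
inside the tumor; its coordinates are the tumor estimate that guides the
reduced-aperture antenna placement.

:func:`synthesize_field` is a deterministic stand-in for a full-wave solved
field: an aperture-offset spherical decay E = A·d0/(d0 + d) from the source,
multiplied by a contrast-enhancement factor inside tumors. The offset d0
(default 50 mm, of the order of the antenna aperture) keeps the incident
field finite near the source, as a physical finite-aperture antenna does.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .errors import GeometryError, InputError
from .forward_sim import ScanGeometry
from .phantom import LABEL_AIR, BreastPhantom, contains, label_points, tissue_for_label

__all__ = [
    "FieldGrid",
    "SarMap",
    "FieldParams",
    "TumorEstimate",
    "default_grid_axes",
    "synthesize_field",
    "sar_from_field",
    "locate_tumor",
    "plan_aperture",
    "plan_full_ring",
]


@dataclass(frozen=True)
class FieldGrid:
    """Electric-field magnitude |E| (V/m) on a regular 3-D lattice (mm axes)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    magnitude: np.ndarray  # (nx, ny, nz), >= 0

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            ax = np.asarray(getattr(self, name), dtype=float)
            if ax.ndim != 1 or ax.size == 0:
                raise InputError(f"axis {name} must be a non-empty 1-D array")
            if ax.size > 1:
                d = np.diff(ax)
                if d[0] <= 0 or not np.allclose(d, d[0], rtol=1e-9):
                    raise InputError(f"axis {name} must be regular and ascending")
            object.__setattr__(self, name, ax)
        mag = np.asarray(self.magnitude, dtype=float)
        if mag.shape != (self.x.size, self.y.size, self.z.size):
            raise InputError("magnitude shape must match (nx, ny, nz)")
        if np.any(mag < 0):
            raise InputError("field magnitudes must be non-negative")
        object.__setattr__(self, "magnitude", mag)

    def points(self) -> np.ndarray:
        """All voxel coordinates, shape (nx*ny*nz, 3), C-order."""
        gx, gy, gz = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass(frozen=True)
class SarMap:
    """SAR (W/kg) on the same lattice as a FieldGrid; optional tissue labels."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sar: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sar) < 0):
            raise InputError("SAR must be non-negative everywhere")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("x", "y", "z"):
                f.create_dataset(f"axis_{name}_mm", data=getattr(self, name))
            f.create_dataset("sar_w_per_kg", data=self.sar)
            if self.labels is not None:
                f.create_dataset("tissue_labels", data=self.labels)


@dataclass(frozen=True)
class FieldParams:
    """Stand-in incident-field parameters (amplitude V/m, lengths mm)."""

    amplitude: float = 1.0
    decay_offset: float = 50.0
    tumor_enhancement: float = 4.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.decay_offset <= 0 or self.tumor_enhancement <= 0:
            raise InputError("FieldParams values must be strictly positive")


@dataclass(frozen=True)
class TumorEstimate:
    """Location and value of the SAR maximum, with a detection-confidence flag.

    ``position`` is the raw argmax voxel. ``centroid`` is the SAR-weighted
    centroid of the voxels within the exclusion ball that exceed half the
    peak — the argmax sits on the tumor face nearest the illumination, so
    the hotspot centroid is the better estimate of the tumor *center* and is
    what downstream aperture planning uses.
    """

    position: tuple[float, float, float]
    sar_max: float
    peak_ratio: float
    confident: bool
    centroid: tuple[float, float, float] | None = None

    @property
    def center_estimate(self) -> tuple[float, float, float]:
        return self.centroid if self.centroid is not None else self.position

    def to_dict(self) -> dict:
        return {
            "x_mm": self.position[0],
            "y_mm": self.position[1],
            "z_mm": self.position[2],
            "sar_w_per_kg": self.sar_max,
            "peak_ratio": self.peak_ratio,
            "confident": self.confident,
        }


def default_grid_axes(phantom: BreastPhantom, spacing: float = 1.0):
    """1-mm lattice covering the phantom bounding box (z >= 0 half-space)."""
    r = phantom.breast_radius
    xy = np.arange(-r, r + spacing / 2, spacing)
    z = np.arange(0.0, r + spacing / 2, spacing)
    return xy, xy.copy(), z


def synthesize_field(
    phantom: BreastPhantom,
    source_position,
    params: FieldParams = FieldParams(),
    axes=None,
) -> FieldGrid:
    """Deterministic stand-in for a solved internal field.

    |E| = A·d0/(d0 + d) from the source, multiplied by ``tumor_enhancement``
    inside tumor spheres and zeroed in air (no internal field outside tissue).
    Fields from several sources may be superposed by summing magnitudes.
    """
    src = np.asarray(source_position, dtype=float)
    if contains(phantom, src) != "air":
        raise GeometryError("field source must be outside the phantom (in air)")
    if axes is None:
        axes = default_grid_axes(phantom)
    x, y, z = axes
    gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d = np.linalg.norm(pts - src, axis=1)
    mag = params.amplitude * params.decay_offset / (params.decay_offset + d)
    labels = label_points(phantom, pts)
    mag[labels >= 0] *= params.tumor_enhancement
    mag[labels == LABEL_AIR] = 0.0
    return FieldGrid(x=x, y=y, z=z, magnitude=mag.reshape(gx.shape))


def sar_from_field(field: FieldGrid, phantom: BreastPhantom) -> SarMap:
    """Point-wise SAR = σ·E²/ρ with tissue properties looked up per voxel.

    Air voxels receive SAR 0. This is the point-wise quantity, not an
    IEEE 1 g/10 g mass-averaged SAR.
    """
    if field.magnitude.size == 0:
        raise InputError("empty field grid")
    pts = field.points()
    labels = label_points(phantom, pts)
    sigma = np.zeros(labels.shape)
    rho = np.ones(labels.shape)
    for lab in np.unique(labels):
        tissue = tissue_for_label(phantom, int(lab))
        if tissue is not None:
            sigma[labels == lab] = tissue.conductivity
            rho[labels == lab] = tissue.mass_density
    sar = sigma * field.magnitude.ravel() ** 2 / rho
    return SarMap(
        x=field.x,
        y=field.y,
        z=field.z,
        sar=sar.reshape(field.magnitude.shape),
        labels=labels.reshape(field.magnitude.shape),
    )


def locate_tumor(
    sar_map: SarMap,
    exclusion_radius: float = 10.0,
    ratio_threshold: float = 1.5,
) -> TumorEstimate | None:
    """Coordinates and value of the global SAR maximum; ``None`` on an all-zero map.

    Ties are broken by lexicographic voxel order (C-order argmax over the
    (x, y, z)-indexed array), which is deterministic. The confidence ratio
    compares the peak with the largest SAR outside an ``exclusion_radius``
    ball around it: a localized absorber (tumor) scores high, a smooth
    field (no tumor) scores near 1.
    """
    sar = sar_map.sar
    if not np.any(sar > 0):
        return None
    flat = int(np.argmax(sar))
    ix, iy, iz = np.unravel_index(flat, sar.shape)
    pos = (float(sar_map.x[ix]), float(sar_map.y[iy]), float(sar_map.z[iz]))
    peak = float(sar[ix, iy, iz])

    gx, gy, gz = np.meshgrid(sar_map.x, sar_map.y, sar_map.z, indexing="ij")
    dist2 = (gx - pos[0]) ** 2 + (gy - pos[1]) ** 2 + (gz - pos[2]) ** 2
    outside = sar[dist2 > exclusion_radius**2]
    background = float(outside.max()) if outside.size else 0.0
    ratio = np.inf if background == 0.0 else peak / background

    hot = (dist2 <= exclusion_radius**2) & (sar >= 0.5 * peak)
    w = sar[hot]
    centroid = (
        float(np.average(gx[hot], weights=w)),
        float(np.average(gy[hot], weights=w)),
        float(np.average(gz[hot], weights=w)),
    )
    return TumorEstimate(
        position=pos,
        sar_max=peak,
        peak_ratio=float(ratio),
        confident=bool(ratio >= ratio_threshold),
        centroid=centroid,
    )


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def plan_aperture(
    tumor_estimate,
    phantom: BreastPhantom,
    standoff: float = 10.0,
    rows: int = 3,
    cols: int = 3,
    angular_step: float = 10.0,
    mode: str = "grid",
) -> ScanGeometry:
    """Reduced-aperture antenna placement around the radial ray through the estimate.

    Antennas sit on the sphere of radius ``breast_radius + standoff`` at
    angular offsets ``(i − (rows−1)/2)·step × (j − (cols−1)/2)·step`` about two
    orthogonal axes perpendicular to the radial direction through the tumor
    estimate; boresights point at the estimate. ``mode="arc"`` instead lays
    ``rows·cols`` positions along a single arc at ``angular_step`` spacing (the
    alternative wide-scan reading of the published geometry). Within-arc and
    within-column neighbour separations are exactly ``angular_step``; cross-row
    separations on the 2-D grid differ by the usual O(step²) spherical-excess
    factor.
    """
    est = np.asarray(tumor_estimate, dtype=float)
    norm = np.linalg.norm(est)
    if norm == 0:
        raise InputError("tumor estimate at the origin has no radial direction")
    if contains(phantom, est) == "air":
        raise GeometryError("tumor estimate must lie inside the phantom")
    u = est / norm
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e_row = np.cross(u, ref)
    e_row /= np.linalg.norm(e_row)
    e_col = np.cross(u, e_row)  # orthonormal, perpendicular to u
    radius = phantom.breast_radius + standoff
    step = np.deg2rad(angular_step)

    def offsets(n: int) -> list[float]:
        # Odd counts: centered on the radial ray (the published 3x3 layout).
        # Even counts: one antenna anchored on the ray, the rest stepped to one
        # side — a symmetric even grid is mirror-symmetric about the tumor
        # direction, and row-average clutter removal would then cancel the
        # tumor response identically.
        return [(i - (n - 1) // 2) * step for i in range(n)]

    dirs = []
    if mode == "arc":
        n = rows * cols
        for ang in offsets(n):
            dirs.append(_rotation_matrix(e_row, ang) @ u)
        grid_rows, grid_cols = 1, n
    elif mode == "grid":
        for a in offsets(rows):
            Ra = _rotation_matrix(e_row, a)
            for b in offsets(cols):
                dirs.append(Ra @ (_rotation_matrix(e_col, b) @ u))
        grid_rows, grid_cols = rows, cols
    else:
        raise InputError(f"unknown aperture mode {mode!r}")

    positions = radius * np.array(dirs)
    boresights = est[None, :] - positions
    geom = ScanGeometry(
        positions=positions,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        standoff=standoff,
        boresights=boresights,
    )
    for p in positions:
        if contains(phantom, p) != "air":
            raise GeometryError("planned antenna position falls inside the phantom")
    return geom


def plan_full_ring(
    phantom: BreastPhantom,
    n_positions: int = 36,
    standoff: float = 10.0,
    plane_height: float = 0.0,
) -> ScanGeometry:
    """Conventional full-circle scan: a uniform ring of antennas around the breast.

    ``n_positions`` antennas (default 36 → 10° azimuth spacing) on a circle of
    radius ``breast_radius + standoff`` about the z-axis in the horizontal
    plane ``z = plane_height``, boresights toward the central axis. Logical
    grid shape 1 × n.
    """
    if n_positions < 3:
        raise InputError("a ring needs at least 3 positions")
    radius = phantom.breast_radius + standoff
    az = 2 * np.pi * np.arange(n_positions) / n_positions
    positions = np.column_stack(
        [radius * np.cos(az), radius * np.sin(az), np.full(n_positions, float(plane_height))]
    )
    boresights = np.column_stack([-np.cos(az), -np.sin(az), np.zeros(n_positions)])
    return ScanGeometry(
        positions=positions,
        grid_rows=1,
        grid_cols=n_positions,
        standoff=standoff,
        boresights=boresights,
    )
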