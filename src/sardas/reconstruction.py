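"""Calibration, clutter removal, and delay-and-sum (DAS) image formation.

The imaging chain is the package's core:

1. **Calibration** — subtract the tumor-free baseline record from the
   cancerous record per antenna, T_XY(t) = TB_XY(t) − B_XY(t), isolating an
   approximate tumor waveform.
2. **Clutter removal** — subtract the per-row average from each calibrated
   channel, P_XY(t) = T_XY(t) − A_X(t), A_X = (1/n) Σ_Y T_XY, suppressing
   residual clutter common to a scan row.
3. **Synthetic focusing** — for each pixel (xi, yj) of a physical region,
   sample every processed channel at its round-trip delay and sum an even
   power of the samples: I(xi, yj) = Σ_XY P_XY(t_XY(xi, yj))^q.

Round-trip geometry per antenna is D = 2·√((X−xi)² + (Y−yj)² + h²) with h
the antenna's height above the imaging plane, and t = D·√εr/c for a single
effective medium permittivity εr. A ``strict_literal_velocity`` flag
substitutes the non-physical t = D·εr/c reading of the source expression.
The effective permittivity may be given numerically or derived from the
phantom as a path-averaged value (:func:`effective_permittivity`), the
"estimated average of the environment permittivity" a beamformer needs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import InputError
from .forward_sim import C_M_PER_S, ScanRecord, one_way_optical_path_mm
from .phantom import BreastPhantom

__all__ = [
    "ImagingConfig",
    "IntensityImage",
    "calibrate",
    "remove_clutter",
    "focusing_distance",
    "round_trip_time",
    "effective_permittivity",
    "form_image",
    "reconstruct",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImagingConfig:
    """Pixel grid, physical region, and delay-model parameters.

    The default 350×350 pixels map onto the 100 mm × 100 mm footprint
    [−50, 50]² mm (pixel count and physical area are deliberately decoupled).
    ``medium_permittivity`` defaults to the skin value 37; pipelines usually
    override it with a path-averaged effective value. ``intensity_exponent``
    must be even (default 2; larger even powers sharpen the peak).
    ``plane_z`` is the height (mm) of the imaging plane: each antenna's h is
    its z-coordinate minus ``plane_z``. ``time_reference`` (s) is the instant
    of the excitation-pulse center on the record's time axis; computed
    round-trip delays are offset by it when sampling the channels (a record
    whose time axis already starts at the excitation center uses 0).
    """

    n_x: int = 350
    n_y: int = 350
    region: tuple[float, float, float, float] = (-50.0, 50.0, -50.0, 50.0)
    medium_permittivity: float = 37.0
    intensity_exponent: int = 2
    interpolation: str = "linear"
    plane_z: float = 0.0
    time_reference: float = 0.0
    strict_literal_velocity: bool = False

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2:
            raise InputError("pixel grid must be at least 2x2")
        x0, x1, y0, y1 = self.region
        if not (x1 > x0 and y1 > y0):
            raise InputError("imaging region must be non-degenerate")
        if self.intensity_exponent < 2 or self.intensity_exponent % 2 != 0:
            raise InputError("intensity_exponent must be an even integer >= 2")
        if self.medium_permittivity < 1:
            raise InputError("medium_permittivity must be >= 1")
        if self.interpolation not in ("linear", "nearest"):
            raise InputError("interpolation must be 'linear' or 'nearest'")

    def pixel_axes(self) -> tuple[np.ndarray, np.ndarray]:
        x0, x1, y0, y1 = self.region
        return np.linspace(x0, x1, self.n_x), np.linspace(y0, y1, self.n_y)

    @property
    def pixel_pitch(self) -> float:
        """Mean pixel spacing in mm."""
        x, y = self.pixel_axes()
        return float((x[1] - x[0] + y[1] - y[0]) / 2)


@dataclass
class IntensityImage:
    """Raw DAS intensity I(xi, yj) >= 0 with physical pixel coordinates.

    ``values[i, j]`` corresponds to x=``x[i]``, y=``y[j]``.
    """

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise InputError("intensity values must be non-negative")
        if self.values.shape != (np.size(self.x), np.size(self.y)):
            raise InputError("image shape must match axis lengths")

    def normalized(self) -> np.ndarray:
        """Values scaled to [0, 1] for rendering; raw values are retained."""
        vmax = self.values.max()
        return self.values / vmax if vmax > 0 else self.values.copy()

    def argmax_xy(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return float(self.x[i]), float(self.y[j])

    def to_text(self, path) -> None:
        header = (
            f"x_mm {self.x[0]} {self.x[-1]} {self.x.size}\n"
            f"y_mm {self.y[0]} {self.y[-1]} {self.y.size}"
        )
        np.savetxt(path, self.values, header=header)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("x_mm", data=self.x)
            f.create_dataset("y_mm", data=self.y)
            f.create_dataset("intensity", data=self.values)
            f.attrs["provenance"] = json.dumps(self.provenance, default=str)

    def to_png(self, path, cmap: str = "inferno") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4.2))
        im = ax.imshow(
            self.normalized().T,
            origin="lower",
            extent=(self.x[0], self.x[-1], self.y[0], self.y[-1]),
            cmap=cmap,
            aspect="equal",
        )
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        fig.colorbar(im, ax=ax, label="normalized intensity")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _check_compatible(a: ScanRecord, b: ScanRecord) -> None:
    if not np.allclose(a.geometry.positions, b.geometry.positions, rtol=1e-9, atol=1e-9):
        raise InputError("records have different antenna geometries")
    if a.geometry.grid_rows != b.geometry.grid_rows or a.geometry.grid_cols != b.geometry.grid_cols:
        raise InputError("records have different grid shapes")
    if a.time.shape != b.time.shape or not np.allclose(a.time, b.time, rtol=1e-9, atol=0.0):
        raise InputError("records have different time axes")


def calibrate(cancerous: ScanRecord, tumor_free: ScanRecord) -> ScanRecord:
    """Per-position baseline subtraction, T_XY(t) = TB_XY(t) − B_XY(t)."""
    _check_compatible(cancerous, tumor_free)
    return ScanRecord(
        geometry=cancerous.geometry,
        time=cancerous.time,
        signals=cancerous.signals - tumor_free.signals,
        label="calibrated",
        provenance={
            "cancerous": cancerous.provenance,
            "tumor_free": tumor_free.provenance,
        },
    )


def remove_clutter(calibrated: ScanRecord) -> ScanRecord:
    """Row-average subtraction: P_XY(t) = T_XY(t) − (1/n) Σ_Y T_XY(t).

    A row with a single antenna is annihilated (P ≡ 0); this degenerate case
    is emitted with a warning rather than an error. A 1×n ring collapses to a
    single row, so its "row average" is the mean over all positions — the
    documented ring-mode variant.
    """
    g = calibrated.geometry
    if g.grid_cols == 1:
        warnings.warn(
            "clutter removal on 1-antenna rows annihilates the signal (P == 0)",
            stacklevel=2,
        )
    cube = calibrated.signals.reshape(g.grid_rows, g.grid_cols, -1)
    row_avg = cube.mean(axis=1, keepdims=True)
    processed = (cube - row_avg).reshape(calibrated.signals.shape)
    return ScanRecord(
        geometry=g,
        time=calibrated.time,
        signals=processed,
        label="processed",
        provenance=dict(calibrated.provenance, clutter_removal="row_average"),
    )


def focusing_distance(antenna_xy, pixel_xy, h: float) -> np.ndarray | float:
    """Round-trip focusing distance D = 2·√((X−xi)² + (Y−yj)² + h²), mm.

    Accepts scalars or broadcastable arrays for the pixel coordinates.
    """
    ax, ay = antenna_xy
    px = np.asarray(pixel_xy[0], dtype=float)
    py = np.asarray(pixel_xy[1], dtype=float)
    return 2.0 * np.sqrt((ax - px) ** 2 + (ay - py) ** 2 + h * h)


def round_trip_time(distance_mm, medium_permittivity: float, strict_literal: bool = False):
    """Convert a focusing distance (mm) into a round-trip delay (s).

    Physical reading: t = D·√εr/c (wave speed c/√εr). ``strict_literal=True``
    reproduces the literal t = D·εr/c form of the source expression.
    """
    d = np.asarray(distance_mm, dtype=float)
    if np.any(d < 0):
        raise InputError("distance must be non-negative")
    if medium_permittivity < 1:
        raise InputError("medium permittivity must be >= 1")
    factor = medium_permittivity if strict_literal else np.sqrt(medium_permittivity)
    return d * 1e-3 * factor / C_M_PER_S


def effective_permittivity(phantom: BreastPhantom, positions, focus) -> float:
    """Path-averaged effective permittivity for the delay model.

    For each antenna, the ratio of optical path (Σ length·√εr along the
    straight ray to the focus) to geometric distance is an average slowness;
    the square of the mean ratio over antennas is the single-medium εr that
    best reproduces the piecewise delays near the focus.
    """
    focus = np.asarray(focus, dtype=float)
    ratios = []
    for p in np.atleast_2d(np.asarray(positions, dtype=float)):
        geo = float(np.linalg.norm(focus - p))
        if geo == 0:
            continue
        ratios.append(one_way_optical_path_mm(phantom, p, focus) / geo)
    if not ratios:
        raise InputError("no usable antenna positions for permittivity estimate")
    return float(np.mean(ratios)) ** 2


def form_image(processed: ScanRecord, config: ImagingConfig) -> IntensityImage:
    """Synthetic focusing: I(xi,yj) = Σ_XY P_XY(t_XY(xi,yj))^q on the pixel grid.

    Channels are sampled at fractional delays by linear interpolation
    (``config.interpolation="nearest"`` snaps to the closest sample instead);
    delays outside the recorded window contribute 0 and are counted in a log
    message.
    """
    if processed.signals.size == 0:
        raise InputError("empty scan record")
    if processed.label != "processed":
        warnings.warn(
            f"form_image expects a 'processed' record, got {processed.label!r}",
            stacklevel=2,
        )
    xs, ys = config.pixel_axes()
    px, py = np.meshgrid(xs, ys, indexing="ij")
    image = np.zeros(px.shape)
    t_axis = processed.time
    out_of_window = 0
    for i in range(processed.geometry.n_positions):
        pos = processed.geometry.positions[i]
        h = pos[2] - config.plane_z
        d = focusing_distance((pos[0], pos[1]), (px, py), h)
        t = round_trip_time(d, config.medium_permittivity, config.strict_literal_velocity)
        t = t + config.time_reference
        out_of_window += int(np.count_nonzero((t < t_axis[0]) | (t > t_axis[-1])))
        if config.interpolation == "nearest":
            idx = np.rint((t - t_axis[0]) / (t_axis[1] - t_axis[0])).astype(int)
            valid = (idx >= 0) & (idx < t_axis.size)
            samp = np.zeros(t.shape)
            samp[valid] = processed.signals[i][idx[valid]]
        else:
            samp = np.interp(t, t_axis, processed.signals[i], left=0.0, right=0.0)
        image += samp**config.intensity_exponent
    if out_of_window:
        logger.info("form_image: %d pixel delays fell outside the recorded window", out_of_window)
    return IntensityImage(
        values=image,
        x=xs,
        y=ys,
        provenance={
            "record": processed.provenance,
            "config_hash": hashlib.sha256(
                json.dumps(config.__dict__, sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
            "out_of_window_samples": out_of_window,
        },
    )


def reconstruct(
    cancerous: ScanRecord, tumor_free: ScanRecord, config: ImagingConfig
) -> IntensityImage:
    """Full chain: form_image ∘ remove_clutter ∘ calibrate."""
    return form_image(remove_clutter(calibrate(cancerous, tumor_free)), config)
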