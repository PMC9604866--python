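"""Synthetic monostatic backscatter simulator (point-scatterer forward model).

Generates the tumor-free (B) and cancerous (TB) scan records that a full-wave
solver would produce for the phantom, using a simple physics stand-in: each
recorded waveform is the sum of

* a position-independent antenna-reverberation artifact (damped sinusoid),
* a skin echo — the impedance-contrast reflection at the air/skin interface
  along the antenna boresight, with 1/d² spreading,
* one echo per tumor — delayed by the piecewise round-trip time of flight
  (air at c, tissue at c/√εr along the straight ray), scaled by the
  interior/tumor impedance contrast, tissue attenuation e^(−α·path), 1/d²
  spreading, a cosⁿ antenna directivity toward boresight, and a Rayleigh
  (radius/5 mm)³ volume factor,
* seeded additive white Gaussian noise.

Propagation is straight-ray (no refraction at the skin), matching the
assumption of the delay-and-sum imaging model downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from .errors import GeometryError, InputError
from .phantom import LABEL_AIR, LABEL_SKIN, BreastPhantom, contains, label_points
from .pulse import PulseParams, evaluate_pulse

__all__ = [
    "C_M_PER_S",
    "ScanGeometry",
    "ScanRecord",
    "ForwardModelParams",
    "simulate_scan",
    "round_trip_delay",
    "ray_tissue_lengths",
    "one_way_optical_path_mm",
]

#: Speed of light in vacuum, m/s.
C_M_PER_S = 2.9979e8

#: Reference tumor radius (mm) for the Rayleigh volume scaling of echo amplitude.
_REFERENCE_TUMOR_RADIUS_MM = 5.0


@dataclass(frozen=True)
class ScanGeometry:
    """Antenna phase centers arranged in a logical rows×cols grid.

    ``positions`` is ``(n, 3)`` mm; ``boresights`` unit vectors (pointing
    directions). Position ``i`` sits at grid row ``i // grid_cols``, column
    ``i % grid_cols`` (row-major).
    """

    positions: np.ndarray
    grid_rows: int
    grid_cols: int
    standoff: float = 10.0
    boresights: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.shape[1] != 3:
            raise InputError("positions must be (n, 3)")
        if self.grid_rows * self.grid_cols != pos.shape[0]:
            raise InputError(
                f"grid {self.grid_rows}x{self.grid_cols} does not match "
                f"{pos.shape[0]} positions"
            )
        if self.boresights is None:
            # Default: point each antenna at the origin.
            b = -pos / np.linalg.norm(pos, axis=1, keepdims=True)
        else:
            b = np.atleast_2d(np.asarray(self.boresights, dtype=float))
            b = b / np.linalg.norm(b, axis=1, keepdims=True)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "boresights", b)

    @property
    def n_positions(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class ForwardModelParams:
    """Knobs of the stand-in physics. All amplitudes are dimensionless.

    Attenuation coefficients are Np/mm (one-way); defaults 0.1 for skin and
    0.02 for interior tissue are plausible microwave values. The spreading
    exponent 2 gives round-trip 1/d² amplitude decay; directivity is cosⁿ
    about boresight with n=4 for a moderately directive antenna.
    """

    attenuation_skin: float = 0.1
    attenuation_interior: float = 0.02
    spreading_exponent: float = 2.0
    directivity_exponent: float = 4.0
    artifact_amplitude: float = 0.02
    artifact_decay: float = 0.5e-9
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "attenuation_skin",
            "attenuation_interior",
            "spreading_exponent",
            "directivity_exponent",
            "artifact_amplitude",
            "artifact_decay",
            "noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"ForwardModelParams.{name} must be non-negative")


@dataclass
class ScanRecord:
    """One monostatic waveform per antenna position, shared time axis."""

    geometry: ScanGeometry
    time: np.ndarray
    signals: np.ndarray  # (n_positions, n_samples)
    label: str = "tumor_free"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape != (self.geometry.n_positions, self.time.size):
            raise InputError("signals must be (n_positions, n_samples) matching the time axis")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("geometry")
            g.create_dataset("positions_mm", data=self.geometry.positions)
            g.create_dataset("boresights", data=self.geometry.boresights)
            g.attrs["grid_rows"] = self.geometry.grid_rows
            g.attrs["grid_cols"] = self.geometry.grid_cols
            g.attrs["standoff_mm"] = self.geometry.standoff
            f.create_dataset("time_axis", data=self.time)
            f.create_dataset("signals", data=self.signals)
            meta = f.create_group("meta")
            meta.attrs["label"] = self.label
            meta.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def from_hdf5(cls, path) -> "ScanRecord":
        with h5py.File(path, "r") as f:
            g = f["geometry"]
            geom = ScanGeometry(
                positions=g["positions_mm"][:],
                grid_rows=int(g.attrs["grid_rows"]),
                grid_cols=int(g.attrs["grid_cols"]),
                standoff=float(g.attrs["standoff_mm"]),
                boresights=g["boresights"][:],
            )
            return cls(
                geometry=geom,
                time=f["time_axis"][:],
                signals=f["signals"][:],
                label=str(f["meta"].attrs["label"]),
                provenance=json.loads(f["meta"].attrs["provenance"]),
            )

    @classmethod
    def from_text_files(cls, geometry: ScanGeometry, paths, label: str = "imported") -> "ScanRecord":
        """Assemble a record from per-position two-column (time, amplitude) text files."""
        cols = [np.loadtxt(p) for p in paths]
        if len(cols) != geometry.n_positions:
            raise InputError("number of files must equal number of antenna positions")
        time = cols[0][:, 0]
        for c in cols[1:]:
            if not np.allclose(c[:, 0], time, rtol=1e-9, atol=0.0):
                raise InputError("all per-position files must share one time axis")
        return cls(geometry=geometry, time=time, signals=np.stack([c[:, 1] for c in cols]), label=label)


def _sphere_crossings(origin: np.ndarray, direction: np.ndarray, radius: float) -> list[float]:
    """Parameters t in (0, 1) where origin + t*direction crosses |p| = radius."""
    a = float(direction @ direction)
    b = 2.0 * float(origin @ direction)
    c = float(origin @ origin) - radius * radius
    disc = b * b - 4 * a * c
    if disc <= 0 or a == 0:
        return []
    sq = np.sqrt(disc)
    return [t for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)) if 0.0 < t < 1.0]


def ray_tissue_lengths(phantom: BreastPhantom, origin, target) -> dict[int, float]:
    """One-way path lengths (mm) per region label along the straight ray origin→target.

    Regions are resolved at segment midpoints with the phantom classifier, so
    tumor crossings are attributed to the tumor's own label.
    """
    o = np.asarray(origin, dtype=float)
    tgt = np.asarray(target, dtype=float)
    d = tgt - o
    total = float(np.linalg.norm(d))
    if total == 0.0:
        return {}
    ts = {0.0, 1.0}
    for radius in (phantom.breast_radius, phantom.interior_radius):
        ts.update(_sphere_crossings(o, d, radius))
    for tum in phantom.tumors:
        ts.update(_sphere_crossings(o - np.asarray(tum.center), d, tum.radius))
    knots = sorted(ts)
    mids = np.array([o + 0.5 * (a + b) * d for a, b in zip(knots[:-1], knots[1:])])
    labels = label_points(phantom, mids)
    out: dict[int, float] = {}
    for (a, b), lab in zip(zip(knots[:-1], knots[1:]), labels):
        out[int(lab)] = out.get(int(lab), 0.0) + (b - a) * total
    return out


def one_way_optical_path_mm(phantom: BreastPhantom, origin, target) -> float:
    """Σ length·√εr over the ray segments (air counts √εr = 1), in mm.

    Point-scatterer convention: tumor inclusions are treated as part of the
    interior medium for propagation (the scatterer is a point at the tumor
    center; only air, skin, and interior govern the time of flight).
    """
    lengths = ray_tissue_lengths(phantom, origin, target)
    total = 0.0
    for lab, length in lengths.items():
        if lab == LABEL_AIR:
            total += length
        elif lab == LABEL_SKIN:
            total += length * np.sqrt(phantom.skin.relative_permittivity)
        else:
            total += length * np.sqrt(phantom.interior.relative_permittivity)
    return total


def round_trip_delay(position, target, phantom: BreastPhantom) -> float:
    """Monostatic round-trip time of flight (s) along the straight ray.

    2 × (air/c + skin·√εr_skin/c + interior·√εr_interior/c + ...), straight-ray,
    no refraction.
    """
    return 2.0 * one_way_optical_path_mm(phantom, position, target) * 1e-3 / C_M_PER_S


def _one_way_attenuation_np(
    phantom: BreastPhantom, params: ForwardModelParams, lengths: dict[int, float]
) -> float:
    """One-way attenuation in nepers along a ray, from per-tissue coefficients."""
    alpha = 0.0
    for lab, length in lengths.items():
        if lab == LABEL_SKIN:
            alpha += params.attenuation_skin * length
        elif lab != LABEL_AIR:
            # interior and tumor tissue share the interior coefficient
            alpha += params.attenuation_interior * length
    return alpha


def _reflection_coefficient(eps_outer: float, eps_inner: float) -> float:
    """Normal-incidence amplitude reflection at a dielectric interface."""
    a, b = np.sqrt(eps_outer), np.sqrt(eps_inner)
    return (a - b) / (a + b)


def _boresight_skin_distance(phantom: BreastPhantom, position: np.ndarray, boresight: np.ndarray) -> float | None:
    """Distance (mm) from an antenna to the skin surface along its boresight."""
    a = float(boresight @ boresight)
    b = 2.0 * float(position @ boresight)
    c = float(position @ position) - phantom.breast_radius**2
    disc = b * b - 4 * a * c
    if disc <= 0:
        return None
    s = (-b - np.sqrt(disc)) / (2 * a)
    return s if s > 0 else None


def _params_hash(*objs) -> str:
    payload = json.dumps([asdict(o) if hasattr(o, "__dataclass_fields__") else o for o in objs],
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate_scan(
    phantom: BreastPhantom,
    geometry: ScanGeometry,
    pulse: PulseParams,
    params: ForwardModelParams,
    with_tumors: bool = True,
    time_axis: np.ndarray | None = None,
) -> ScanRecord:
    """Produce a monostatic ScanRecord (B when ``with_tumors=False``, else TB).

    Echo replicas are evaluated from the closed-form pulse at the exact
    delayed times, so delays are not quantized to the sample grid. The noise
    realization depends only on ``params.seed`` and the record shape, never on
    ``with_tumors``, so a tumor-free phantom yields bit-identical records for
    either flag at equal seed.
    """
    if time_axis is None:
        # 2048 samples over 5 ns: ~2.4 ps sampling, ample for a 172 ps monocycle.
        time_axis = np.arange(2048) * (5e-9 / 2048)
    t = np.asarray(time_axis, dtype=float)

    for p in geometry.positions:
        if contains(phantom, p) != "air":
            raise GeometryError(f"antenna position {tuple(p)} is not outside the phantom")

    n = geometry.n_positions
    signals = np.zeros((n, t.size))

    # Position-independent antenna reverberation: damped sinusoid from t=0.
    if params.artifact_amplitude > 0:
        artifact = (
            params.artifact_amplitude
            * np.exp(-t / params.artifact_decay)
            * np.sin(2 * np.pi * pulse.center_frequency * t)
        )
        signals += artifact[None, :]

    gamma_skin = _reflection_coefficient(1.0, phantom.skin.relative_permittivity)
    tumors = phantom.tumors if with_tumors else ()

    for i in range(n):
        pos = geometry.positions[i]
        bore = geometry.boresights[i]

        d_skin = _boresight_skin_distance(phantom, pos, bore)
        if d_skin is not None:
            tau_skin = 2.0 * d_skin * 1e-3 / C_M_PER_S
            amp = gamma_skin / max(d_skin, 1.0) ** params.spreading_exponent
            signals[i] += amp * evaluate_pulse(pulse, t - tau_skin)

        for tum in tumors:
            center = np.asarray(tum.center)
            d_geo = float(np.linalg.norm(center - pos))
            lengths = ray_tissue_lengths(phantom, pos, center)
            tau = round_trip_delay(pos, center, phantom)
            gamma = _reflection_coefficient(
                phantom.interior.relative_permittivity, tum.tissue.relative_permittivity
            )
            atten = np.exp(-2.0 * _one_way_attenuation_np(phantom, params, lengths))
            to_target = (center - pos) / d_geo
            cosang = float(np.clip(to_target @ bore, 0.0, 1.0))
            directivity = cosang**params.directivity_exponent
            size_factor = (tum.radius / _REFERENCE_TUMOR_RADIUS_MM) ** 3
            amp = gamma * atten * directivity * size_factor
            amp /= max(d_geo, 1.0) ** params.spreading_exponent
            signals[i] += amp * evaluate_pulse(pulse, t - tau)

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        signals = signals + rng.normal(0.0, params.noise_sigma, size=signals.shape)

    return ScanRecord(
        geometry=geometry,
        time=t,
        signals=signals,
        label="cancerous" if (with_tumors and phantom.tumors) else "tumor_free",
        provenance={
            "config_hash": _params_hash(params, pulse),
            "seed": params.seed,
            "with_tumors": bool(with_tumors),
        },
    )
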