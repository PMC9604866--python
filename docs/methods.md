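# Methods

This note documents the models behind `sardas`, the defaults and why they
were chosen, and what the synthetic data can and cannot establish.

## Phantom and coordinate frame

Right-handed frame, millimetres, origin at the center of the hemisphere
base, breast in the z ≥ 0 half-space, antennas approaching from outside the
curved surface. The phantom is a hemisphere of radius 50 mm whose outer
2 mm are skin; the remainder is homogeneous interior tissue with spherical
tumors embedded. Tissue dielectrics:

| tissue   | εr    | σ (S/m) | ρ (kg/m³) | source |
|----------|-------|---------|-----------|--------|
| skin     | 37    | 1.1     | 1000      | published phantom |
| tumor    | 50    | 1.2     | 1000      | published phantom |
| interior | 9     | 0.4     | 1000      | adipose-dominated literature values |

Mass density is not part of the published phantom; 1000 kg/m³ is used for
every tissue (the SAR argmax is invariant to a common density scale), and
each tissue's density is overridable. The published description places the
tumor at coordinates that lie outside a 50-mm hemisphere; the package's
default tumor instead sits at (20, −13, 14) mm with a 5 mm radius — an
off-center placement consistent with the reported SAR-maximum coordinates
— and every placement is configurable. `contains()` classifies any point
as air / skin / interior / tumor-index; boundary points belong to the
innermost region whose closed ball contains them, and tumors win over
interior.

## Excitation pulse

Gaussian monocycle `S(t) = −A·(2π/τ)·(t−Tc)·exp(−½·(2π(t−Tc)/τ)²)` with
τ = 1/f0 and f0 = 5.8 GHz (ISM band). The pulse is odd about Tc, has
exactly two extrema at Tc ± τ/(2π), and its spectrum peaks at f0. The
leading constant of the source expression is typeset ambiguously ("e·" may
be Euler's number or an amplitude symbol); since DAS images are invariant
to a global pulse scale, the default normalizes the peak to 1
(`normalize=True`, A = √e) and a flag restores the literal Euler-number
amplitude. Default sampling for simulated records: 2048 samples over
0–5 ns (≈2.4 ps spacing, ~11 samples per Gaussian σ of the monocycle);
the pulse-only default grid is 512 samples over the same window. Tc
defaults to 0.5 ns so the full pulse fits the record.

## Synthetic forward model (the stand-in for a full-wave solver)

The generator produces the study conditions that full-wave simulations
provided in the original study. Per antenna, the monostatic waveform is

```
artifact(t) + Γ_skin · g(d_skin) · S(t − τ_skin)
            + Σ_tumors Γ_tum · g · D(θ) · (r/5mm)³ · S(t − τ_tum)
            + noise
```

* **Delays** are piecewise straight-ray: air at c, tissue at c/√εr, with
  segment lengths from exact sphere intersections; no refraction at the
  skin (the DAS imaging model makes the same straight-ray assumption).
  Tumor volumes count as interior for propagation: the scatterer is a
  point at the tumor center, so only air/skin/interior slownesses enter
  the time of flight.
* **Amplitudes**: normal-incidence impedance contrasts
  Γ = (√ε₁−√ε₂)/(√ε₁+√ε₂) at the air/skin interface (skin echo) and the
  interior/tumor interface (tumor echo); spreading 1/d^2 (round-trip,
  exponent configurable); attenuation e^(−α·path) with α_skin = 0.1 Np/mm
  and α_interior = 0.02 Np/mm one-way (plausible microwave values — the
  source gives none); cosⁿ directivity about the antenna boresight with
  n = 4 (moderately directive antenna); and a (radius/5 mm)³ Rayleigh
  volume factor, appropriate because the tumor is small compared to the
  in-tissue wavelength at 5.8 GHz (~17 mm in εr = 9), so echo strength
  scales with scatterer volume.
* **Artifact**: a position-independent damped sinusoid (amplitude 0.02,
  decay 0.5 ns) models antenna reverberation; being identical in B and TB
  it cancels exactly in calibration, and being position-independent it is
  also removed by row-average clutter subtraction alone.
* **Noise**: seeded additive white Gaussian noise, default σ = 0. The
  noise realization depends only on the seed and record shape, so equal
  seeds give bit-identical records. Pipelines derive distinct seeds for
  the B and TB acquisitions (two separate measurements), so calibration
  does not artificially cancel noise.
* Echo replicas are evaluated from the closed-form pulse at exact delayed
  times — no interpolation error enters the simulation itself.

What the generator does **not** emulate: multiple scattering, skin-interface
refraction and creeping waves, antenna dispersion and S-parameters,
frequency-dependent tissue properties, and heterogeneous fibroglandular
structure. Tests passing on this generator therefore demonstrate the
correctness and internal consistency of the processing chain, not clinical
performance on real breasts.

## SAR localization

`synthesize_field` stands in for a solved internal field: magnitude
A·d0/(d0+d) from the source with aperture offset d0 = 50 mm (a finite
aperture antenna's field does not diverge near the antenna), multiplied by
a tumor enhancement factor (default 4) inside tumor spheres, zero in air.
`sar_from_field` applies σE²/ρ voxel-wise (point-wise SAR; IEEE 1 g/10 g
mass-averaging is out of scope). The default lattice is 1 mm.

`locate_tumor` returns the global SAR argmax (C-order lexicographic
tie-break, deterministic) with a confidence ratio: peak divided by the
largest SAR outside a 10-mm exclusion ball. A localized absorber scores
high (the default scenario scores ≈ 6.7); a healthy phantom's smooth field
scores near 1; the confidence threshold is 1.5. An all-zero map returns a
"no detection" result rather than a position. Because the argmax sits on
the tumor face nearest the illumination, the estimate also carries the
SAR-weighted centroid of the above-half-max hotspot voxels; downstream
planning uses this centroid as the center estimate.

Absolute SAR magnitudes reported by full-wave solvers depend on the drive
power normalization, which the source does not state; only the *location*
of the maximum is meaningful here, and no attempt is made to reproduce
absolute W/kg values.

## Aperture planning

SAR-guided placement puts antennas on the sphere of radius
breast_radius + standoff (60 mm by default) at angular offsets of
`angular_step` (10°) about two orthogonal axes perpendicular to the radial
direction through the tumor estimate; boresights point at the estimate.
Odd row/column counts are centered on the radial ray (the published 3×3
layout has its central antenna on it). Even counts anchor one antenna on
the ray and step the rest to one side: a symmetric even grid would be
mirror-symmetric about the tumor direction, making the tumor echoes in a
row identical so that row-average clutter removal cancels them exactly.
On a sphere, a rectangular angular grid cannot have *all* neighbor
separations equal (spherical excess): within-row separations are exactly
the step; across rows they contract by a cos(elevation) factor (≈ 9.85°
for 10° offsets). An alternative `arc` layout places all positions along a
single great-circle arc at exact step spacing (the "wide scan" reading of
the published geometry, which describes both a 3×3 grid and a 90° scan).
The conventional baseline is a uniform ring (default 36 positions → 10°
azimuth spacing) about the z-axis at a configurable plane height, logical
grid shape 1×n.

## Imaging model

The 2-D image is formed in the horizontal plane through the estimated
tumor height; each antenna's `h` is its z-coordinate minus the plane
height, which makes the in-plane focusing distance at the true pixel equal
to the true 3-D antenna–tumor distance. Pixel count (350×350) and physical
region (100×100 mm) are deliberately decoupled.

The delay model uses a single effective permittivity. The physical reading
t = D·√εr/c is the default; a `strict_literal_velocity` flag reproduces
the literal t = D·εr/c form of the source expression for comparison. The
effective εr can be given numerically (the source's parenthetical suggests
the skin value 37, which `ImagingConfig` keeps as its direct-construction
default) or — as the pipelines default to — estimated as the source
prescribes ("the estimated average of the environment permittivity"): for
each antenna the ratio of optical path (Σ length·√εr along the ray to the
focus) to geometric distance is an average slowness, and the squared mean
ratio is the effective εr. With a 10-mm air standoff, 2-mm skin and εr = 9
interior this comes to ≈ 6.6–7.2 depending on geometry; using the skin
value 37 for the whole path including the air standoff would place every
echo earlier than the earliest pixel delay and no focusing is possible, so
the path-averaged estimate is the operative default.

Delays are referenced to the excitation center: `time_reference` (set to
Tc by the pipelines) is added to each computed delay before sampling.
Channels are sampled at fractional delays by linear interpolation
(`nearest` optional); delays outside the recorded window contribute zero
and are counted in a log message rather than raising. The intensity
exponent q must be even (squaring makes negative-polarity echoes add
constructively); the default is the literal q = 2, and larger even values
sharpen the peak — the source raised the power without stating the value,
so it is configurable rather than guessed.

Degenerate inputs: clutter removal on rows with a single antenna
annihilates the signal and emits a warning; a 1×n ring collapses the row
average to the mean over all positions, which is the documented ring-mode
variant. Calibration requires bit-compatible geometries and time axes
(relative tolerance 1e-9).

## Evaluation

"Detection" is operationalized as: image argmax within one tumor radius
plus one pixel pitch of the true center's in-plane projection AND a
positive signal-to-clutter ratio (SCR = 10·log10 of the peak inside the
tumor disk over the peak outside the disk dilated by one radius; an
identically-zero exterior returns +inf as a documented sentinel). FWHM is
the mean half-max width along the two axis lines through the peak. The
scenario suite runs the tumor-size sweep (1/3/5 mm, noiseless), the
four-tissue dielectric sweep (noiseless), and the antenna-count/placement
comparison (4 and 9 antennas, SAR-guided vs uniform ring; noiseless plus
20 noisy replicates per cell). The replicate noise σ = 2e-6 signal units
was fixed from the measured calibrated-channel scale of the reference
9-antenna scenario (~1.1e-4 peak, i.e. ~35 dB peak SNR) — a functioning,
moderately noisy measurement; all replicate seeds derive from the global
seed by stable hashing, so tables reproduce bit-for-bit.

Problem sizes used throughout (350×350 pixels, 1-mm SAR lattice, 2048-point
records, 20 replicates) keep a full scenario suite in the tens of seconds
on a single CPU.

## Known limitations

* Straight-ray, single-effective-medium imaging and a point-scatterer
  forward model: results quantify chain consistency, not clinical accuracy.
* Absolute SAR values and solver/hardware-dependent quantities (drive
  power, CPU-time comparisons) are out of scope.
* Single-tumor scenarios only; multiple-tumor separation and 3-D
  volumetric reconstruction are not implemented.
* The SAR stage assumes the stand-in field's monotone decay; real solved
  fields contain standing-wave structure that could displace the argmax.
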