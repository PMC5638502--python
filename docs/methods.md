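# Methods

This note documents the physical model, the numerical choices and the
limits of what the desk-scale simulation can and cannot show.

## Measurement model

The antenna reading is the complex input impedance
`Z_L = Z0 (1 + S11)/(1 - S11)` at a port with source impedance `Z0`
(default 50 Ω — the conventional value; the monitoring metric is a
*difference* of readings, so the choice only scales the numbers).
Monitoring compares a baseline reading at `t1` (the instant of the
conventional image) with later readings:
`ΔZ = |Z_L(t2) - Z_L(t1)|`, which weights amplitude and phase changes
equally.

A change of tissue inside the probed volume perturbs `Z_L`. We evaluate
the perturbation to first order (Born approximation): the field inside
the perturbed region is replaced by the unperturbed incident field
`E⁰`, giving

    ΔZ_L = -(1/I²) Σ_v (δσ - iωδε) (E⁰·E⁰) Δv

with an **unconjugated** dot product, absolute permittivity contrast
`δε` (F/m), and no magnetic term because all tissues have `δμ = 0`.
The port current `I` is not observable in this setup and is fixed at
1 A; `ΔZ` scales as `1/I²`, a constant prefactor that cancels in every
trend comparison. First-order perturbation makes two exact structural
predictions that the tests assert: additivity over disjoint lesions
and linearity in the contrast. What it gives up is multiple
scattering, so no claim is made about absolute ohm values — trends
across frequency, volume, depth and angle are the reproduction
surface.

Phasor convention: `e^{+jωt}`, complex relative permittivity
`ε* = ε' - jσ/(ωε₀)`, propagation `e^{-jkd}` with `Im(k) < 0` in lossy
media. The Born kernel keeps the `(δσ - iωδε)` sign; only the sign of
`Im(ΔZ)` depends on this choice and every asserted quantity uses
`|ΔZ|` or orderings.

## Tissue dielectrics

Seven materials (blood, white matter, gray matter, CSF, skull/cortical
bone, air, antenna substrate) are described by 4-term Cole-Cole
dispersions with a static conductivity term, using the Gabriel-family
literature parameterization that public tissue-property databases
expose. The table ships as versioned JSON fixture data
(`src/hemoradar/data/tissue_dispersion.json`) and is validated for
10 MHz – 3 GHz; outside that band the package refuses to evaluate.
"Effective conductivity" folds the dielectric loss of the relaxation
terms with the ionic term, and `ε_r` is the real part — matching how
(ε_r, σ) pairs are tabulated. Spot anchor: blood at 1 GHz evaluates to
ε_r = 61.06, σ = 1.583 S/m. The dispersion behavior (ε_r non-increasing,
σ non-decreasing with frequency) is asserted numerically for every
material on a 50-point log grid.

## Phantom

The canonical head is a concentric layered sphere: outer radius 9 cm,
skull 7 mm, CSF 3 mm, gray matter 4 mm, white-matter core, air outside.
These are round anatomical values for an adult head chosen once; a
loader accepts externally segmented label grids for users with real
data. Voxel membership is a center-point test (no partial volumes),
which keeps every geometric oracle exact and mirrors element-wise
property assignment. Lesions are ellipsoids parameterized by volume,
axis ratios and a proper rotation; semi-axes solve
`(4/3)π a b c = V`. The projected cross section (PCS) — the lesion's
shadow toward the antenna — has the closed form
`π sqrt(det(M) uᵀM⁻¹u)` with `M = R diag(a²,b²,c²) Rᵀ`, verified
against a 10⁶-sample Monte-Carlo shadow oracle to 0.5%.

Voxelization accuracy at the defaults: a 10 ml sphere at 1 mm spacing
is recovered to well within 2% by voxel counting, and the error falls
monotonically under refinement (4 → 0.5 mm). Sweeps default to 2 mm
spacing, which keeps a full-head grid at ~780k voxels and a complete
three-frequency volume sweep under a second on one CPU; the Born
refinement checks use 1 mm grids with a 0.5 mm oracle.

## Incident-field surrogate

The full-wave antenna solution is out of scope; the Born integral only
needs `E⁰` at lesion voxels. Three surrogates are provided, all
propagating with the complex wavenumber of a single background medium
(default: volume-weighted gray/white "average brain" of the layered
head — single-medium propagation keeps the integral well-defined;
layered corrections are not attempted):

* `plane_wave` — uniform transverse field; reference/testing.
* `lossy_point_source` — spherical wave `A e^{-jkd}/d` with
  dipole-pattern transverse polarization.
* `short_dipole` (default) — the full near-field radial profile
  `e^{-jkd} (1/d - j/(kd²) - 1/(k²d³))`.

The near-field terms matter physically: at 100 MHz (λ = 3 m) the
7.5 cm antenna is electrically small and a 6 cm deep lesion sits in
its reactive near zone, where the field falls as ~1/d³; at 1 GHz the
same distance is radiative. A pure 1/d source makes low and high
frequencies differ only through tissue attenuation, which *inverts*
the observed frequency ordering (attenuation grows faster with
frequency than the contrast term `|δσ - iωδε|`); the near-field dipole
restores it, with |ΔZ| at 1 GHz ≈ 2.5 orders of magnitude above
100 MHz at 6 cm depth. This is the package's design choice for the
default in-head source.

Calibration fixes `|E⁰| = 79.05 V/m` at a probe point 3 mm in front of
the antenna face, per frequency, so readings are comparable across
frequencies; calibration is idempotent and independent of the initial
amplitude. Antenna tilt is modeled by rotating the source pose about
the probe point.

## Mie backscatter theory

The volume–signal non-monotonicity is explained by the sphere
backscatter RCS. The exact Lorenz-Mie series is implemented with
Riccati-Bessel functions: `σ_b = (π/k²) |Σ (-1)ⁿ(2n+1)(aₙ - bₙ)|²`,
perfect conductors as the limiting boundary condition, dielectric
spheres through the logarithmic derivative of `ψₙ(mx)` computed by
downward recurrence (stable for lossy, complex `m`). Truncation uses
the Wiscombe rule `x + 4x^{1/3} + 2`, floored at `x + 10`; results are
stable to < 1e-6 under 10 extra terms. Checks: the Rayleigh closed
form `9πr²(kr)⁴` is matched to 1% for `kr ≤ 0.05` (the classical
fourth-power law is implemented and verified against the series;
sources occasionally misprint the exponent as 2), the optical mean
over `ka ∈ [20, 50]` is `πr²` within 10%, and the resonance region
shows the classical overshoot (> 3) and ≥ 3 local extrema on
`kr ∈ (0.8, 10)`. Region thresholds (Rayleigh < 0.5, Mie 0.5–10,
optical > 10) are declared constants from standard radar practice —
the canonical region diagram is schematic, not numeric. A lossy *host*
medium has no exact Mie theory; the package then uses `Re(k)` and
flags the result approximate. The Mie module is explanatory and
validating; it is not coupled into the head forward model.

## Noise studies

**Property noise** emulates uncertainty in literature tissue values:
each perturbed voxel's σ and ε are scaled by independent factors
`1 + N(0, p/100)` per repeat ("white Gaussian noise" at p = 1, 3, 5%).
Because the Born map is linear in the contrast, zero-mean multiplicative
noise leaves the mean ΔZ unbiased; with 200 repeats the mean |ΔZ| sits
within 3 standard errors of the noiseless value, and at 5% noise the
monotone-segment pattern of the volume curve (sphere, 0–4.25 ml, 7 cm
deep, 1 GHz) is preserved in ≥ 95% of repeats. The volume study draws
one noise field per repeat over the union of lesion voxels and shares
it across volumes, so each repeat is a coherent noisy growth curve.

**Receiver noise** uses `SNR_dB = 20 log10(V_signal/V_noise)`. The
baseline load is the matched port; complex white Gaussian noise at the
stated SNR below each reading pair's working reflected-wave amplitude
is added to both reflected signals before conversion back to
impedance. The histogram of `|ΔZ|_noisy - |ΔZ|_clean` is Gaussian-like
with a peak at the origin (mean within 3 SEM of 0 at 40 dB, 500
repeats), and averaging N repeats shrinks the std of the mean by √N
(verified for N = 128 within 15% over 50 meta-replicates). Scaling the
noise to each reading's own signal level models a receiver whose noise
floor tracks its gain staging; an absolute noise floor would add a
volume-independent error pedestal instead.

## Numerical and design choices

* Lesion placement is specified relative to the antenna (offset + depth
  along boresight), reconstructing the clinical presets' coordinates;
  absolute placement inside the head follows from the antenna standoff
  (0.5 cm from the skull by default).
* Lesions that cannot fit inside the gray/white region are computed
  anyway and *flagged* in the result table, never dropped.
* All RNG flows through explicit `numpy.random.default_rng(seed)`
  instances; identical config + seed reproduces tables bit-identically.
* CSV is the canonical result format (complex ΔZ as two real columns,
  documented fixed column order, `%.17g` + round-trip float parsing);
  every CLI run writes a JSON manifest with a sha256 of the
  canonicalized config.
* Spiral-slot geometry: `x = 1.5 s cos s`, `y = 1.5 s sin s` (mm),
  `s ∈ [0, 14π]`, second arm point-reflected; outer radius 66 mm,
  inside the 75 mm disk.

## What the synthetic setup does and does not show

The layered-sphere phantom, single-medium propagation and first-order
Born model reproduce the *mechanisms* — frequency/depth/volume trends,
Mie-region non-monotonicity, noise robustness — not the absolute
impedance magnitudes of a full-wave finite-element head model, which
depend on antenna feed details, wave reflections at tissue interfaces
and multiple scattering. Passing tests therefore certify internal
consistency and the physics of the trends, not quantitative agreement
with any particular full-wave solver or with measurements on real
heads. PCS-normalized curves are computed for inspection, but their
collapse across orientations is a full-wave scattering effect that a
first-order model is not expected to reproduce, and no test asserts
it.
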