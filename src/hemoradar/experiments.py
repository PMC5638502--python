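"""Numerical experiments: volume/frequency/distance/angle sweeps and
noise-robustness studies for radar monitoring of blood accumulation.

Geometry convention (meters, right-handed, head center at the origin):
the antenna sits on the -z axis at ``standoff`` below the skull surface
and looks up along +z; the lesion center of gravity lies ``depth`` from
the antenna center along the boresight, optionally offset in x/y.  The
incident-field surrogate propagates in a single volume-weighted
average-brain background (gray/white mixture of the layered head).

All stochastic operations consume an explicit seed; there is no hidden
global RNG state, and a fixed config + seed reproduces results
bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dielectrics, fields, forward, phantom as ph

DEFAULT_FREQUENCIES = (100e6, 500e6, 1e9)


@dataclass(frozen=True)
class SweepConfig:
    """Grid of monitoring conditions for :func:`run_sweep`."""

    frequencies: tuple = DEFAULT_FREQUENCIES          # Hz
    volumes_ml: tuple = tuple(np.linspace(0.0, 50.0, 11))
    lesion_ratios: tuple = (2.0, 2.0, 1.0)            # (rx, ry, rz)
    depths_m: tuple = (0.06,)                         # antenna center -> lesion CG
    tilt_angles_deg: tuple = (0.0,)
    baseline_volume_ml: float = 0.0
    lesion_offset_xy: tuple = (0.0, 0.0)              # m, lateral lesion offset
    seed: int = 0
    repeats: int = 1
    spacing: float = 0.002                            # m, voxel size
    standoff: float = 0.005                           # m, antenna face to skull
    source_kind: str = "short_dipole"
    layers: ph.HeadLayers = field(default_factory=ph.HeadLayers)

    def __post_init__(self):
        v = np.asarray(self.volumes_ml, dtype=float)
        if np.any(v < 0) or np.any(np.diff(v) < 0):
            raise ValueError("volumes must be non-negative and ascending")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic perturbation description for the robustness studies."""

    kind: str                  # "property_noise" or "snr_noise"
    magnitude: float           # percent (property) or dB (snr)
    repeats: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("property_noise", "snr_noise"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "property_noise" and not (0 <= self.magnitude < 100):
            raise ValueError("property noise percent must be in [0, 100)")
        if self.kind == "snr_noise" and self.magnitude <= 0:
            raise ValueError("SNR must be positive dB")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


# ---------------------------------------------------------------------------
# scene construction helpers

def antenna_position(config: SweepConfig) -> np.ndarray:
    """Antenna center: ``standoff`` below the skull on the -z axis."""
    return np.array([0.0, 0.0, -(config.layers.outer_radius + config.standoff)])


def brain_background(config: SweepConfig, frequency: float):
    """Average-brain propagation medium (volume-weighted gray/white)."""
    return dielectrics.mixture_properties(
        config.layers.brain_volume_weights(), frequency)


def make_source(config: SweepConfig, frequency: float,
                tilt_deg: float = 0.0) -> fields.SourceModel:
    """Calibrated source for one frequency; tilt rotates the pose about
    the probe point (x-axis), modeling antenna/head misalignment."""
    src = fields.SourceModel(kind=config.source_kind,
                             position=tuple(antenna_position(config)),
                             axis=(0.0, 0.0, 1.0),
                             polarization=(1.0, 0.0, 0.0),
                             background_props=brain_background(config, frequency))
    if tilt_deg:
        R = ph.rotation_about_axis((1.0, 0.0, 0.0), tilt_deg)
        probe = src.probe_point
        pos = probe + R @ (np.asarray(src.position) - probe)
        src = replace(src, position=tuple(pos),
                      axis=tuple(R @ np.asarray(src.axis)),
                      polarization=tuple(R @ np.asarray(src.polarization)))
    return fields.calibrate_source(src, frequency)


def make_lesion(config: SweepConfig, volume_ml: float,
                depth: float) -> ph.EllipsoidLesion:
    center = antenna_position(config) + np.array(
        [config.lesion_offset_xy[0], config.lesion_offset_xy[1], depth])
    axes = ph.ellipsoid_semi_axes(volume_ml, config.lesion_ratios)
    return ph.EllipsoidLesion(center=tuple(center), semi_axes=axes)


def lesion_escapes_brain(config: SweepConfig, lesion: ph.EllipsoidLesion) -> bool:
    """True when the lesion cannot be contained in the gray/white region."""
    if lesion.is_empty:
        return False
    dist = float(np.linalg.norm(np.asarray(lesion.center)
                                - np.asarray(config.layers.center)))
    return dist + max(lesion.semi_axes) > config.layers.csf_inner


# ---------------------------------------------------------------------------
# sweeps

SWEEP_COLUMNS = ["frequency_hz", "volume_ml", "depth_m", "angle_deg", "repeat",
                 "dz_re_ohm", "dz_im_ohm", "dz_abs_ohm", "pcs_m2",
                 "orientation", "flagged"]


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Tidy table of complex dZ over the configured condition grid.

    One baseline phantom (at ``baseline_volume_ml``) per depth; one row
    per (frequency, volume, depth, angle, repeat).  Lesions that cannot
    fit inside the brain are computed anyway but flagged, never
    silently dropped.
    """
    head = ph.make_layered_head(config.layers, config.spacing,
                                padding=config.spacing)
    orientation = ":".join(f"{r:g}" for r in config.lesion_ratios)
    rows = []
    for depth in config.depths_m:
        base_lesion = make_lesion(config, config.baseline_volume_ml, depth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            baseline = ph.insert_lesion(head, base_lesion)
            currents = {}
            for v in config.volumes_ml:
                currents[v] = (ph.insert_lesion(head, make_lesion(config, v, depth)),
                               make_lesion(config, v, depth))
        for angle in config.tilt_angles_deg:
            for f in config.frequencies:
                src = make_source(config, f, angle)
                for v in config.volumes_ml:
                    current, lesion = currents[v]
                    dz = forward.born_delta_impedance(baseline, current, src, f)
                    pcs = (0.0 if lesion.is_empty
                           else ph.projected_cross_section(lesion, src.axis))
                    flagged = lesion_escapes_brain(config, lesion)
                    for rep in range(config.repeats):
                        rows.append((f, v, depth, angle, rep, dz.real, dz.imag,
                                     abs(dz), pcs, orientation, flagged))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def pcs_normalized_curves(result: pd.DataFrame) -> pd.DataFrame:
    """|Re dZ| normalized by the projected cross section, per orientation.

    Zero-PCS rows (empty lesions) are excluded with a warning.  The
    normalized curves are provided for inspection and plotting; no
    collapse across orientations is asserted.
    """
    zero = result["pcs_m2"] <= 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-PCS rows from "
                      "normalization")
    keep = result.loc[~zero].copy()
    keep["re_dz_over_pcs"] = keep["dz_re_ohm"].abs() / keep["pcs_m2"]
    cols = ["frequency_hz", "volume_ml", "depth_m", "angle_deg",
            "orientation", "re_dz_over_pcs"]
    return keep[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# property-noise study (per-voxel Gaussian errors on sigma and eps)

def _changed_voxel_data(baseline: ph.VoxelPhantom, current: ph.VoxelPhantom,
                        frequency: float):
    changed = baseline.labels != current.labels
    centers = current.voxel_centers(changed)
    old = baseline.labels[changed]
    new = current.labels[changed]
    props = {}
    for lab in np.unique(np.concatenate([old, new])):
        tissue = current.label_map[int(lab)]
        props[int(lab)] = dielectrics.tissue_properties(tissue, frequency)
    return centers, old, new, props


def property_noise_experiment(baseline: ph.VoxelPhantom,
                              current: ph.VoxelPhantom,
                              source: fields.SourceModel,
                              frequency: float,
                              noise: NoiseSpec) -> dict:
    """Distribution of |dZ| under per-voxel property errors.

    Each changed voxel's perturbed-tissue sigma and eps are scaled by
    independent factors (1 + N(0, percent/100)) in every repeat; the
    Born integral is then re-evaluated.  Returns the noiseless
    reference and the per-repeat samples with summary statistics.
    """
    if noise.kind != "property_noise":
        raise ValueError("property_noise_experiment needs a property_noise spec")
    centers, old, new, props = _changed_voxel_data(baseline, current, frequency)
    w = 2.0 * np.pi * frequency
    dv = current.spacing ** 3
    E, _ = fields.incident_field(source, centers, frequency)
    e_dot_e = np.einsum("ij,ij->i", E, E)
    sig_new = np.array([props[int(l)].sigma for l in new])
    eps_new = np.array([props[int(l)].eps_rel for l in new])
    sig_old = np.array([props[int(l)].sigma for l in old])
    eps_old = np.array([props[int(l)].eps_rel for l in old])

    def dz_with(sig_factor, eps_factor):
        dsig = sig_new * sig_factor - sig_old
        deps = dielectrics.EPS0 * (eps_new * eps_factor - eps_old)
        kappa = dsig - 1j * w * deps
        return -np.sum(kappa * e_dot_e * dv, axis=-1)

    clean = complex(dz_with(1.0, 1.0))
    rng = np.random.default_rng(noise.seed)
    s = noise.magnitude / 100.0
    fs = 1.0 + s * rng.standard_normal((noise.repeats, len(centers)))
    fe = 1.0 + s * rng.standard_normal((noise.repeats, len(centers)))
    samples = dz_with(fs, fe)
    abs_samples = np.abs(samples)
    return {
        "noiseless_dz": clean,
        "noiseless_abs": abs(clean),
        "samples": samples,
        "mean_abs": float(abs_samples.mean()),
        "std_abs": float(abs_samples.std(ddof=1)) if noise.repeats > 1 else 0.0,
        "sem_abs": (float(abs_samples.std(ddof=1) / np.sqrt(noise.repeats))
                    if noise.repeats > 1 else 0.0),
    }


def property_noise_volume_study(config: SweepConfig,
                                noise: NoiseSpec,
                                frequency: float = 1e9,
                                depth: float = 0.07) -> dict:
    """Volume-curve robustness to property noise (growth-monitoring analog).

    A spherical lesion grows through ``config.volumes_ml``; one noise
    field per repeat is drawn over the union of lesion voxels and
    shared across volumes, so each repeat yields a coherent noisy
    volume-|dZ| curve.  Reports the fraction of repeats whose curve
    preserves the noiseless monotone-segment pattern.
    """
    head = ph.make_layered_head(config.layers, config.spacing,
                                padding=config.spacing)
    src = make_source(config, frequency)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        baseline = ph.insert_lesion(
            head, make_lesion(config, config.baseline_volume_ml, depth))
        phantoms = [ph.insert_lesion(head, make_lesion(config, v, depth))
                    for v in config.volumes_ml]
    # union of changed voxels across volumes, with a stable index
    union_mask = np.zeros(head.shape, dtype=bool)
    for p in phantoms:
        union_mask |= p.labels != baseline.labels
    union_idx = np.flatnonzero(union_mask.reshape(-1))

    w = 2.0 * np.pi * frequency
    dv = config.spacing ** 3
    centers = baseline.voxel_centers(union_mask)
    E, _ = fields.incident_field(src, centers, frequency)
    e_dot_e = np.einsum("ij,ij->i", E, E)

    rng = np.random.default_rng(noise.seed)
    s = noise.magnitude / 100.0
    fs = 1.0 + s * rng.standard_normal((noise.repeats, len(union_idx)))
    fe = 1.0 + s * rng.standard_normal((noise.repeats, len(union_idx)))

    clean_curve = np.zeros(len(config.volumes_ml))
    noisy_curves = np.zeros((noise.repeats, len(config.volumes_ml)))
    for iv, p in enumerate(phantoms):
        changed = (p.labels != baseline.labels).reshape(-1)
        sel = np.searchsorted(union_idx, np.flatnonzero(changed))
        if len(sel) == 0:
            continue
        old = baseline.labels.reshape(-1)[changed]
        new = p.labels.reshape(-1)[changed]
        p_old = {int(l): dielectrics.tissue_properties(p.label_map[int(l)],
                                                       frequency)
                 for l in np.unique(old)}
        p_new = {int(l): dielectrics.tissue_properties(p.label_map[int(l)],
                                                       frequency)
                 for l in np.unique(new)}
        sig_o = np.array([p_old[int(l)].sigma for l in old])
        eps_o = np.array([p_old[int(l)].eps_rel for l in old])
        sig_n = np.array([p_new[int(l)].sigma for l in new])
        eps_n = np.array([p_new[int(l)].eps_rel for l in new])
        ee = e_dot_e[sel]
        kap = (sig_n - sig_o) - 1j * w * dielectrics.EPS0 * (eps_n - eps_o)
        clean_curve[iv] = abs(-np.sum(kap * ee * dv))
        kap_noisy = ((sig_n * fs[:, sel] - sig_o)
                     - 1j * w * dielectrics.EPS0 * (eps_n * fe[:, sel] - eps_o))
        noisy_curves[:, iv] = np.abs(-np.sum(kap_noisy * ee * dv, axis=1))

    clean_pattern = np.sign(np.diff(clean_curve))
    preserved = np.array([np.array_equal(np.sign(np.diff(c)), clean_pattern)
                          for c in noisy_curves])
    return {
        "volumes_ml": np.asarray(config.volumes_ml, dtype=float),
        "clean_curve": clean_curve,
        "noisy_curves": noisy_curves,
        "pattern_preserved_fraction": float(preserved.mean()),
    }


# ---------------------------------------------------------------------------
# SNR study (additive receiver noise on the port signal)

def _noisy_delta_z(delta_z_clean: np.ndarray, snr_db: float,
                   repeats: int, rng: np.random.Generator,
                   z0: float = forward.Z0_DEFAULT) -> np.ndarray:
    """Complex noisy dZ per (repeat, reading).

    The baseline load is the matched port z0; the later reading is
    z0 + dZ.  Complex white Gaussian noise at ``snr_db`` below the
    working reflected-wave amplitude of each reading pair is added to
    both reflected signals before conversion back to impedance.
    """
    dz = np.atleast_1d(np.asarray(delta_z_clean, dtype=complex))
    s1 = np.zeros_like(dz)                             # matched baseline
    s2 = np.array([forward.impedance_to_s11(z0 + d, z0) for d in dz])
    v_signal = np.maximum(np.abs(s1), np.abs(s2))
    v_noise = v_signal * 10.0 ** (-snr_db / 20.0)
    shape = (repeats, len(dz))
    cn = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
    cn2 = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
    s1n = s1 + v_noise * cn
    s2n = s2 + v_noise * cn2
    z1n = z0 * (1 + s1n) / (1 - s1n)
    z2n = z0 * (1 + s2n) / (1 - s2n)
    return z2n - z1n


def snr_experiment(delta_z_series: np.ndarray, snr_db: float,
                   repeats: int = 500, seed: int = 0,
                   z0: float = forward.Z0_DEFAULT) -> dict:
    """Distribution of |dZ| errors under receiver noise (Gaussian, SNR dB).

    ``delta_z_series`` are clean complex impedance changes (one per
    monitored volume/reading).  Returns the per-(repeat, reading)
    differences |dZ|_noisy - |dZ|_clean, whose histogram peaks at the
    origin, plus summary statistics.
    """
    if snr_db <= 0:
        raise ValueError("SNR must be positive dB")
    rng = np.random.default_rng(seed)
    dz = np.atleast_1d(np.asarray(delta_z_series, dtype=complex))
    noisy = _noisy_delta_z(dz, snr_db, repeats, rng, z0)
    diffs = np.abs(noisy) - np.abs(dz)[None, :]
    flat = diffs[:, np.abs(dz) > 0].ravel()
    return {
        "differences": flat,
        "noisy_abs": np.abs(noisy),
        "mean_diff": float(flat.mean()) if flat.size else 0.0,
        "std_diff": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
        "sem_diff": (float(flat.std(ddof=1) / np.sqrt(flat.size))
                     if flat.size > 1 else 0.0),
    }


def averaged_measurement(delta_z_clean: complex, snr_db: float,
                         repeats: int = 128, seed: int = 0,
                         z0: float = forward.Z0_DEFAULT) -> tuple[complex, float]:
    """Mean noisy dZ over ``repeats`` and the std of that mean.

    Averaging N repeats shrinks the noise std by sqrt(N), which is the
    rationale for taking ~128 repeats per frequency in practice.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    noisy = _noisy_delta_z(np.array([delta_z_clean]), snr_db, repeats, rng,
                           z0)[:, 0]
    mean = complex(noisy.mean())
    if repeats == 1:
        return mean, 0.0
    std_single = float(np.sqrt(noisy.real.var(ddof=1) + noisy.imag.var(ddof=1)))
    return mean, std_single / np.sqrt(repeats)


# ---------------------------------------------------------------------------
# clinical-case presets

CASE_PRESETS = ("subarachnoid_deep_sphere", "intraparenchymal_4to1_ellipsoid")


def case_preset(name: str) -> SweepConfig:
    """Fully specified configs for the two clinical monitoring scenarios.

    Both place the antenna 0.5 cm from the skull and probe at 1 GHz.
    The subarachnoid case is a deep sphere offset (-2, -3) cm laterally
    at 10 cm depth; the intraparenchymal case is a 4:1:1 ellipsoid with
    its major axis along the boresight, offset (-3, -4) cm at 8 cm.
    """
    if name == "subarachnoid_deep_sphere":
        return SweepConfig(frequencies=(1e9,),
                           volumes_ml=tuple(np.linspace(0.0, 30.0, 13)),
                           lesion_ratios=(1.0, 1.0, 1.0),
                           depths_m=(0.10,),
                           lesion_offset_xy=(-0.02, -0.03),
                           standoff=0.005)
    if name == "intraparenchymal_4to1_ellipsoid":
        return SweepConfig(frequencies=(1e9,),
                           volumes_ml=tuple(np.linspace(0.0, 30.0, 13)),
                           lesion_ratios=(1.0, 1.0, 4.0),
                           depths_m=(0.08,),
                           lesion_offset_xy=(-0.03, -0.04),
                           standoff=0.005)
    raise ValueError(f"unknown case preset {name!r}; "
                     f"known: {CASE_PRESETS}")
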