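"""Monitoring physics: port relations and the Born impedance perturbation.

The antenna reading is the complex input impedance Z_L, related to the
reflection coefficient by Z_L = Z0 (1 + S11) / (1 - S11).  A change of
material inside the probed volume perturbs Z_L; to first order (Born
approximation, E ~ E0 inside the perturbation) the change is the
volume integral

    dZ_L = -(1/I^2) sum_voxels (d_sigma - i w d_eps) (E0 . E0) dV

with an unconjugated complex dot product and no magnetic term (tissues
are non-magnetic, d_mu = 0; the H.H0 term is carried in the data model
but evaluates to zero).  The port current I is not observable in the
monitoring setup and defaults to 1 A; dZ scales as 1/I^2, a constant
that cancels in every trend comparison.

The monitoring metric compares readings at a baseline time t1 (the
conventional-imaging instant) and a later time t2:
dZ = |Z_{L,t2} - Z_{L,t1}|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dielectrics import EPS0, tissue_properties
from .fields import SourceModel, incident_field
from .phantom import VoxelPhantom

Z0_DEFAULT = 50.0  # ohm, conventional source impedance


class PortSingularityError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class PortState:
    """Port condition: source impedance, reflection coefficient, load."""

    z0: float
    s11: complex

    @property
    def z_load(self) -> complex:
        return s11_to_impedance(self.s11, self.z0)


@dataclass(frozen=True)
class ImpedanceReading:
    frequency: float      # Hz
    time_tag: str         # "t1_baseline" or "t2"
    z: complex            # ohm


@dataclass(frozen=True)
class DeltaZ:
    """Complex impedance change and its monitoring summaries."""

    complex_delta: complex

    @property
    def abs_delta(self) -> float:
        return abs(self.complex_delta)

    @property
    def real_delta(self) -> float:
        return self.complex_delta.real


def s11_to_impedance(s11: complex, z0: float = Z0_DEFAULT) -> complex:
    """Z_L = Z0 (1 + S11) / (1 - S11)."""
    if s11 == 1:
        raise PortSingularityError("S11 = 1 is an open circuit")
    return z0 * (1 + s11) / (1 - s11)


def impedance_to_s11(z_load: complex, z0: float = Z0_DEFAULT) -> complex:
    """S11 = (Z_L - Z0) / (Z_L + Z0); inverse of :func:`s11_to_impedance`."""
    if z_load == -z0:
        raise PortSingularityError("Z_L = -Z0 is singular")
    return (z_load - z0) / (z_load + z0)


def delta_z_metric(reading_t1: ImpedanceReading,
                   reading_t2: ImpedanceReading) -> DeltaZ:
    """Monitoring metric between a baseline and a later reading."""
    if reading_t1.frequency != reading_t2.frequency:
        raise ValueError("readings must share a frequency")
    return DeltaZ(complex_delta=reading_t2.z - reading_t1.z)


def born_contrast_sum(centers: np.ndarray,
                      delta_sigma: np.ndarray,
                      delta_eps_abs: np.ndarray,
                      source: SourceModel,
                      frequency: float,
                      dv: float | np.ndarray,
                      port_current: float = 1.0) -> complex:
    """Born quadrature over explicit per-point contrasts.

    ``centers`` are quadrature points (N, 3) with volume weight ``dv``
    (scalar or per-point); contrasts are per-point d_sigma (S/m) and
    absolute d_eps (F/m).  This is the kernel behind
    :func:`born_delta_impedance` and is exposed for refinement oracles
    and synthetic-contrast (linearity) studies.
    """
    if len(centers) == 0:
        return 0.0 + 0.0j
    w = 2.0 * np.pi * frequency
    E, _ = incident_field(source, centers, frequency)
    e_dot_e = np.einsum("ij,ij->i", E, E)          # unconjugated
    kappa = delta_sigma - 1j * w * delta_eps_abs
    total = np.sum(kappa * e_dot_e * dv)
    return complex(-total / port_current ** 2)


def born_delta_impedance(baseline: VoxelPhantom,
                         current: VoxelPhantom,
                         source: SourceModel,
                         frequency: float,
                         port_current: float = 1.0) -> complex:
    """First-order impedance change between two phantom states.

    Only voxels whose label differs between ``baseline`` and
    ``current`` contribute; each carries the property contrast of its
    new tissue against its baseline tissue.  Exactly zero when the
    phantoms are identical, additive over disjoint changed regions and
    linear in the contrast.
    """
    if (baseline.spacing != current.spacing
            or baseline.shape != current.shape
            or not np.allclose(baseline.origin, current.origin)):
        raise ValueError("phantoms must share grid geometry")
    if not source.calibrated:
        raise RuntimeError("source must be calibrated before the Born integral")
    changed = baseline.labels != current.labels
    if not changed.any():
        return 0.0 + 0.0j
    centers = current.voxel_centers(changed)
    old = baseline.labels[changed]
    new = current.labels[changed]
    # per-(old,new) label-pair contrasts, evaluated once per pair
    dsig = np.empty(len(centers))
    deps = np.empty(len(centers))
    pairs = {(int(o), int(n)) for o, n in zip(old, new)}
    for o, n in pairs:
        p_old = tissue_properties(baseline.tissue_of(o), frequency)
        p_new = tissue_properties(current.tissue_of(n), frequency)
        sel = (old == o) & (new == n)
        dsig[sel] = p_new.sigma - p_old.sigma
        deps[sel] = EPS0 * (p_new.eps_rel - p_old.eps_rel)
    dv = current.spacing ** 3
    return born_contrast_sum(centers, dsig, deps, source, frequency, dv,
                             port_current)
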