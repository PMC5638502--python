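"""Frequency-dependent complex electrical properties of head tissues.

Tissues are described by a multi-term Cole-Cole dispersion

    eps*(w) = eps_inf + sum_k  d_eps_k / (1 + (j w tau_k)^(1-alpha_k))
              + sigma_s / (j w eps0)

evaluated under the e^{+j w t} time-harmonic convention, so that the
complex relative permittivity is ``eps* = eps_rel - j sigma/(w eps0)``
with ``eps_rel >= 1`` and effective conductivity ``sigma >= 0`` for
physical tissues.  The effective conductivity folds the dielectric loss
of the relaxation terms together with the static ionic conductivity,
matching how tissue-property databases report (eps_r, sigma) pairs.

The parameter table ships with the package as JSON fixture data
(``data/tissue_dispersion.json``) and is validated for 10 MHz - 3 GHz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

EPS0 = 8.8541878128e-12  # F/m
MU0 = 4e-7 * np.pi       # H/m
C0 = 299792458.0         # m/s

FREQ_MIN = 1e7   # Hz, validated range of the embedded table
FREQ_MAX = 3e9

TISSUE_NAMES = ("blood", "white_matter", "gray_matter", "csf", "skull",
                "air", "substrate")


class InvalidTissueError(KeyError):
    """Unknown tissue/material name."""


class FrequencyRangeError(ValueError):
    """Frequency outside the validated range of the dispersion table."""


@dataclass(frozen=True)
class TissueDispersion:
    """Cole-Cole dispersion parameters for one material.

    Parameters
    ----------
    tissue_name : str
        One of :data:`TISSUE_NAMES`.
    eps_inf : float
        High-frequency relative permittivity (>= 1).
    terms : tuple of (delta_eps, tau, alpha)
        Relaxation terms; ``tau`` in seconds, ``alpha`` in [0, 1).
    sigma_static : float
        Static ionic conductivity in S/m.
    """

    tissue_name: str
    eps_inf: float
    terms: tuple = ()
    sigma_static: float = 0.0

    def __post_init__(self):
        if self.eps_inf < 1.0:
            raise ValueError("eps_inf must be >= 1")
        if self.sigma_static < 0.0:
            raise ValueError("sigma_static must be >= 0")
        for de, tau, alpha in self.terms:
            if de < 0 or tau <= 0 or not (0.0 <= alpha < 1.0):
                raise ValueError(f"invalid Cole-Cole term ({de}, {tau}, {alpha})")

    def complex_permittivity(self, frequency: float | np.ndarray) -> complex | np.ndarray:
        """Complex relative permittivity eps* at ``frequency`` (Hz)."""
        w = 2.0 * np.pi * np.asarray(frequency, dtype=float)
        ec = np.full_like(w, self.eps_inf, dtype=complex)
        for de, tau, alpha in self.terms:
            if de:
                ec = ec + de / (1.0 + (1j * w * tau) ** (1.0 - alpha))
        if self.sigma_static:
            ec = ec + self.sigma_static / (1j * w * EPS0)
        return ec if ec.shape else complex(ec)


@dataclass(frozen=True)
class ElectricalProperties:
    """(eps_rel, sigma) of a material at a single frequency.

    ``eps_complex`` reconstructs ``eps_rel - j sigma/(w eps0)``.
    """

    frequency: float   # Hz
    eps_rel: float     # dimensionless, real relative permittivity
    sigma: float       # S/m, effective conductivity

    @property
    def eps_complex(self) -> complex:
        w = 2.0 * np.pi * self.frequency
        return self.eps_rel - 1j * self.sigma / (w * EPS0)

    @property
    def wavenumber(self) -> complex:
        """Complex propagation constant k = (w/c) sqrt(eps*), Im(k) <= 0."""
        w = 2.0 * np.pi * self.frequency
        return (w / C0) * np.sqrt(self.eps_complex)

    @property
    def intrinsic_impedance(self) -> complex:
        """eta = w mu0 / k (ohm)."""
        w = 2.0 * np.pi * self.frequency
        return w * MU0 / self.wavenumber


@dataclass(frozen=True)
class Contrast:
    """Property differences lesion minus background (same frequency).

    ``delta_eps_abs`` is an absolute permittivity difference (F/m);
    ``delta_mu`` is identically zero: tissues are non-magnetic.
    """

    delta_sigma: float       # S/m
    delta_eps_abs: float     # F/m
    delta_mu: float = 0.0    # H/m, fixed 0


def _load_table() -> dict:
    with resources.files("hemoradar.data").joinpath("tissue_dispersion.json").open() as fh:
        raw = json.load(fh)
    table = {}
    for name, rec in raw["materials"].items():
        table[name] = TissueDispersion(
            tissue_name=name,
            eps_inf=rec["eps_inf"],
            terms=tuple((d, t, a) for d, t, a in rec["terms"]),
            sigma_static=rec["sigma_static"],
        )
    return table


DISPERSION_TABLE: dict[str, TissueDispersion] = _load_table()


def get_tissue(name: str) -> TissueDispersion:
    try:
        return DISPERSION_TABLE[name]
    except KeyError:
        raise InvalidTissueError(
            f"unknown tissue {name!r}; known: {sorted(DISPERSION_TABLE)}") from None


def tissue_properties(tissue: TissueDispersion | str, frequency: float) -> ElectricalProperties:
    """Evaluate (eps_rel, sigma) for a tissue at ``frequency`` in Hz.

    Raises
    ------
    InvalidTissueError
        If ``tissue`` is an unknown name.
    FrequencyRangeError
        If ``frequency`` lies outside the validated 10 MHz - 3 GHz range.
    """
    if isinstance(tissue, str):
        tissue = get_tissue(tissue)
    if not (FREQ_MIN <= frequency <= FREQ_MAX):
        raise FrequencyRangeError(
            f"frequency {frequency:g} Hz outside validated range "
            f"[{FREQ_MIN:g}, {FREQ_MAX:g}] Hz")
    w = 2.0 * np.pi * frequency
    ec = tissue.complex_permittivity(frequency)
    return ElectricalProperties(frequency=frequency,
                                eps_rel=float(np.real(ec)),
                                sigma=float(-w * EPS0 * np.imag(ec)))


def mixture_properties(components: list[tuple[TissueDispersion | str, float]],
                       frequency: float) -> ElectricalProperties:
    """Volume-weighted (eps_rel, sigma) mixture of several tissues.

    Weights are normalized to sum to one.  Used for the average-brain
    background medium of the incident-field surrogate.
    """
    weights = np.array([w for _, w in components], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("mixture weights must be non-negative with positive sum")
    weights = weights / weights.sum()
    eps = sig = 0.0
    for (tissue, _), w in zip(components, weights):
        p = tissue_properties(tissue, frequency)
        eps += w * p.eps_rel
        sig += w * p.sigma
    return ElectricalProperties(frequency=frequency, eps_rel=eps, sigma=sig)


def contrast(lesion: ElectricalProperties, background: ElectricalProperties) -> Contrast:
    """Property contrast (Born perturbation strengths) lesion - background."""
    if lesion.frequency != background.frequency:
        raise ValueError("contrast requires properties at the same frequency")
    return Contrast(delta_sigma=lesion.sigma - background.sigma,
                    delta_eps_abs=EPS0 * (lesion.eps_rel - background.eps_rel))


def fresnel_reflectivity(medium1: ElectricalProperties,
                         medium2: ElectricalProperties) -> float:
    """Normal-incidence power reflectivity |Gamma|^2 between two media.

    Gamma = (sqrt(eps1*) - sqrt(eps2*)) / (sqrt(eps1*) + sqrt(eps2*))
    with principal square roots of the complex relative permittivities.
    Symmetric under exchange of the media.
    """
    if medium1.frequency != medium2.frequency:
        raise ValueError("reflectivity requires properties at the same frequency")
    n1 = np.sqrt(medium1.eps_complex)
    n2 = np.sqrt(medium2.eps_complex)
    gamma = (n1 - n2) / (n1 + n2)
    return float(np.abs(gamma) ** 2)
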