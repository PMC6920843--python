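"""Closed-form forward models for proton spin-lattice relaxation dispersion.

The total :math:`R_1(\\omega_H)` of a solid protein is modelled as the sum of a
homonuclear ("model-free") contribution -- three Lorentzian dispersion terms
plus a frequency-independent offset -- and a heteronuclear H-N contribution
that carries the quadrupole relaxation enhancement (QRE) peaks.

Unit conventions
----------------
* All rate formulas evaluate in angular frequency (rad/s); conversion from
  Larmor frequency in MHz is centralized in :func:`angular_frequency`.
* Dipolar relaxation constants ``C`` are squared angular frequencies
  (rad^2 s^-2).  Printed tables sometimes label these "Hz^2"; only the
  rad^2 s^-2 reading is consistent with the inter-spin distances this module
  produces, so that is what is used throughout.
* Quadrupole amplitudes and transition frequencies are in MHz, correlation
  times in seconds, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CODATA",
    "angular_frequency",
    "QuadrupoleCoupling",
    "QuadrupoleSpectrum",
    "transition_frequencies",
    "HHComponent",
    "HHModelParams",
    "HNModelParams",
    "hh_component_rate",
    "hh_total_rate",
    "hn_angular_weights",
    "hn_closed_form_rate",
    "hn_extreme_narrowing_rate",
    "total_rate",
    "hn_constant_from_distance",
    "hn_distance_from_constant",
    "hh_constant_from_distance",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Nuclear and electromagnetic constants used by the dipolar formulas.

    Attributes
    ----------
    gamma_H, gamma_N:
        Gyromagnetic ratios of 1H and 14N in rad s^-1 T^-1.
    hbar:
        Reduced Planck constant, J s.
    mu0_over_4pi:
        Magnetic constant divided by 4 pi, T m A^-1.
    """

    gamma_H: float = 2.6752e8
    gamma_N: float = 1.9338e7
    hbar: float = 1.0546e-34
    mu0_over_4pi: float = 1.0e-7

    def __post_init__(self) -> None:
        for name in ("gamma_H", "gamma_N", "hbar", "mu0_over_4pi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def gamma_ratio(self) -> float:
        """gamma_N / gamma_H, used to derive omega_N from omega_H (~0.0723)."""
        return self.gamma_N / self.gamma_H


#: Default constant set.
CODATA = PhysicalConstants()


def angular_frequency(nu_MHz):
    """Convert a Larmor frequency in MHz to angular frequency in rad/s.

    This is the single point where the ``omega = 2 pi nu`` convention lives.
    """
    return 2.0 * np.pi * np.asarray(nu_MHz, dtype=float) * 1.0e6


@dataclass(frozen=True)
class QuadrupoleCoupling:
    """Amplitude and asymmetry of the 14N quadrupole coupling.

    ``a_Q`` is e^2 q Q / h in MHz; ``eta`` is the dimensionless asymmetry
    parameter of the electric-field-gradient tensor.
    """

    a_Q: float
    eta: float

    def __post_init__(self) -> None:
        if self.a_Q <= 0:
            raise ValueError(f"a_Q must be > 0, got {self.a_Q}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {self.eta}")


@dataclass(frozen=True)
class QuadrupoleSpectrum:
    """Zero-field 14N energy levels (units of a_Q) and transition frequencies (MHz)."""

    E1: float
    E2: float
    E3: float
    nu_minus: float
    nu_plus: float
    nu_zero: float


def transition_frequencies(quad: QuadrupoleCoupling) -> QuadrupoleSpectrum:
    """Energy levels and transition frequencies of a quadrupole-dominated S=1 nucleus.

    E1 = a_Q (1 - eta)/4, E2 = -a_Q/2, E3 = a_Q (1 + eta)/4, and the three
    transitions nu_- = 3 a_Q (1 - eta/3)/4, nu_+ = 3 a_Q (1 + eta/3)/4,
    nu_0 = eta a_Q / 2 = nu_+ - nu_-.
    """
    a, eta = quad.a_Q, quad.eta
    return QuadrupoleSpectrum(
        E1=0.25 * a * (1.0 - eta),
        E2=-0.5 * a,
        E3=0.25 * a * (1.0 + eta),
        nu_minus=0.75 * a * (1.0 - eta / 3.0),
        nu_plus=0.75 * a * (1.0 + eta / 3.0),
        nu_zero=0.5 * eta * a,
    )


@dataclass(frozen=True)
class HHComponent:
    """One Lorentzian H-H dispersion term: constant C (rad^2 s^-2) and
    correlation time tau (s)."""

    C: float
    tau: float

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError(f"dipolar constant must be >= 0, got {self.C}")
        if self.tau <= 0:
            raise ValueError(f"correlation time must be > 0, got {self.tau}")


@dataclass(frozen=True)
class HHModelParams:
    """Three-component model-free parameters plus the constant offset A (s^-1).

    The component labels are ordered: tau_slow > tau_intermediate > tau_fast.
    """

    slow: HHComponent
    intermediate: HHComponent
    fast: HHComponent
    A: float = 0.0

    def __post_init__(self) -> None:
        if not (self.slow.tau > self.intermediate.tau > self.fast.tau):
            raise ValueError(
                "correlation times must be ordered slow > intermediate > fast, "
                f"got {self.slow.tau} / {self.intermediate.tau} / {self.fast.tau}"
            )
        if self.A < 0:
            raise ValueError(f"A must be >= 0, got {self.A}")

    @property
    def components(self) -> tuple[HHComponent, HHComponent, HHComponent]:
        return (self.slow, self.intermediate, self.fast)


@dataclass(frozen=True)
class HNModelParams:
    """Parameters of the H-N (QRE) relaxation contribution.

    ``theta``/``phi`` (degrees) orient the H-N dipole-dipole axis in the
    principal axis system of the electric field gradient.
    """

    C_HN: float
    tau_Q: float
    theta: float
    phi: float
    quad: QuadrupoleCoupling

    def __post_init__(self) -> None:
        if self.C_HN < 0:
            raise ValueError(f"C_HN must be >= 0, got {self.C_HN}")
        if self.tau_Q <= 0:
            raise ValueError(f"tau_Q must be > 0, got {self.tau_Q}")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError(f"theta must lie in [0, 180] deg, got {self.theta}")
        if not 0.0 <= self.phi < 360.0:
            raise ValueError(f"phi must lie in [0, 360) deg, got {self.phi}")


def _check_omega(omega_H) -> np.ndarray:
    omega = np.asarray(omega_H, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega_H must be non-negative")
    return omega


def _lorentzian_pair(tau: float, omega: np.ndarray) -> np.ndarray:
    """tau/(1+w^2 tau^2) + 4 tau/(1+4 w^2 tau^2) -- the H-H dispersion kernel."""
    wt2 = (omega * tau) ** 2
    return tau / (1.0 + wt2) + 4.0 * tau / (1.0 + 4.0 * wt2)


def hh_component_rate(comp: HHComponent, omega_H):
    """Single-process H-H rate: C [tau/(1+w^2 tau^2) + 4 tau/(1+4 w^2 tau^2)].

    Equals 5 C tau at zero frequency and decays monotonically to zero.
    """
    omega = _check_omega(omega_H)
    return comp.C * _lorentzian_pair(comp.tau, omega)


def hh_total_rate(params: HHModelParams, omega_H):
    """Sum of the slow/intermediate/fast H-H terms plus the constant A."""
    omega = _check_omega(omega_H)
    rate = np.full_like(omega, params.A, dtype=float)
    for comp in params.components:
        rate = rate + comp.C * _lorentzian_pair(comp.tau, omega)
    return rate if rate.ndim else float(rate)


def hn_angular_weights(theta_deg: float, phi_deg: float) -> tuple[float, float, float]:
    """Angular weights of the nu_-, nu_+ and nu_0 QRE terms; they sum to 2."""
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    s2 = np.sin(th) ** 2
    return (
        1.0 / 3.0 + s2 * np.cos(ph) ** 2,
        1.0 / 3.0 + s2 * np.sin(ph) ** 2,
        1.0 / 3.0 + np.cos(th) ** 2,
    )


def hn_closed_form_rate(params: HNModelParams, omega_H):
    """Closed-form H-N QRE rate: three angular-weighted Lorentzian pairs
    centred at the 14N transition frequencies.

    Valid in the motional limits omega_Q tau_Q << 1 or >> 1; the caller is
    responsible for checking validity (see :mod:`nmrdfit.sle`).
    """
    omega = _check_omega(omega_H)
    spec = transition_frequencies(params.quad)
    weights = hn_angular_weights(params.theta, params.phi)
    tau = params.tau_Q
    rate = np.zeros_like(omega)
    for w, nu_t in zip(weights, (spec.nu_minus, spec.nu_plus, spec.nu_zero)):
        wt = angular_frequency(nu_t)
        rate = rate + w * (
            tau / (1.0 + (omega - wt) ** 2 * tau**2)
            + tau / (1.0 + (omega + wt) ** 2 * tau**2)
        )
    rate = params.C_HN * rate
    return rate if rate.ndim else float(rate)


def hn_extreme_narrowing_rate(C_HN: float, tau_Q: float, omega_H):
    """Extreme-narrowing (omega_Q tau_Q << 1) limit: 4 C_HN tau_Q/(1+w^2 tau_Q^2).

    Identical to :func:`hn_closed_form_rate` with all three transition
    frequencies set to zero.
    """
    omega = _check_omega(omega_H)
    rate = 4.0 * C_HN * tau_Q / (1.0 + (omega * tau_Q) ** 2)
    return rate if np.ndim(rate) else float(rate)


def total_rate(hh: HHModelParams, hn: HNModelParams, omega_H):
    """Total R1 = R1_HH + R1_HN."""
    return hh_total_rate(hh, omega_H) + hn_closed_form_rate(hn, omega_H)


_M_PER_ANGSTROM = 1.0e-10


def hn_constant_from_distance(r_HN: float, constants: PhysicalConstants = CODATA) -> float:
    """C_HN = (2/3) ((mu0/4pi) gamma_H gamma_N hbar / r^3)^2, r in Angstrom."""
    if r_HN <= 0:
        raise ValueError("distance must be > 0")
    r3 = (r_HN * _M_PER_ANGSTROM) ** 3
    k = constants.mu0_over_4pi * constants.gamma_H * constants.gamma_N * constants.hbar
    return (2.0 / 3.0) * (k / r3) ** 2


def hn_distance_from_constant(C_HN: float, constants: PhysicalConstants = CODATA) -> float:
    """Effective H-N inter-spin distance (Angstrom) from a dipolar constant.

    Inverse of :func:`hn_constant_from_distance` to machine precision.
    """
    if C_HN <= 0:
        raise ValueError("C_HN must be > 0 to define a distance")
    k = constants.mu0_over_4pi * constants.gamma_H * constants.gamma_N * constants.hbar
    r3 = k / np.sqrt(1.5 * C_HN)
    return float(r3 ** (1.0 / 3.0) / _M_PER_ANGSTROM)


def hh_constant_from_distance(r_HH: float, constants: PhysicalConstants = CODATA) -> float:
    """C_HH = (3/10) ((mu0/4pi) gamma_H^2 hbar / r^3)^2, r in Angstrom."""
    if r_HH <= 0:
        raise ValueError("distance must be > 0")
    r3 = (r_HH * _M_PER_ANGSTROM) ** 3
    k = constants.mu0_over_4pi * constants.gamma_H**2 * constants.hbar
    return 0.3 * (k / r3) ** 2
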