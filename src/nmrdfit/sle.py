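"""Stochastic-Liouville computation of the H-N relaxation contribution.

The proton is relaxed by its dipole-dipole coupling to a quadrupolar S=1
nucleus (14N).  The "lattice" seen by the proton -- the S spin plus the
molecular orientation undergoing isotropic rotational diffusion -- is treated
exactly: the relaxation rate is the real part of a matrix element of the
inverse lattice resolvent,

    R1_HN(omega_H) = 12 C_HN * Re{ [T11]^+ [M]^-1 [T11] },

evaluated in the outer-product basis |Sigma, sigma) x |L, K, M) of normalized
spin tensor operators and Wigner rotation functions.  [M] combines

* the 14N Zeeman precession sigma * omega_N (omega_N = omega_H gamma_N/gamma_H),
* the proton frequency -omega_H at which the spectral density is evaluated,
* the quadrupole Liouvillian (rank-2 coupling with PAS components
  proportional to sqrt(6)/4 and eta/4 in units of 2 pi a_Q), and
* isotropic rotational-diffusion damping L(L+1)/(6 tau_Q).

This solver is valid at arbitrary omega_Q tau_Q and is the reference against
which the closed-form expression of :func:`nmrdfit.models.hn_closed_form_rate`
is judged (see :func:`validity_scan`).

Implementation notes
--------------------
* Spin-superoperator matrix elements are computed numerically as traces over
  explicit S=1 matrices; rotational matrix elements reduce to products of two
  Wigner 3-j symbols.  Both are cached.
* The observable vector couples only to the sector with sigma + M = 1 and
  even K, so the working basis is that block; :func:`assemble_M` builds the
  full matrix for structural checks and block/full equivalence tests.
* The L = 0 rotational functions (pure spin operators) are retained: they
  dominate the slow-motion (omega_Q tau_Q >> 1) response and removing them
  changes the rate by large factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .models import (
    CODATA,
    PhysicalConstants,
    QuadrupoleCoupling,
    angular_frequency,
    hn_closed_form_rate,
    HNModelParams,
    transition_frequencies,
)

__all__ = [
    "SLEBasisVector",
    "SLESystem",
    "SLEConvergenceError",
    "SingularSLEMatrixError",
    "build_basis",
    "rotational_dimension",
    "assemble_M",
    "t11_vector",
    "r1_hn_sle",
    "validity_scan",
    "ValidityScanResult",
]


class SLEConvergenceError(RuntimeError):
    """Raised when the rate has not converged in the basis truncation L_max."""


class SingularSLEMatrixError(np.linalg.LinAlgError):
    """Raised when [M] is singular at a given (omega_H, tau_Q)."""


@dataclass(frozen=True)
class SLEBasisVector:
    """One |Sigma, sigma) x |L, K, M) basis member."""

    Sigma: int
    sigma: int
    L: int
    K: int
    M: int

    def __post_init__(self) -> None:
        if abs(self.sigma) > self.Sigma:
            raise ValueError("|sigma| must not exceed Sigma")
        if abs(self.K) > self.L or abs(self.M) > self.L:
            raise ValueError("|K| and |M| must not exceed L")


def rotational_dimension(L_max: int, L_min: int = 1) -> int:
    """Number of Wigner functions |L, K, M| with L_min <= L <= L_max."""
    return sum((2 * L + 1) ** 2 for L in range(L_min, L_max + 1))


def _spin_ranks(S: float) -> tuple[int, ...]:
    # rank 0 is the identity and does not relax; ranks 1..2S couple.
    return tuple(range(1, int(round(2 * S)) + 1))


def build_basis(L_max: int, S: float = 1, L_min: int = 1) -> tuple[SLEBasisVector, ...]:
    """Ordered (lexicographic in Sigma, sigma, L, K, M) Liouville basis.

    ``L_max`` must be at least 2 so the rank-2 couplings are representable.
    """
    if L_max < 2:
        raise ValueError("L_max must be >= 2 to represent rank-2 couplings")
    if L_min < 0 or L_min > L_max:
        raise ValueError("L_min must satisfy 0 <= L_min <= L_max")
    out = []
    for Sig in _spin_ranks(S):
        for sig in range(-Sig, Sig + 1):
            for L in range(L_min, L_max + 1):
                for K in range(-L, L + 1):
                    for M in range(-L, L + 1):
                        out.append(SLEBasisVector(Sig, sig, L, K, M))
    return tuple(out)


@lru_cache(maxsize=None)
def _wigner3j(j1: int, j2: int, j3: int, m1: int, m2: int, m3: int) -> float:
    from sympy.physics.wigner import wigner_3j

    return float(wigner_3j(j1, j2, j3, m1, m2, m3))


@lru_cache(maxsize=1)
def _spin1_tensors() -> dict[tuple[int, int], np.ndarray]:
    """Orthonormal (Tr{T^+ T} = 1) irreducible tensor operators for S = 1."""
    Sz = np.diag([1.0, 0.0, -1.0])
    Sp = np.zeros((3, 3))
    Sp[0, 1] = Sp[1, 2] = np.sqrt(2.0)
    Sm = Sp.T.copy()
    eye = np.eye(3)
    return {
        (1, 0): Sz / np.sqrt(2.0),
        (1, 1): -Sp / 2.0,
        (1, -1): Sm / 2.0,
        (2, 0): (3.0 * Sz @ Sz - 2.0 * eye) / np.sqrt(6.0),
        (2, 1): -(Sz @ Sp + Sp @ Sz) / 2.0,
        (2, -1): (Sz @ Sm + Sm @ Sz) / 2.0,
        (2, 2): Sp @ Sp / 2.0,
        (2, -2): Sm @ Sm / 2.0,
    }


@lru_cache(maxsize=1)
def _spin_coupling_table() -> dict[tuple[int, int, int, int, int], float]:
    """Tr{ T(Sigma', sigma')^+ [T(2, m), T(Sigma, sigma)] } for S = 1.

    Non-zero only for Sigma + Sigma' odd and sigma' = sigma + m (the
    commutator structure of the rank-2 coupling).
    """
    T = _spin1_tensors()
    table: dict[tuple[int, int, int, int, int], float] = {}
    for (Sp_, sp_), Ap in T.items():
        for (S_, s_), A in T.items():
            m = sp_ - s_
            if abs(m) > 2:
                continue
            comm = T[(2, m)] @ A - A @ T[(2, m)]
            val = float(np.trace(Ap.conj().T @ comm).real)
            if abs(val) > 1e-14:
                table[(Sp_, sp_, m, S_, s_)] = val
    return table


def _rotational_element(Lp: int, Kp: int, Mp: int, k: int, q: int, L: int, K: int, M: int) -> float:
    """Matrix element of D^2_{k,q}(Omega) between normalized Wigner functions."""
    if Kp != K + k or Mp != M + q or abs(Lp - L) > 2:
        return 0.0
    return (
        np.sqrt((2 * L + 1) * (2 * Lp + 1))
        * (-1.0) ** (Kp - Mp)
        * _wigner3j(Lp, 2, L, -Kp, k, K)
        * _wigner3j(Lp, 2, L, -Mp, q, M)
    )


# PAS components of the quadrupole coupling in units of omega_aQ = 2 pi a_Q:
# v_0 = sqrt(6)/4, v_(+/-2) = eta/4 (the eta/sqrt(6) ratio of the printed
# F factors), v_(+/-1) = 0.
_U0 = np.sqrt(6.0) / 4.0
_U2 = 0.25


def _quad_matrices(basis: tuple[SLEBasisVector, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Quadrupole Liouvillian in units of omega_aQ, split as Q0 + eta * Q2."""
    n = len(basis)
    index = {(b.Sigma, b.sigma, b.L, b.K, b.M): i for i, b in enumerate(basis)}
    spin = _spin_coupling_table()
    Q0 = np.zeros((n, n))
    Q2 = np.zeros((n, n))
    for col, b in enumerate(basis):
        for (Sp_, sp_, m, S_, s_), cs in spin.items():
            if S_ != b.Sigma or s_ != b.sigma:
                continue
            # spatial function attached to T^2_m is (-1)^m sum_k v_k D^2_{k,-m}
            Mp = b.M - m
            ph = (-1.0) ** m
            for k, Qmat, u in ((0, Q0, _U0), (2, Q2, _U2), (-2, Q2, _U2)):
                Kp = b.K + k
                for Lp in range(max(abs(Kp), abs(Mp), 0), b.L + 3):
                    if abs(Lp - b.L) > 2:
                        continue
                    row = index.get((Sp_, sp_, Lp, Kp, Mp))
                    if row is None:
                        continue
                    cr = _rotational_element(Lp, Kp, Mp, k, -m, b.L, b.K, b.M)
                    if cr != 0.0:
                        Qmat[row, col] += ph * u * cs * cr
    return Q0, Q2


# Non-zero elements of the observable vector: the lattice side of the
# proton-flip part of the H-N dipolar coupling.  Amplitudes are the
# Clebsch-Gordan weights (1, -1/sqrt(2), 1/sqrt(6)) projected on the
# normalized basis (squares 1/5, 1/10, 1/30).
_T11_ELEMENTS = {
    (1, -1, 2, 0, 2): 1.0 / np.sqrt(5.0),
    (1, 0, 2, 0, 1): -1.0 / np.sqrt(10.0),
    (1, 1, 2, 0, 0): 1.0 / np.sqrt(30.0),
}


def t11_vector(basis: tuple[SLEBasisVector, ...]) -> np.ndarray:
    """Representation of the T_1^1 spin-flip operator in ``basis``.

    Exactly three entries are non-zero; raises if the basis omits them.
    """
    t = np.zeros(len(basis))
    found = 0
    for i, b in enumerate(basis):
        key = (b.Sigma, b.sigma, b.L, b.K, b.M)
        if key in _T11_ELEMENTS:
            t[i] = _T11_ELEMENTS[key]
            found += 1
    if found != len(_T11_ELEMENTS):
        raise ValueError("basis does not contain all three T11 carrier states")
    return t


@dataclass(frozen=True)
class SLESystem:
    """Assembled SLE problem for one proton frequency."""

    basis: tuple[SLEBasisVector, ...]
    M_matrix: np.ndarray
    T11_vector: np.ndarray
    omega_H: float
    omega_N: float
    quad: QuadrupoleCoupling
    tau_Q: float


def assemble_M(
    omega_H: float,
    quad: QuadrupoleCoupling,
    tau_Q: float,
    L_max: int = 8,
    basis: tuple[SLEBasisVector, ...] | None = None,
    constants: PhysicalConstants = CODATA,
) -> SLESystem:
    """Assemble [M] over a full (or supplied) basis.

    Diagonal: i (sigma omega_N - omega_H) + L(L+1)/(6 tau_Q); off-diagonal:
    i times the quadrupole Liouvillian.  The real part of [M] is symmetric
    and positive (diffusion damping), the imaginary part carries the
    precession and quadrupole terms.
    """
    if tau_Q <= 0:
        raise ValueError("tau_Q must be > 0")
    if basis is None:
        basis = build_basis(L_max, L_min=0)
    Q0, Q2 = _quad_matrices(basis)
    omega_aQ = float(angular_frequency(quad.a_Q))
    Q = omega_aQ * (Q0 + quad.eta * Q2)
    sigma = np.array([b.sigma for b in basis], dtype=float)
    damp = np.array([b.L * (b.L + 1) for b in basis], dtype=float) / (6.0 * tau_Q)
    omega_N = omega_H * constants.gamma_ratio
    M = 1j * (Q + np.diag(sigma * omega_N - omega_H)) + np.diag(damp)
    return SLESystem(
        basis=basis,
        M_matrix=M,
        T11_vector=t11_vector(basis) if _has_t11(basis) else np.zeros(len(basis)),
        omega_H=omega_H,
        omega_N=omega_N,
        quad=quad,
        tau_Q=tau_Q,
    )


def _has_t11(basis: tuple[SLEBasisVector, ...]) -> bool:
    keys = {(b.Sigma, b.sigma, b.L, b.K, b.M) for b in basis}
    return all(k in keys for k in _T11_ELEMENTS)


@lru_cache(maxsize=8)
def _block_data(L_max: int):
    """Working block: sigma + M = 1, K even, L = 0..L_max (cached per L_max)."""
    members = []
    for Sig in (1, 2):
        for sig in range(-Sig, Sig + 1):
            M = 1 - sig
            for L in range(0, L_max + 1):
                if abs(M) > L:
                    continue
                for K in range(-L, L + 1, 2) if L % 2 == 0 else range(-L + 1, L, 2):
                    members.append(SLEBasisVector(Sig, sig, L, K, M))
    basis = tuple(members)
    Q0, Q2 = _quad_matrices(basis)
    t = t11_vector(basis)
    sigma = np.array([b.sigma for b in basis], dtype=float)
    damp6 = np.array([b.L * (b.L + 1) for b in basis], dtype=float) / 6.0
    return basis, sigma, damp6, Q0, Q2, t


def _solve_block(
    omegas: np.ndarray,
    quad: QuadrupoleCoupling,
    tau_Q: float,
    C_HN: float,
    L_max: int,
    constants: PhysicalConstants,
) -> np.ndarray:
    _, sigma, damp6, Q0, Q2, t = _block_data(L_max)
    omega_aQ = float(angular_frequency(quad.a_Q))
    Q = omega_aQ * (Q0 + quad.eta * Q2)
    damp = damp6 / tau_Q
    ratio = constants.gamma_ratio
    out = np.empty(omegas.shape, dtype=float)
    for i, w in np.ndenumerate(omegas):
        M = 1j * (Q + np.diag(sigma * (w * ratio) - w)) + np.diag(damp)
        try:
            y = np.linalg.solve(M, t)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise SingularSLEMatrixError(
                f"singular SLE matrix at omega_H={w!r} rad/s, tau_Q={tau_Q!r} s"
            ) from exc
        out[i] = 12.0 * C_HN * float(np.real(t @ y))
    return out


def r1_hn_sle(
    omega_H,
    quad: QuadrupoleCoupling,
    tau_Q: float,
    C_HN: float,
    L_max: int = 8,
    constants: PhysicalConstants = CODATA,
    check_convergence: bool = False,
    convergence_tol: float = 1e-3,
):
    """H-N relaxation rate from the stochastic Liouville equation.

    Real, non-negative and exactly linear in ``C_HN``.  With
    ``check_convergence=True`` the result is recomputed at ``L_max + 2`` and a
    :class:`SLEConvergenceError` is raised if the relative change exceeds
    ``convergence_tol``.
    """
    if tau_Q <= 0:
        raise ValueError("tau_Q must be > 0")
    omegas = np.asarray(omega_H, dtype=float)
    if np.any(omegas < 0):
        raise ValueError("omega_H must be non-negative")
    scalar = omegas.ndim == 0
    omegas = np.atleast_1d(omegas)
    out = _solve_block(omegas, quad, tau_Q, C_HN, L_max, constants)
    if check_convergence:
        ref = _solve_block(omegas, quad, tau_Q, C_HN, L_max + 2, constants)
        rel = np.max(np.abs(out - ref) / np.maximum(np.abs(ref), 1e-300))
        if rel > convergence_tol:
            raise SLEConvergenceError(
                f"rate changed by {rel:.2e} (> {convergence_tol:.1e}) between "
                f"L_max={L_max} and L_max={L_max + 2}"
            )
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class ValidityScanResult:
    """Per-frequency curves and per-x summary of the SLE vs closed-form scan."""

    curves: pd.DataFrame
    summary: pd.DataFrame


def _refine_peak(nu: np.ndarray, rate: np.ndarray, center: float, halfwidth: float):
    """Local maximum of ``rate`` near ``center`` (parabolic refinement)."""
    mask = (nu >= center - halfwidth) & (nu <= center + halfwidth)
    if mask.sum() < 3:
        return np.nan
    idx = np.flatnonzero(mask)
    j = idx[np.argmax(rate[idx])]
    if j == 0 or j == len(nu) - 1:
        return float(nu[j])
    x0, x1, x2 = nu[j - 1], nu[j], nu[j + 1]
    y0, y1, y2 = rate[j - 1], rate[j], rate[j + 1]
    # vertex of the parabola through the three bracketing points
    num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
    den = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if den == 0.0:
        return float(x1)
    return float(x1 - 0.5 * num / den)


def validity_scan(
    x_values,
    quad: QuadrupoleCoupling,
    C_HN: float,
    frequencies_MHz,
    L_max: int = 8,
    constants: PhysicalConstants = CODATA,
) -> ValidityScanResult:
    """Compare the SLE rate with the closed form over a range of x = omega_Q tau_Q.

    For each x the correlation time is tau_Q = x / (2 pi a_Q).  The closed
    form is evaluated at Theta = Phi = 0 (dipole axis along the EFG z axis,
    matching the SLE observable).  The summary reports, per x: max and mean
    relative deviation over the grid, the deviation restricted to the
    quadrupole-peak neighbourhoods, and the SLE peak positions.
    """
    nu = np.asarray(frequencies_MHz, dtype=float)
    omega = angular_frequency(nu)
    spec = transition_frequencies(quad)
    curve_rows = []
    summary_rows = []
    for x in np.atleast_1d(np.asarray(x_values, dtype=float)):
        if x <= 0:
            raise ValueError("x values must be > 0")
        tau_Q = float(x / angular_frequency(quad.a_Q))
        hn = HNModelParams(C_HN=C_HN, tau_Q=tau_Q, theta=0.0, phi=0.0, quad=quad)
        r_sle = r1_hn_sle(omega, quad, tau_Q, C_HN, L_max=L_max, constants=constants)
        r_cf = hn_closed_form_rate(hn, omega)
        rel = np.abs(r_sle - r_cf) / r_cf
        curve_rows.append(
            pd.DataFrame(
                {
                    "x": x,
                    "tau_Q_s": tau_Q,
                    "frequency_MHz": nu,
                    "r1_sle_per_s": r_sle,
                    "r1_closed_form_per_s": r_cf,
                    "rel_dev": rel,
                }
            )
        )
        fwhm = 1.0 / (np.pi * tau_Q) / 1e6  # MHz
        peaks = {}
        height_devs = []
        for name, nu_t in (
            ("nu_minus", spec.nu_minus),
            ("nu_plus", spec.nu_plus),
            ("nu_zero", spec.nu_zero),
        ):
            halfwin = max(fwhm, 0.1 * nu_t)
            peaks[name + "_sle_MHz"] = _refine_peak(nu, r_sle, nu_t, halfwin)
            near = np.abs(nu - nu_t) <= halfwin
            if near.any():
                height_devs.append(
                    abs(r_sle[near].max() - r_cf[near].max()) / r_cf[near].max()
                )
        summary_rows.append(
            {
                "x": float(x),
                "tau_Q_s": tau_Q,
                "max_rel_dev": float(rel.max()),
                "mean_rel_dev": float(rel.mean()),
                "peak_height_rel_dev": float(max(height_devs)) if height_devs else np.nan,
                **peaks,
            }
        )
    return ValidityScanResult(
        curves=pd.concat(curve_rows, ignore_index=True),
        summary=pd.DataFrame(summary_rows),
    )
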