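"""Equilibrium species distribution of a nucleated linear enzyme polymer.

The model
---------
Free tetramers exchange UTP and CTP; polymerized subunits bind CTP only
(the substrate site is occluded in the filament).  Taking the ligand-free
free tetramer, concentration ``b``, as the reference species, the free
pool sums to ``f = b * P_f`` where ``P_f`` is the free-tetramer binding
polynomial.  A filament of ``n >= 2`` tetramers carries statistical
weight

    c_n = K_e * sigma * z**n,        z = (b / K_e) * P_p,

with ``P_p = 1 + C/K_cp`` the per-subunit polymer binding polynomial and
``sigma = exp(-E_nuc)`` a nucleation factor paid once per filament.
Geometric sums give closed forms for the polymer mass and number:

    M_poly = K_e * sigma * z**2 * (2 - z) / (1 - z)**2
    N_fil  = K_e * sigma * z**2 / (1 - z)
    <n>    = M_poly / N_fil = (2 - z) / (1 - z)

The solver finds ``b`` from conservation of enzyme, f + M_poly = E_tot,
by bracketed root-finding (the left side is strictly increasing in b).
The active, catalytically competent species is the free, UTP-bound,
CTP-free tetramer in both inhibition mechanisms, so the active fraction
is ``a = b * (U/K_uf) / E_tot`` and the apparent specific activity is
``kcat_obs = k_max * a``.

At E_nuc = 0 the ladder reduces to the standard isodesmic case
(c_{n+1}/c_n = z with no nucleation penalty).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import Conditions, ThermoParams

# guard keeping z strictly below 1 at the upper bracket edge
_Z_GUARD = 1e-12
#: largest representable z strictly below 1
_Z_MAX = math.nextafter(1.0, 0.0)
_MAX_ITER = 200
_RTOL = 1e-12


class SolverError(RuntimeError):
    """Equilibrium root-finding failed; carries bracket and residuals."""

    def __init__(self, msg: str, bracket=None, residuals=None):
        super().__init__(msg)
        self.bracket = bracket
        self.residuals = residuals


@dataclass(frozen=True)
class EquilibriumState:
    """Solved species distribution and derived statistics.

    Attributes
    ----------
    b : float
        Ligand-free free-tetramer concentration (reference species), μM.
    f : float
        Total free-tetramer concentration over all ligation states, μM.
    z : float
        Per-subunit filament statistical weight, 0 <= z < 1.
    M_poly : float
        Enzyme mass (tetramer units) in filaments, μM.
    N_fil : float
        Filament number concentration, μM.
    mean_len : float
        Mean filament length in tetramers; NaN when no polymer.
    frac_poly : float
        M_poly / E_tot (0 for an empty system).
    a : float
        Active fraction: free AND UTP-bound AND CTP-free tetramers / E_tot.
    kcat_obs : float
        Apparent specific activity k_max * a, s⁻¹.
    """

    b: float
    f: float
    z: float
    M_poly: float
    N_fil: float
    mean_len: float
    frac_poly: float
    a: float
    kcat_obs: float


def binding_polynomials(params: ThermoParams, cond: Conditions) -> tuple[float, float]:
    """Binding polynomials (P_f, P_p) of the free tetramer and the polymer subunit.

    Competitive mechanism: UTP and CTP share a site on the free tetramer,
    P_f = 1 + U/K_uf + C/K_cf.  Noncompetitive: independent sites,
    P_f = (1 + U/K_uf)(1 + C/K_cf).  Polymerized subunits bind CTP only:
    P_p = 1 + C/K_cp.
    """
    u = cond.U / params.K_uf
    c = cond.C / params.K_cf
    if params.mechanism == "competitive":
        P_f = 1.0 + u + c
    else:
        P_f = (1.0 + u) * (1.0 + c)
    P_p = 1.0 + cond.C / params.K_cp
    return P_f, P_p


def _polymer_mass(z: float, K_e: float, sigma: float) -> float:
    """Closed form of sum_{n>=2} n * K_e * sigma * z^n."""
    return K_e * sigma * z * z * (2.0 - z) / (1.0 - z) ** 2


def _polymer_number(z: float, K_e: float, sigma: float) -> float:
    """Closed form of sum_{n>=2} K_e * sigma * z^n."""
    return K_e * sigma * z * z / (1.0 - z)


def solve_equilibrium(params: ThermoParams, cond: Conditions) -> EquilibriumState:
    """Solve mass balance f + M_poly = E_tot for the reference species b.

    The balance function b*P_f + M_poly(b) is strictly increasing on
    [0, K_e/P_p), so the root is unique; it is bracketed on
    [0, min(E_tot/P_f, (K_e/P_p)(1-eps))] and found with Brent's method
    at relative tolerance 1e-12.

    Raises
    ------
    SolverError
        If the bracketed iteration fails to converge within its budget.
    """
    P_f, P_p = binding_polynomials(params, cond)
    E_tot = cond.E_tot

    if E_tot == 0.0:
        return EquilibriumState(
            b=0.0, f=0.0, z=0.0, M_poly=0.0, N_fil=0.0,
            mean_len=float("nan"), frac_poly=0.0, a=0.0, kcat_obs=0.0,
        )

    if not params.polymerizing:
        b = E_tot / P_f
        a = b * (cond.U / params.K_uf) / E_tot
        return EquilibriumState(
            b=b, f=E_tot, z=0.0, M_poly=0.0, N_fil=0.0,
            mean_len=float("nan"), frac_poly=0.0, a=a,
            kcat_obs=params.k_max * a,
        )

    K_e, sigma = params.K_e, params.sigma

    def balance(b: float) -> float:
        z = b * P_p / K_e
        return b * P_f + _polymer_mass(z, K_e, sigma) - E_tot

    b_hi = min(E_tot / P_f, (K_e / P_p) * (1.0 - _Z_GUARD))
    # balance(0) = -E_tot < 0; balance(b_hi) >= 0 up to rounding: either
    # b_hi*P_f = E_tot already, or z ~ 1 makes M_poly enormous.
    bal_hi = balance(b_hi)
    if bal_hi <= 0.0:
        if bal_hi >= -1e-9 * max(E_tot, 1.0):
            # polymer term underflowed and b_hi*P_f - E_tot rounded an ulp
            # below 0: the root is the bracket edge, polymer negligible
            b = b_hi
        else:
            # sigma so small that the mass-balance knee is narrower than
            # machine epsilon in z: the free pool pins at the critical
            # value b = K_e/P_p and the excess sits in (very few, very
            # long) filaments.  1 - z is computed analytically to keep
            # the filament statistics finite.
            b = K_e / P_p
            M_poly = E_tot - b * P_f
            d = math.sqrt(K_e * sigma / M_poly)  # = 1 - z
            f = E_tot - M_poly
            a = b * (cond.U / params.K_uf) / E_tot
            return EquilibriumState(
                b=b, f=f, z=min(1.0 - d, _Z_MAX), M_poly=M_poly,
                N_fil=M_poly * d / (1.0 + d) if d > 0 else 0.0,
                mean_len=(1.0 + d) / d if d > 0 else float("inf"),
                frac_poly=M_poly / E_tot, a=a, kcat_obs=params.k_max * a,
            )
    else:
        try:
            b = brentq(balance, 0.0, b_hi, rtol=_RTOL, maxiter=_MAX_ITER)
        except (RuntimeError, ValueError) as exc:
            raise SolverError(
                f"equilibrium root-finding failed for {cond}: {exc}",
                bracket=(0.0, b_hi),
                residuals=(balance(0.0), balance(b_hi)),
            ) from exc

    z = b * P_p / K_e
    M_poly = _polymer_mass(z, K_e, sigma)
    N_fil = _polymer_number(z, K_e, sigma)
    f = E_tot - M_poly  # exact complement keeps mass balance to rounding
    a = b * (cond.U / params.K_uf) / E_tot
    mean_len = (2.0 - z) / (1.0 - z) if M_poly > 0.0 else float("nan")
    return EquilibriumState(
        b=b, f=f, z=z, M_poly=M_poly, N_fil=N_fil,
        mean_len=mean_len, frac_poly=M_poly / E_tot, a=a,
        kcat_obs=params.k_max * a,
    )


def filament_length_distribution(
    state: EquilibriumState, params: ThermoParams, n_max: int
) -> np.ndarray:
    """Filament concentrations c_n = K_e*sigma*z^n for n = 2..n_max.

    Returns a structured view as an (m, 2) array of (n, c_n) rows;
    successive ratios c_{n+1}/c_n equal z exactly (geometric law).
    Empty for a nonpolymerizing or polymer-free state.
    """
    if n_max < 2:
        raise ValueError(f"n_max must be >= 2, got {n_max}")
    if not params.polymerizing or state.M_poly == 0.0:
        return np.empty((0, 2))
    n = np.arange(2, n_max + 1, dtype=float)
    c_n = params.K_e * params.sigma * state.z ** n
    return np.column_stack([n, c_n])


def mean_filament_length(state: EquilibriumState) -> float:
    """Mean filament length (2-z)/(1-z) in tetramers; needs polymer present."""
    if not (state.M_poly > 0.0):
        raise ValueError("mean filament length undefined: no polymer mass")
    return (2.0 - state.z) / (1.0 - state.z)
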