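"""Dose–response curves and their summaries.

Generates model response curves (specific activity vs enzyme, velocity
vs CTP), extracts IC50 by the flanking-point linear-interpolation rule,
locates the half-maximal enzyme concentration [CtpS]_0.5, computes
Goldbeter–Koshland response coefficients R = C_10/C_90, and builds the
four-mechanism comparison (competitive/noncompetitive × polymerizing/
nonpolymerizing) of normalized active fraction vs CTP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibrium import solve_equilibrium, SolverError
from .params import Conditions, ThermoParams

#: default search ceiling for the half-maximal enzyme concentration, μM
E_MAX_DEFAULT = 100.0
#: points used for dense log-spaced evaluations
DENSE_GRID_POINTS = 400


class RangeError(ValueError):
    """The requested crossing lies outside the evaluated grid."""


class AmbiguityError(ValueError):
    """Multiple crossings found; carries every crossing location."""

    def __init__(self, msg: str, crossings):
        super().__init__(msg)
        self.crossings = list(crossings)


@dataclass(frozen=True)
class DoseResponseCurve:
    """A sampled model response along one swept concentration axis.

    ``swept_variable`` is "CTP" or "E_tot"; ``x`` is strictly increasing
    (μM); ``y`` holds kcat_obs (s⁻¹), velocity (μM/s) or a normalized
    active fraction depending on ``normalization`` ("none",
    "to_zero_dose" or "to_max").  ``fixed_conditions`` carries the
    non-swept concentrations.
    """

    swept_variable: str
    x: np.ndarray
    y: np.ndarray
    fixed_conditions: dict
    params_id: str = ""
    normalization: str = "none"

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(x) and np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(~np.isfinite(y)) or np.any(y < 0):
            raise ValueError("y must be finite and >= 0")

    def normalized_to_zero_dose(self) -> "DoseResponseCurve":
        """Rescale y to its value at the smallest x (the v_i/v_o convention)."""
        if self.y[0] == 0:
            raise ValueError("zero-dose response is 0; cannot normalize")
        return DoseResponseCurve(
            self.swept_variable, self.x, self.y / self.y[0],
            self.fixed_conditions, self.params_id, "to_zero_dose",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"swept": self.swept_variable, "x_uM": self.x, "y": self.y,
             "normalized": self.normalization}
        )


def titration_curve(
    params: ThermoParams, U: float, C: float, E_grid
) -> DoseResponseCurve:
    """Apparent specific activity kcat_obs vs total enzyme concentration."""
    E_grid = np.asarray(E_grid, dtype=float)
    if E_grid.size < 3 or np.any(np.diff(E_grid) <= 0):
        raise ValueError("E_grid must be increasing with >= 3 points")
    y = np.empty_like(E_grid)
    for i, E in enumerate(E_grid):
        try:
            y[i] = solve_equilibrium(params, Conditions(U=U, C=C, E_tot=E)).kcat_obs
        except SolverError as exc:
            raise SolverError(f"titration failed at E_tot = {E} μM: {exc}") from exc
    return DoseResponseCurve("E_tot", E_grid, y, {"U": U, "C": C})


def inhibition_curve(
    params: ThermoParams, E_tot: float, U: float, C_grid, normalization: str = "none"
) -> DoseResponseCurve:
    """Velocity v = kcat_obs * E_tot vs CTP at fixed enzyme and UTP.

    With ``normalization="to_zero_dose"`` the curve is rescaled to its
    zero-CTP value (requires C_grid[0] == 0), matching the assay's
    v_i/v_o convention.
    """
    C_grid = np.asarray(C_grid, dtype=float)
    if C_grid.size and np.any(np.diff(C_grid) <= 0):
        raise ValueError("C_grid must be strictly increasing")
    y = np.empty_like(C_grid)
    for i, C in enumerate(C_grid):
        try:
            st = solve_equilibrium(params, Conditions(U=U, C=C, E_tot=E_tot))
        except SolverError as exc:
            raise SolverError(f"inhibition failed at C = {C} μM: {exc}") from exc
        y[i] = st.kcat_obs * E_tot
    curve = DoseResponseCurve("CTP", C_grid, y, {"U": U, "E_tot": E_tot})
    if normalization == "to_zero_dose":
        if C_grid[0] != 0.0:
            raise ValueError("to_zero_dose normalization requires C_grid[0] == 0")
        curve = curve.normalized_to_zero_dose()
    return curve


def ic50(curve: DoseResponseCurve) -> float:
    """IC50 by linear interpolation between the points flanking y = 1/2.

    The curve must sweep CTP and be normalized so the zero-dose response
    is 1; an exact grid hit is returned as-is.  Raises RangeError if the
    curve never crosses one half, and AmbiguityError (carrying every
    crossing) if it crosses more than once.
    """
    if curve.swept_variable != "CTP":
        raise ValueError("ic50 requires a curve swept in CTP")
    x, y = curve.x, curve.y
    if abs(y[0] - 1.0) > 1e-9:
        raise ValueError("curve must be normalized to its zero-dose response")

    exact = np.flatnonzero(y == 0.5)
    d = y - 0.5
    flank = np.flatnonzero(d[:-1] * d[1:] < 0)
    crossings = [float(x[i]) for i in exact] + [
        float(x[i] + (0.5 - y[i]) * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))
        for i in flank
    ]
    if not crossings:
        raise RangeError(
            "response never crosses one half on the grid; extend the CTP grid"
        )
    if len(crossings) > 1:
        raise AmbiguityError(
            f"non-monotone response: {len(crossings)} half-crossings", sorted(crossings)
        )
    return crossings[0]


def ctps_half(
    params: ThermoParams, U: float, C: float, E_max: float = E_MAX_DEFAULT
) -> float:
    """Enzyme concentration where kcat_obs falls to half its maximum.

    The maximum of kcat_obs over E_tot in (0, E_max] is taken on a dense
    log grid (for a polymerizing enzyme it sits at the dilute end, where
    no polymer forms); the half-crossing is then bracketed and solved by
    Brent's method.  Raises RangeError when no crossing exists below
    E_max and ValueError for a nonpolymerizing enzyme, whose specific
    activity does not depend on E_tot.
    """
    if not params.polymerizing:
        raise ValueError("ctps_half undefined: kcat_obs is E_tot-independent "
                         "for a nonpolymerizing enzyme")
    grid = np.logspace(-4, np.log10(E_max), DENSE_GRID_POINTS)

    def kc(E: float) -> float:
        return solve_equilibrium(params, Conditions(U=U, C=C, E_tot=E)).kcat_obs

    vals = np.array([kc(E) for E in grid])
    k_top = vals.max()
    if k_top <= 0:
        raise RangeError("specific activity is zero everywhere; no half-point")
    half = 0.5 * k_top
    below = np.flatnonzero(vals < half)
    if below.size == 0:
        raise RangeError(f"kcat_obs never falls below half-maximum up to {E_max} μM")
    j = below[0]
    if j == 0:
        raise RangeError("response already below half-maximum at the dilute end")
    return brentq(lambda E: kc(E) - half, grid[j - 1], grid[j], rtol=1e-10)


def _active_fraction_ratio(params: ThermoParams, E_tot: float, U: float):
    """Return a(C)/a(0) as a callable in C, with a(0) precomputed."""
    a0 = solve_equilibrium(params, Conditions(U=U, C=0.0, E_tot=E_tot)).a
    if a0 <= 0:
        raise ValueError("zero-CTP active fraction is 0; response undefined")

    def ratio(C: float) -> float:
        return solve_equilibrium(params, Conditions(U=U, C=C, E_tot=E_tot)).a / a0

    return ratio


def _quantile_dose(ratio, q: float, C_lo: float, C_hi: float) -> float:
    """CTP concentration where the normalized response equals q (0<q<1)."""
    # dense log-grid bracketing, then bisection-style refinement
    grid = np.logspace(np.log10(C_lo), np.log10(C_hi), DENSE_GRID_POINTS)
    vals = np.array([ratio(C) for C in grid])
    below = np.flatnonzero(vals <= q)
    if below.size == 0:
        raise RangeError(f"normalized response never reaches {q} below {C_hi} μM")
    j = below[0]
    if j == 0:
        raise RangeError(f"normalized response already below {q} at {C_lo} μM")
    # tight so the 90/10 dose ratio built from two quantiles keeps ~1e-9
    return brentq(lambda C: ratio(C) - q, grid[j - 1], grid[j], rtol=1e-12)


def response_coefficient(params: ThermoParams, E_tot: float, U: float) -> float:
    """Goldbeter–Koshland response coefficient R = C_10 / C_90.

    C_q is the CTP concentration at which the active fraction falls to
    q% of its zero-CTP value.  R = 81 for a Michaelian (hyperbolic)
    inhibition curve; R < 81 marks an ultrasensitive switch.
    """
    ratio = _active_fraction_ratio(params, E_tot, U)
    C_lo = 1e-6 * min(params.K_cf, params.K_cp)
    C_hi = 1e8 * max(params.K_cf, params.K_cp)
    C90 = _quantile_dose(ratio, 0.9, C_lo, C_hi)
    C10 = _quantile_dose(ratio, 0.1, C_lo, C_hi)
    return C10 / C90


MECHANISM_VARIANTS = (
    ("competitive_polymerizing", "competitive", True),
    ("noncompetitive_polymerizing", "noncompetitive", True),
    ("competitive_nonpolymerizing", "competitive", False),
    ("noncompetitive_nonpolymerizing", "noncompetitive", False),
)


def compare_mechanisms(
    base_params: ThermoParams, E_tot: float, C_grid
) -> pd.DataFrame:
    """Normalized active fraction a(C)/a(0) for four inhibition mechanisms.

    Evaluates competitive/noncompetitive inhibition with and without
    polymerization at shared dissociation constants, at a fixed UTP
    concentration equal to K_cp.  Returns a long-format frame with
    columns (mechanism, C_uM, a_norm).
    """
    C_grid = np.asarray(C_grid, dtype=float)
    U = base_params.K_cp
    rows = []
    for label, mech, poly in MECHANISM_VARIANTS:
        p = base_params.replace(mechanism=mech, polymerizing=poly)
        ratio = _active_fraction_ratio(p, E_tot, U)
        for C in C_grid:
            rows.append({"mechanism": label, "C_uM": C, "a_norm": ratio(C)})
    return pd.DataFrame(rows)
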