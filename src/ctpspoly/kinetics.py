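"""Coupled CTP-synthesis / polymerization time courses.

A phenomenological kinetic closure of the equilibrium model for the
fluorometer assay: synthesis converts UTP to CTP 1:1 at rate
v = k_max * [free, UTP-bound tetramer], while the polymer mass relaxes
toward its instantaneous equilibrium value on a single timescale
tau_poly (measured disassembly/reassembly happens within seconds).
Scripted events (substrate additions, glutamine-analog inactivation as
a k_max jump) are applied as state discontinuities.  Light-scattering
and transmittance proxies are emitted in arbitrary units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .equilibrium import solve_equilibrium
from .params import Conditions, ThermoParams

#: transmittance decay scale, μM CTP (arbitrary-unit convention)
C_REF_UM = 500.0
#: default polymer relaxation timescale, s
TAU_POLY_DEFAULT = 2.0

EVENT_KINDS = ("add_UTP", "add_ATP", "set_kmax")


@dataclass(frozen=True)
class Event:
    """A scripted perturbation: (time s, kind, magnitude).

    ``add_UTP`` adds the magnitude (μM) to U instantaneously; ``add_ATP``
    is a recorded no-op (ATP is saturating and untracked); ``set_kmax``
    replaces the catalytic rate (used to model covalent inactivation).
    """

    time: float
    kind: str
    magnitude: float = 0.0

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")


@dataclass(frozen=True)
class EventScript:
    """Ordered events within the simulation horizon."""

    events: tuple = ()

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    def within(self, horizon: float) -> tuple:
        if self.events and self.events[-1].time >= horizon:
            raise ValueError("event times must lie within the horizon")
        return self.events


@dataclass(frozen=True)
class AssayTimeCourse:
    """Simulated assay trace sampled on a uniform output grid.

    All concentration channels in μM; ``scatter`` and ``trans`` are
    arbitrary-unit proxies for right-angle light scattering
    (polymer mass × mean filament length, a second-moment-like weight)
    and 291 nm transmittance (exp(-C/C_ref), falling as CTP accumulates).
    """

    t: np.ndarray
    U: np.ndarray
    C: np.ndarray
    M: np.ndarray
    v: np.ndarray
    scatter: np.ndarray
    trans: np.ndarray
    E_tot: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t, "U_uM": self.U, "C_uM": self.C, "M_uM": self.M,
            "v_uM_per_s": self.v, "scatter_au": self.scatter,
            "trans_au": self.trans,
        })


def _rate(params: ThermoParams, U: float, C: float, M: float, E_tot: float,
          k_max: float) -> float:
    """Synthesis rate from the instantaneous free pool f = E_tot - M.

    The free pool is re-partitioned across ligation states with the
    free-tetramer binding polynomial; only the UTP-bound, CTP-free
    species turns over.
    """
    f = max(E_tot - M, 0.0)
    from .equilibrium import binding_polynomials
    P_f, _ = binding_polynomials(params, Conditions(U=U, C=C, E_tot=E_tot))
    b = f / P_f
    return k_max * b * (U / params.K_uf)


def simulate_assay(
    params: ThermoParams,
    cond0: Conditions,
    tau_poly: float = TAU_POLY_DEFAULT,
    horizon: float = 1200.0,
    events: EventScript = EventScript(),
    dt_out: float = 1.0,
    M0: float | None = None,
    scatter_proxy: str = "mass_x_length",
    rtol: float = 1e-8,
) -> AssayTimeCourse:
    """Integrate dU/dt = -v, dC/dt = +v, dM/dt = (M_eq - M)/tau_poly.

    ``M_eq(U, C)`` is the equilibrium polymer mass at the instantaneous
    ligand concentrations (clamped-total enzyme), so polymerization is a
    single-timescale relaxation to the equilibrium manifold.  Events are
    applied as jumps between integration segments.  ``M0`` defaults to
    the initial equilibrium polymer mass.  ``scatter_proxy`` is
    "mass_x_length" (Rayleigh-like) or "mass".

    Between events U + C is conserved exactly (1:1 UTP → CTP); the model
    tracks neither ATP nor glutamine (saturating).
    """
    if tau_poly <= 0:
        raise ValueError("tau_poly must be positive")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if scatter_proxy not in ("mass_x_length", "mass"):
        raise ValueError(f"unknown scatter proxy {scatter_proxy!r}")

    E_tot = cond0.E_tot
    k_max_now = params.k_max

    def M_eq(U: float, C: float) -> float:
        return solve_equilibrium(
            params, Conditions(U=max(U, 0.0), C=max(C, 0.0), E_tot=E_tot)
        ).M_poly

    def rhs(_t, y, k_max):
        U, C, M = y
        if U < 0 or C < 0 or M < 0:  # integrator overshoot; clip in-RHS
            U, C, M = max(U, 0.0), max(C, 0.0), max(M, 0.0)
        v = _rate(params, U, C, M, E_tot, k_max)
        return [-v, v, (M_eq(U, C) - M) / tau_poly]

    if M0 is None:
        M0 = M_eq(cond0.U, cond0.C)
    state = np.array([cond0.U, cond0.C, float(M0)])

    breakpoints = [0.0] + [e.time for e in events.within(horizon)] + [horizon]
    ev_iter = list(events.within(horizon))
    t_out = np.arange(0.0, horizon + 0.5 * dt_out, dt_out)
    t_out = t_out[t_out <= horizon]

    ts, ys, ks = [], [], []
    for seg in range(len(breakpoints) - 1):
        t0, t1 = breakpoints[seg], breakpoints[seg + 1]
        mask = (t_out >= t0) & (t_out < t1) if seg < len(breakpoints) - 2 else (
            (t_out >= t0) & (t_out <= t1))
        t_eval = t_out[mask]
        # integrate through t1 so the segment-end state comes for free
        t_all = np.unique(np.append(t_eval, t1))
        sol = solve_ivp(rhs, (t0, t1), state, method="LSODA", rtol=rtol,
                        atol=1e-10, dense_output=False, t_eval=t_all,
                        args=(k_max_now,))
        if not sol.success:
            raise RuntimeError(
                f"integrator failed in [{t0}, {t1}] s: {sol.message}; "
                f"last state {state}")
        keep = np.isin(sol.t, t_eval)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        ks.extend([k_max_now] * int(keep.sum()))
        state = sol.y[:, -1].copy()
        if np.any(state < 0):
            warnings.warn("negative state clipped to 0 after segment", UserWarning)
            state = np.clip(state, 0.0, None)
        if seg < len(ev_iter):
            e = ev_iter[seg]
            if e.kind == "add_UTP":
                state[0] += e.magnitude
            elif e.kind == "set_kmax":
                k_max_now = e.magnitude
            # add_ATP: recorded no-op

    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    k_arr = np.asarray(ks)
    U_t = np.clip(Y[0], 0.0, None)
    C_t = np.clip(Y[1], 0.0, None)
    M_t = np.clip(Y[2], 0.0, None)
    v_t = np.array([
        _rate(params, u, c, m, E_tot, k)
        for u, c, m, k in zip(U_t, C_t, M_t, k_arr)
    ])
    if scatter_proxy == "mass_x_length":
        mean_len = np.array([
            _equilibrium_mean_len(params, u, c, E_tot) for u, c in zip(U_t, C_t)
        ])
        scatter = M_t * mean_len
    else:
        scatter = M_t.copy()
    trans = np.exp(-C_t / C_REF_UM)
    return AssayTimeCourse(t=t, U=U_t, C=C_t, M=M_t, v=v_t, scatter=scatter,
                           trans=trans, E_tot=E_tot)


def _equilibrium_mean_len(params: ThermoParams, U: float, C: float,
                          E_tot: float) -> float:
    st = solve_equilibrium(params, Conditions(U=U, C=C, E_tot=E_tot))
    return st.mean_len if st.M_poly > 0 else 0.0
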