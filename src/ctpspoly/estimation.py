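"""Parameter estimation: nucleation barrier, anchored defaults, assay fits.

Three layers:

* :func:`estimate_nucleation_energy` inverts the equilibrium model to
  read the nucleation barrier off an observed mean filament length.
* :func:`calibrate_defaults` produces the package's default parameter
  set by solving the model against published wild-type anchors (IC50 at
  dilute enzyme, the half-maximal enzyme concentration with and without
  CTP) by nested 1-D root-finding; the result is deterministic.
* :func:`fit_parameters` least-squares-fits free parameters to assay
  tables (synthetic or user-provided) with multi-start in log space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .dose_response import AmbiguityError, RangeError, ctps_half, ic50, inhibition_curve
from .equilibrium import binding_polynomials, solve_equilibrium
from .params import Conditions, ThermoParams

__all__ = [
    "estimate_nucleation_energy",
    "calibrate_defaults",
    "default_params",
    "fit_parameters",
    "FitResult",
    "NegativeBarrierWarning",
    "CalibrationError",
]


class NegativeBarrierWarning(UserWarning):
    """Implied nucleation factor sigma > 1, i.e. a negative barrier."""


class CalibrationError(RuntimeError):
    """A calibration anchor could not be bracketed."""


class InconsistentLengthError(ValueError):
    """Observed mean length incompatible with the total concentration."""


# ---------------------------------------------------------------------------
# nucleation barrier from mean filament length
# ---------------------------------------------------------------------------

def estimate_nucleation_energy(
    mean_len_obs: float, cond: Conditions, params: ThermoParams
) -> float:
    """Invert the model: nucleation barrier (k_B·T) from mean polymer length.

    The mean length fixes the subunit weight, z = (L-2)/(L-1); z fixes
    the reference species b = z*K_e/P_p and hence the free pool
    f = b*P_f; the polymer mass follows by difference from E_tot; and
    the nucleation factor is whatever sigma makes the closed-form
    polymer mass match:

        sigma = M_poly (1-z)^2 / (K_e z^2 (2-z)),   E_nuc = -ln sigma.

    The ``E_nuc`` field of ``params`` is ignored.  Raises
    InconsistentLengthError when the implied free pool already exceeds
    E_tot; warns (and returns the negative value) when sigma > 1.
    """
    if not mean_len_obs > 2.0:
        raise ValueError(f"mean filament length must exceed 2 tetramers, got {mean_len_obs}")
    if not cond.E_tot > 0.0:
        raise ValueError("E_tot must be positive")
    P_f, P_p = binding_polynomials(params, cond)
    z = (mean_len_obs - 2.0) / (mean_len_obs - 1.0)
    b = z * params.K_e / P_p
    f = b * P_f
    M_poly = cond.E_tot - f
    if M_poly <= 0.0:
        raise InconsistentLengthError(
            f"observed length incompatible with total concentration: implied free "
            f"pool {f:.4g} μM >= E_tot {cond.E_tot:.4g} μM"
        )
    sigma = M_poly * (1.0 - z) ** 2 / (params.K_e * z * z * (2.0 - z))
    if sigma > 1.0 + 1e-9:  # tolerance: exact zero-barrier round trips
        warnings.warn(
            f"implied sigma = {sigma:.4g} > 1: negative nucleation barrier",
            NegativeBarrierWarning,
            stacklevel=2,
        )
    return -math.log(sigma)


# ---------------------------------------------------------------------------
# anchored default calibration
# ---------------------------------------------------------------------------

#: published wild-type anchors, all under the standard assay (600 μM UTP)
IC50_ANCHOR_UM = 360.0       #: CTP IC50 at 0.2 μM enzyme, μM
IC50_ANCHOR_E_TOT = 0.2      #: enzyme concentration of the IC50 anchor, μM
HALF_POINT_C0_UM = 3.3       #: [CtpS]_0.5 at zero CTP, μM
HALF_POINT_C800_UM = 1.4     #: [CtpS]_0.5 at 800 μM CTP, μM
KCAT_MAX_OBS = 6.7           #: maximal observed specific activity, s⁻¹
ASSAY_UTP_UM = 600.0         #: assay UTP concentration, μM
E_NUC_DEFAULT = 9.0          #: nucleation barrier pinned at its length-based estimate
K_UF_DEFAULT = 600.0         #: UTP/free-tetramer dissociation constant default, μM

_CAL_RTOL = 1e-8
_IC50_GRID = None  # built lazily


def _ic50_grid() -> np.ndarray:
    global _IC50_GRID
    if _IC50_GRID is None:
        _IC50_GRID = np.concatenate([[0.0], np.logspace(-2.0, 5.0, 300)])
    return _IC50_GRID


def _model_ic50(params: ThermoParams, E_tot: float, U: float) -> float:
    curve = inhibition_curve(params, E_tot=E_tot, U=U, C_grid=_ic50_grid(),
                             normalization="to_zero_dose")
    return ic50(curve)


def _bracketed_root(fn, grid, target, label):
    """Scan a grid for a sign change of fn-target.

    Grid points where fn is undefined (no crossing in range, ambiguous
    crossing, or a nested calibration failure) are skipped; the root is
    then refined between the bracketing evaluable points.
    """
    lo = hi = None
    for x in grid:
        try:
            v = fn(x) - target
        except (RangeError, AmbiguityError, CalibrationError):
            continue
        if v == 0.0:
            return x
        if v < 0.0:
            lo, f_lo = x, v
        elif lo is not None:
            hi = x
            break
    if lo is None or hi is None:
        raise CalibrationError(
            f"could not bracket {label}: no sign change of the residual on the scan grid"
        )
    return brentq(lambda x: fn(x) - target, lo, hi, rtol=_CAL_RTOL)


@lru_cache(maxsize=8)
def calibrate_defaults(
    E_nuc: float = E_NUC_DEFAULT, K_uf: float = K_UF_DEFAULT
) -> ThermoParams:
    """Competitive polymerizing parameters anchored to the wild-type assays.

    The calibration pins ``E_nuc`` (default 9 k_B·T, the length-based
    estimate) and ``K_uf`` (default 600 μM) and solves the remaining
    constants against three printed anchors, each by bracketed 1-D
    root-finding to relative 1e-8:

    1. ``K_e`` from the zero-CTP half-maximal enzyme concentration
       (3.3 μM) — at zero CTP this anchor involves neither K_cf nor K_cp.
    2. ``(K_cf, K_cp)`` by nested root-finding: for each trial K_cp the
       inner loop re-solves K_cf so the model CTP IC50 at 0.2 μM enzyme
       equals 360 μM; the outer loop moves K_cp until the half-maximal
       enzyme concentration at 800 μM CTP equals 1.4 μM.  The solution
       satisfies K_cp < K_cf (CTP binds the filament more tightly).
    3. ``k_max`` in closed form so the dilute-limit specific activity at
       assay UTP equals the observed maximum of 6.7 s⁻¹.

    Deterministic: repeated calls are bit-identical (and cached).
    """
    U = ASSAY_UTP_UM
    probe = dict(K_uf=K_uf, E_nuc=E_nuc, k_max=1.0, mechanism="competitive",
                 polymerizing=True)

    # 1. K_e from the zero-CTP half point (K_cf/K_cp placeholders inert at C=0)
    def half0(K_e: float) -> float:
        p = ThermoParams(K_cf=1e3, K_cp=999.0, K_e=K_e, **probe)
        return ctps_half(p, U=U, C=0.0)

    K_e = _bracketed_root(half0, np.logspace(-3, 2, 40), HALF_POINT_C0_UM,
                          "K_e against the zero-CTP half point")

    # 2. nested (K_cp outer, K_cf inner)
    def K_cf_given(K_cp: float) -> float:
        def anchor(K_cf: float) -> float:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # trial K_cp may exceed K_cf
                p = ThermoParams(K_cf=K_cf, K_cp=K_cp, K_e=K_e, **probe)
            return _model_ic50(p, IC50_ANCHOR_E_TOT, U)
        return _bracketed_root(anchor, np.logspace(0, 5, 40), IC50_ANCHOR_UM,
                               "K_cf against the IC50 anchor")

    def half800(K_cp: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = ThermoParams(K_cf=K_cf_given(K_cp), K_cp=K_cp, K_e=K_e, **probe)
        return ctps_half(p, U=U, C=800.0)

    K_cp = _bracketed_root(half800, np.logspace(0, 4, 40), HALF_POINT_C800_UM,
                           "K_cp against the 800 μM CTP half point")
    K_cf = K_cf_given(K_cp)

    # 3. k_max: dilute limit kcat_obs -> k_max * (U/K_uf)/P_f at C = 0
    a_dilute = (U / K_uf) / (1.0 + U / K_uf)
    k_max = KCAT_MAX_OBS / a_dilute

    return ThermoParams(K_uf=K_uf, K_cf=K_cf, K_cp=K_cp, K_e=K_e,
                        E_nuc=E_nuc, k_max=k_max)


@lru_cache(maxsize=1)
def default_params() -> ThermoParams:
    """The shipped calibrated default parameter set.

    Reads the frozen output of :func:`calibrate_defaults` from the
    package's default config file (fast); calibrate_defaults() itself
    recomputes the same numbers from the anchors.
    """
    import tomllib
    from importlib.resources import files

    doc = tomllib.loads(
        files("ctpspoly").joinpath("data/default_params.toml").read_text()
    )
    return ThermoParams(**doc["params"])


# ---------------------------------------------------------------------------
# assay-table fitting
# ---------------------------------------------------------------------------

#: box bounds for fitted parameters
K_BOUNDS_UM = (1e-4, 1e6)
E_NUC_BOUNDS = (0.0, 30.0)
_LOG_PARAMS = ("K_uf", "K_cf", "K_cp", "K_e", "k_max")
FITTABLE = _LOG_PARAMS + ("E_nuc",)


@dataclass
class FitResult:
    """Outcome of a multi-start least-squares fit."""

    params: ThermoParams
    loss: float
    n_points: int
    converged: bool
    n_restarts_used: int
    per_dataset_residuals: pd.DataFrame

    def report(self) -> pd.DataFrame:
        """Tidy (parameter, estimate, lower_bound_used, upper_bound_used) table."""
        rows = []
        for name in FITTABLE:
            lo, hi = (E_NUC_BOUNDS if name == "E_nuc" else K_BOUNDS_UM)
            rows.append({"parameter": name, "estimate": getattr(self.params, name),
                         "lower_bound_used": lo, "upper_bound_used": hi})
        return pd.DataFrame(rows)


def _predict(params: ThermoParams, dataset) -> np.ndarray:
    """Forward-model the observable of one dataset kind."""
    kind = dataset.kind
    design = dataset.design
    y = np.empty(len(design))
    for i, row in enumerate(design.itertuples(index=False)):
        cond = Conditions(U=getattr(row, "U_uM", 0.0), C=getattr(row, "C_uM", 0.0),
                          E_tot=row.E_tot_uM)
        st = solve_equilibrium(params, cond)
        if kind == "titration":
            y[i] = st.kcat_obs
        elif kind == "inhibition":
            y[i] = st.kcat_obs * cond.E_tot
        elif kind == "pellet":
            y[i] = st.frac_poly
        else:
            raise ValueError(f"cannot fit dataset kind {kind!r}")
    return y


def _pack(params: ThermoParams, free: list[str]) -> np.ndarray:
    x = []
    for name in free:
        v = getattr(params, name)
        x.append(math.log10(v) if name in _LOG_PARAMS else v)
    return np.asarray(x)


def _unpack(x: np.ndarray, free: list[str], base: ThermoParams) -> ThermoParams:
    changes = {}
    for name, v in zip(free, x):
        changes[name] = 10.0 ** v if name in _LOG_PARAMS else v
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # optimizer may cross K_cp >= K_cf
        return base.replace(**changes)


def _sensitivity_check(init: ThermoParams, free: list[str], datasets) -> None:
    """Warn when a free parameter moves no dataset (finite differences)."""
    base = [_predict(init, d) for d in datasets]
    for name in free:
        v = getattr(init, name)
        bumped = init.replace(**{name: v * 1.1 if name in _LOG_PARAMS else v + 0.5})
        moved = False
        for d, y0 in zip(datasets, base):
            y1 = _predict(bumped, d)
            if np.any(np.abs(y1 - y0) > 1e-9 * (np.abs(y0) + 1e-12)):
                moved = True
                break
        if not moved:
            warnings.warn(
                f"free parameter {name!r} does not influence any supplied dataset; "
                "it is structurally non-identifiable from this design",
                UserWarning,
                stacklevel=3,
            )


def fit_parameters(
    datasets,
    free,
    init: ThermoParams,
    n_restarts: int = 8,
    jitter_decades: float = 1.0,
    seed: int = 0,
    max_nfev: int = 400,
) -> FitResult:
    """Bound-constrained multi-start least-squares fit on log residuals.

    Minimizes sum over datasets of (log(y_obs + eps) - log(y_model + eps))^2
    with eps = 1e-6 of each dataset's observed median (assay responses
    span decades; the log loss weights them evenly).  Dissociation
    constants and k_max are fitted in log10 space within [1e-4, 1e6] μM,
    E_nuc linearly within [0, 30] k_B·T.  ``n_restarts`` starts jitter
    the K's log-uniformly ±``jitter_decades`` around ``init`` (E_nuc:
    uniform ±3 k_B·T, clipped); the best local optimum wins.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("at least one dataset is required")
    free = [f for f in FITTABLE if f in set(free)]
    if not free:
        raise ValueError("no recognised free parameters")
    _sensitivity_check(init, free, datasets)

    y_obs = [np.asarray(d.y_obs, dtype=float) for d in datasets]
    eps = [1e-6 * max(float(np.median(y)), 1e-30) for y in y_obs]
    log_obs = [np.log(y + e) for y, e in zip(y_obs, eps)]
    n_points = sum(len(y) for y in y_obs)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _unpack(x, free, init)
        out = []
        for d, lo, e in zip(datasets, log_obs, eps):
            out.append(np.log(_predict(p, d) + e) - lo)
        return np.concatenate(out)

    lo = np.array([E_NUC_BOUNDS[0] if f == "E_nuc" else math.log10(K_BOUNDS_UM[0])
                   for f in free])
    hi = np.array([E_NUC_BOUNDS[1] if f == "E_nuc" else math.log10(K_BOUNDS_UM[1])
                   for f in free])
    x0 = np.clip(_pack(init, free), lo, hi)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        jit = np.array([
            rng.uniform(-3.0, 3.0) if f == "E_nuc"
            else rng.uniform(-jitter_decades, jitter_decades)
            for f in free
        ])
        starts.append(np.clip(x0 + jit, lo, hi))

    best = None
    failures = []
    for x_start in starts:
        try:
            sol = least_squares(residuals, x_start, bounds=(lo, hi),
                                max_nfev=max_nfev, xtol=1e-12, ftol=1e-12,
                                gtol=1e-12)
        except Exception as exc:  # pragma: no cover - solver-internal failures
            failures.append(str(exc))
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"all {len(starts)} fit starts failed: {failures}")

    p_hat = _unpack(best.x, free, init)
    rows = []
    for k, d in enumerate(datasets):
        y_model = _predict(p_hat, d)
        for i in range(len(y_model)):
            rows.append({"dataset": k, "kind": d.kind, "index": i,
                         "y_obs": y_obs[k][i], "y_model": y_model[i],
                         "log_residual": math.log(y_obs[k][i] + eps[k])
                                         - math.log(y_model[i] + eps[k])})
    return FitResult(
        params=p_hat,
        loss=2.0 * best.cost,  # least_squares cost is 1/2 sum r^2
        n_points=n_points,
        converged=bool(best.status > 0),
        n_restarts_used=len(starts),
        per_dataset_residuals=pd.DataFrame(rows),
    )
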