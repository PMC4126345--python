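"""Seeded synthetic assay datasets.

Generators emulating the statistical structure of the four biochemical
assays the model describes: enzyme-titration specific activity,
CTP-inhibition velocity, sedimentation pellet fraction, and fluorometer
time courses.  Rate-like observables carry multiplicative lognormal
noise (positive, heteroscedastic — standard enzymology practice);
pellet fractions carry additive Gaussian noise truncated to [0, 1].
Every generator is a pure function of (params, design, noise, seed):
the same seed reproduces the same table bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibrium import solve_equilibrium
from .kinetics import AssayTimeCourse, EventScript, simulate_assay
from .params import Conditions, ThermoParams

#: default enzyme-titration design: 0.05–10 μM, log-spaced (the assay's range)
TITRATION_E_GRID = tuple(np.geomspace(0.05, 10.0, 12))
#: default CTP-inhibition design: 0 plus 0.1 μM–10 mM, log-spaced
INHIBITION_C_GRID = (0.0,) + tuple(np.geomspace(0.1, 1e4, 12))

_GENERATOR_ALGORITHM = "numpy.random.default_rng/PCG64"


@dataclass(frozen=True)
class SyntheticDataset:
    """A seeded noisy assay table plus its exact forward-model truth.

    ``design`` holds the swept variable and fixed conditions, one row
    per observation, with concentration columns in μM.  ``y_true`` is
    the noise-free forward model; ``y_obs`` the noisy observable.
    ``noise_model`` records the noise family, its scale, the seed and
    the RNG algorithm so reproducibility is pinned to (seed, algorithm).
    """

    kind: str
    design: pd.DataFrame
    y_true: np.ndarray
    y_obs: np.ndarray
    noise_model: dict
    seed: int

    def to_frame(self) -> pd.DataFrame:
        out = self.design.copy()
        out["y_true"] = self.y_true
        out["y_obs"] = self.y_obs
        return out


def _lognormal_obs(y_true: np.ndarray, cv: float, seed: int) -> np.ndarray:
    """y_obs = y_true * exp(eta), eta ~ N(0, cv), i.i.d."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0.0:
        return y_true.copy()
    rng = np.random.default_rng(seed)
    return y_true * np.exp(rng.normal(0.0, cv, size=y_true.shape))


def gen_titration(
    params: ThermoParams, U: float, C: float, E_grid=None, cv: float = 0.05,
    seed: int = 0,
) -> SyntheticDataset:
    """Specific activity (kcat_obs, s⁻¹) vs total enzyme, lognormal noise."""
    E_grid = np.asarray(TITRATION_E_GRID if E_grid is None else E_grid, float)
    design = pd.DataFrame({"E_tot_uM": E_grid, "U_uM": U, "C_uM": C})
    y_true = np.array([
        solve_equilibrium(params, Conditions(U=U, C=C, E_tot=E)).kcat_obs
        for E in E_grid
    ])
    return SyntheticDataset(
        kind="titration", design=design, y_true=y_true,
        y_obs=_lognormal_obs(y_true, cv, seed),
        noise_model={"family": "lognormal", "cv": cv, "seed": seed,
                     "algorithm": _GENERATOR_ALGORITHM},
        seed=seed,
    )


def gen_inhibition(
    params: ThermoParams, E_tot: float, U: float, C_grid=None, cv: float = 0.05,
    seed: int = 0,
) -> SyntheticDataset:
    """Velocity (μM/s) vs CTP at fixed enzyme and UTP, lognormal noise."""
    C_grid = np.asarray(INHIBITION_C_GRID if C_grid is None else C_grid, float)
    design = pd.DataFrame({"C_uM": C_grid, "U_uM": U, "E_tot_uM": E_tot})
    y_true = np.array([
        solve_equilibrium(params, Conditions(U=U, C=C, E_tot=E_tot)).kcat_obs * E_tot
        for C in C_grid
    ])
    return SyntheticDataset(
        kind="inhibition", design=design, y_true=y_true,
        y_obs=_lognormal_obs(y_true, cv, seed),
        noise_model={"family": "lognormal", "cv": cv, "seed": seed,
                     "algorithm": _GENERATOR_ALGORITHM},
        seed=seed,
    )


def gen_pellet(
    params: ThermoParams, E_tot: float, C_grid=None, sd_abs: float = 0.05,
    seed: int = 0, U: float = 0.0,
) -> SyntheticDataset:
    """Pellet (polymer) fraction vs CTP; additive noise truncated to [0, 1]."""
    if sd_abs < 0:
        raise ValueError("sd_abs must be >= 0")
    C_grid = np.asarray(INHIBITION_C_GRID if C_grid is None else C_grid, float)
    design = pd.DataFrame({"C_uM": C_grid, "U_uM": U, "E_tot_uM": E_tot})
    y_true = np.array([
        solve_equilibrium(params, Conditions(U=U, C=C, E_tot=E_tot)).frac_poly
        for C in C_grid
    ])
    if sd_abs == 0.0:
        y_obs = y_true.copy()
    else:
        rng = np.random.default_rng(seed)
        y_obs = np.clip(y_true + rng.normal(0.0, sd_abs, size=y_true.shape),
                        0.0, 1.0)
    return SyntheticDataset(
        kind="pellet", design=design, y_true=y_true, y_obs=y_obs,
        noise_model={"family": "truncated_gaussian", "sd_abs": sd_abs,
                     "seed": seed, "algorithm": _GENERATOR_ALGORITHM},
        seed=seed,
    )


def gen_timecourse(
    params: ThermoParams, cond0: Conditions, cv: float = 0.05, seed: int = 0,
    events: EventScript = EventScript(), horizon: float = 1200.0,
    dt_out: float = 5.0, tau_poly: float = 2.0,
) -> SyntheticDataset:
    """Noisy fluorometer trace: lognormal noise on scatter and trans channels.

    ``y_true``/``y_obs`` are stacked (scatter, trans) columns; the full
    noise-free trajectory is kept in the design table.
    """
    tc = simulate_assay(params, cond0, tau_poly=tau_poly, horizon=horizon,
                        events=events, dt_out=dt_out)
    design = tc.to_frame()
    y_true = np.column_stack([tc.scatter, tc.trans]).ravel()
    y_obs = _lognormal_obs(y_true, cv, seed)
    return SyntheticDataset(
        kind="timecourse", design=design, y_true=y_true, y_obs=y_obs,
        noise_model={"family": "lognormal", "cv": cv, "seed": seed,
                     "channels": ["scatter_au", "trans_au"],
                     "algorithm": _GENERATOR_ALGORITHM},
        seed=seed,
    )


#: enzyme concentrations of the recovery design's inhibition series, μM —
#: spanning the window where CTP switches polymerization on, which is where
#: the observables are sensitive to the nucleation barrier
RECOVERY_WINDOW_E_UM = tuple(np.round(np.geomspace(0.55, 1.6, 14), 3))
#: CTP grid of the window inhibition curves, μM
RECOVERY_WINDOW_C_GRID = (0.0,) + tuple(np.geomspace(30.0, 1e4, 29))


def recovery_design(params: ThermoParams, U: float = 600.0, cv: float = 0.05,
                    base_seed: int = 0) -> list:
    """The parameter-recovery study design: one seeded replicate.

    Mirrors the assay set the model is calibrated against, sized so the
    nucleation barrier is statistically identifiable at the given noise
    level: an enzyme titration at zero CTP, CTP-inhibition curves at
    dilute (0.2 μM) and polymerized (4 μM) enzyme, and an inhibition
    series across the enzyme window where CTP switches assembly on
    (0.55–1.6 μM) — the only region where equilibrium observables carry
    appreciable information about the nucleation barrier.
    """
    data = [
        gen_titration(params, U=U, C=0.0, cv=cv, seed=base_seed),
        gen_inhibition(params, E_tot=0.2, U=U, cv=cv, seed=base_seed + 1),
        gen_inhibition(params, E_tot=4.0, U=U, cv=cv, seed=base_seed + 2),
    ]
    for k, E in enumerate(RECOVERY_WINDOW_E_UM):
        data.append(gen_inhibition(params, E_tot=float(E), U=U,
                                   C_grid=np.asarray(RECOVERY_WINDOW_C_GRID),
                                   cv=cv, seed=base_seed + 3 + k))
    return data
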