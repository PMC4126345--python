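"""Parameter and condition containers for the polymerization model.

Units are fixed package-wide: concentrations in μM, rates in s⁻¹, and
energies dimensionless in units of the thermal energy k_B·T.  The enzyme
unit throughout is the tetramer (the catalytically competent species);
filaments are linear stacks of tetramers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace


class LinkageDirectionWarning(UserWarning):
    """Polymer CTP affinity is not tighter than free-tetramer affinity.

    With K_cp ≥ K_cf, CTP no longer binds more favorably to the filament
    than to the free tetramer, so CTP does not promote assembly and the
    model's linkage predictions invert.  Legal, but probably not intended.
    """


MECHANISMS = ("competitive", "noncompetitive")


@dataclass(frozen=True)
class ThermoParams:
    """Equilibrium and catalytic constants of the assembly model.

    Parameters
    ----------
    K_uf : float
        Dissociation constant of UTP from the free tetramer, μM.
    K_cf : float
        Dissociation constant of CTP from the free tetramer, μM.
    K_cp : float
        Dissociation constant of CTP from a polymerized subunit, μM.
        Linkage requires K_cp < K_cf for CTP to promote assembly.
    K_e : float
        Per-subunit elongation dissociation constant for adding a
        (CTP-weighted) tetramer to a filament end, μM.
    E_nuc : float
        Nucleation free-energy barrier in units of k_B·T, paid once per
        filament.  The nucleation factor is sigma = exp(-E_nuc).
    k_max : float
        Maximal per-tetramer catalytic rate, s⁻¹.  Non-modeled
        co-substrates (ATP, glutamine, GTP, Mg²⁺) are assumed saturating
        and folded into this number.
    mechanism : str
        "competitive" (CTP excludes UTP from a shared site on the free
        tetramer) or "noncompetitive" (independent sites).
    polymerizing : bool
        False models a nonpolymerizing enzyme (e.g. an assembly-interface
        mutant); the filament sector is then absent entirely.
    """

    K_uf: float
    K_cf: float
    K_cp: float
    K_e: float
    E_nuc: float
    k_max: float
    mechanism: str = "competitive"
    polymerizing: bool = True

    def __post_init__(self) -> None:
        for name in ("K_uf", "K_cf", "K_cp", "K_e"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")
        if not (math.isfinite(self.E_nuc) and self.E_nuc >= 0):
            raise ValueError(f"E_nuc must be finite and >= 0, got {self.E_nuc!r}")
        if not (math.isfinite(self.k_max) and self.k_max >= 0):
            raise ValueError(f"k_max must be finite and >= 0, got {self.k_max!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        if self.polymerizing and self.K_cp >= self.K_cf:
            warnings.warn(
                f"K_cp ({self.K_cp} μM) >= K_cf ({self.K_cf} μM): linkage direction "
                "reversed, CTP will not promote polymer assembly",
                LinkageDirectionWarning,
                stacklevel=2,
            )

    @property
    def sigma(self) -> float:
        """Nucleation factor exp(-E_nuc), dimensionless."""
        return math.exp(-self.E_nuc)

    def replace(self, **changes) -> "ThermoParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class Conditions:
    """Free-ligand concentrations and total enzyme, all in μM.

    Ligands are clamped (buffered): U and C are free concentrations not
    depleted by binding, reflecting the mM-ligand / μM-enzyme excess of
    the in vitro assays.  E_tot counts tetramers.
    """

    U: float = 0.0
    C: float = 0.0
    E_tot: float = 0.0

    def __post_init__(self) -> None:
        for name in ("U", "C", "E_tot"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def replace(self, **changes) -> "Conditions":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {"U": self.U, "C": self.C, "E_tot": self.E_tot}
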