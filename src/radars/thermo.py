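"""Thermodynamic bookkeeping for antibody--antigen binding.

Binding strength is expressed interchangeably as a free-energy change of
binding (ΔG) or as an equilibrium constant (K).  Throughout the package ΔG
is stored as the *magnitude of the free-energy decrease* on binding, so
ΔG ≥ 0 and a larger ΔG means a better binder.  Under this convention

    K_D = exp(-ΔG / RT)        (dissociation)
    K_A = exp(+ΔG / RT)        (association)

With energies in kJ/mol the per-mole gas constant R is used; a dimensionless
"kBT" mode (RT = 1) is available for reduced-unit work.

The module also implements the system equilibrium constant

    K_sys = K_A / <K_A> = exp((ΔG - <ΔG>) / RT)

which normalises a molecule's association constant by the system median, and
the lognormal mean energy exp(μ + σ²/2) that sets the characteristic binding
energy scale of the repertoire (27.67 kJ/mol at 310 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

__all__ = [
    "GAS_CONSTANT_KJ",
    "ThermoContext",
    "BindingEnergy",
    "SystemConstant",
    "k_from_dg",
    "dg_from_k",
    "regulated_antigen_concentration",
    "ksys_from_dg",
    "lognormal_mean_energy",
]

#: Gas constant in kJ·mol⁻¹·K⁻¹ (8.314 J·mol⁻¹·K⁻¹).
GAS_CONSTANT_KJ = 8.314e-3

EnergyUnit = Literal["kJ/mol", "kBT"]
Kind = Literal["association", "dissociation"]


class ThermoError(ValueError):
    """Invalid thermodynamic input (non-finite energy, K ≤ 0, T ≤ 0, ...)."""


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and unit conventions shared by all conversions.

    Parameters
    ----------
    temperature : float
        Thermodynamic temperature in kelvin. Default 310 K (body temperature);
        this is the temperature at which a mean binding energy of
        27.67 kJ/mol corresponds to K_D ≈ 2×10⁻⁵.
    gas_constant : float
        Per-mole gas constant in kJ·mol⁻¹·K⁻¹. Ignored in ``kBT`` mode.
    energy_unit : {"kJ/mol", "kBT"}
        In ``kBT`` mode energies are dimensionless multiples of the thermal
        energy and RT ≡ 1.
    """

    temperature: float = 310.0
    gas_constant: float = GAS_CONSTANT_KJ
    energy_unit: EnergyUnit = "kJ/mol"

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ThermoError(f"temperature must be positive, got {self.temperature}")
        if self.energy_unit not in ("kJ/mol", "kBT"):
            raise ThermoError(f"unknown energy unit {self.energy_unit!r}")
        if self.rt <= 0:
            raise ThermoError("RT must be positive")

    @property
    def rt(self) -> float:
        """Thermal energy RT in the context's energy unit."""
        if self.energy_unit == "kBT":
            return 1.0
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class BindingEnergy:
    """Free-energy decrease on binding, ΔG = F_bound − F_free taken as magnitude.

    ``dg`` is non-negative; optional ``f_bound``/``f_free`` components may be
    supplied and must then be consistent with ``dg``.
    """

    dg: float
    unit: EnergyUnit = "kJ/mol"
    f_bound: Optional[float] = None
    f_free: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.dg):
            raise ThermoError(f"binding energy must be finite, got {self.dg}")
        if self.dg < 0:
            raise ThermoError(
                "dg is the magnitude of the free-energy decrease and must be >= 0"
            )
        if self.f_bound is not None and self.f_free is not None:
            implied = abs(self.f_bound - self.f_free)
            if not math.isclose(implied, self.dg, rel_tol=1e-9, abs_tol=1e-12):
                raise ThermoError(
                    f"dg={self.dg} inconsistent with |f_bound - f_free|={implied}"
                )


@dataclass(frozen=True)
class SystemConstant:
    """A molecule's binding propensity relative to the system.

    ``k_sys`` is the association constant divided by the system median;
    ``k_sys == 1`` for a molecule binding exactly at the system average.
    """

    k_sys: float
    reference_mean_dg: float = 0.0
    reference_median_ka: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k_sys > 0):
            raise ThermoError(f"k_sys must be positive, got {self.k_sys}")


def _as_energy(dg: "BindingEnergy | float", ctx: ThermoContext) -> BindingEnergy:
    if isinstance(dg, BindingEnergy):
        if dg.unit != ctx.energy_unit:
            raise ThermoError(
                f"energy unit {dg.unit!r} does not match context {ctx.energy_unit!r}"
            )
        return dg
    return BindingEnergy(float(dg), unit=ctx.energy_unit)


def k_from_dg(
    dg: "BindingEnergy | float",
    ctx: ThermoContext = ThermoContext(),
    kind: Kind = "dissociation",
) -> float:
    """Equilibrium constant from binding free energy, K = exp(∓ΔG/RT).

    ``kind="dissociation"`` returns K_D = exp(-ΔG/RT); ``"association"``
    returns K_A = exp(+ΔG/RT).  The two are exact reciprocals.
    """
    e = _as_energy(dg, ctx)
    if kind == "dissociation":
        return math.exp(-e.dg / ctx.rt)
    if kind == "association":
        return math.exp(e.dg / ctx.rt)
    raise ThermoError(f"kind must be 'association' or 'dissociation', got {kind!r}")


def dg_from_k(
    k: float,
    ctx: ThermoContext = ThermoContext(),
    kind: Kind = "dissociation",
) -> BindingEnergy:
    """Binding free energy from an equilibrium constant, ΔG = ∓RT·ln K.

    Exact inverse of :func:`k_from_dg`; round trips to better than 1e-12
    relative error.
    """
    if not (k > 0 and math.isfinite(k)):
        raise ThermoError(f"equilibrium constant must be positive and finite, got {k}")
    if kind == "dissociation":
        dg = -ctx.rt * math.log(k)
    elif kind == "association":
        dg = ctx.rt * math.log(k)
    else:
        raise ThermoError(f"kind must be 'association' or 'dissociation', got {kind!r}")
    if dg < 0:
        raise ThermoError(
            f"K={k} ({kind}) implies a negative binding free energy under the "
            "magnitude convention (K_D must be <= 1, K_A >= 1)"
        )
    return BindingEnergy(dg, unit=ctx.energy_unit)


def regulated_antigen_concentration(
    dg: "BindingEnergy | float", ctx: ThermoContext = ThermoContext()
) -> float:
    """Steady-state free antigen level implied by the regulatory principle [Ag] ≈ K_D.

    The humoral system is taken to adjust each antigen's free concentration
    toward the dissociation constant of the controlling antibody, so the
    returned value is exp(-ΔG/RT) in units of K_D — identical to
    ``k_from_dg(dg, ctx, "dissociation")``, monotone decreasing in ΔG.
    """
    return k_from_dg(dg, ctx, "dissociation")


def ksys_from_dg(
    dg: "BindingEnergy | float",
    mean_dg: "BindingEnergy | float",
    ctx: ThermoContext = ThermoContext(),
) -> SystemConstant:
    """System equilibrium constant K_sys = K_A/<K_A> = exp((ΔG − <ΔG>)/RT).

    A stronger-than-average binder has K_sys > 1; K_sys == 1 exactly when
    ΔG equals the system mean.
    """
    e = _as_energy(dg, ctx)
    m = _as_energy(mean_dg, ctx)
    return SystemConstant(
        k_sys=math.exp((e.dg - m.dg) / ctx.rt),
        reference_mean_dg=m.dg,
        reference_median_ka=math.exp(m.dg / ctx.rt),
    )


def lognormal_mean_energy(mu: float, sigma: float) -> float:
    """Mean of a lognormal energy distribution, exp(μ + σ²/2).

    With μ = 0 and σ equal to the numeric value of RT in kJ/mol at 310 K
    (≈ 2.577) this gives the characteristic system mean binding energy of
    ≈ 27.7 kJ/mol.
    """
    if sigma < 0:
        raise ThermoError(f"sigma must be >= 0, got {sigma}")
    if not (math.isfinite(mu) and math.isfinite(sigma)):
        raise ThermoError("mu and sigma must be finite")
    return math.exp(mu + sigma * sigma / 2.0)
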