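"""Dissolved N₂O from headspace equilibration, and deviation from air equilibrium.

A sealed bottle (default 1.12 L) has part of its water (default 0.12 L)
replaced by ambient air; after vigorous mixing the gas partitions between the
remaining water and the headspace. A mole balance over the bottle recovers the
original dissolved concentration C_water; the air-equilibrium concentration
C_eq follows from the ambient mixing ratio at in-situ temperature, and the
saturation anomaly is ΔN₂O = C_water − C_eq. For ice-covered periods, when the
water column cannot exchange with the atmosphere, ΔN₂O for every under-ice
sample is computed against the C_eq of the first under-ice sample of that
winter.

Solubility uses the Weiss & Price (1980) N₂O fit (mol L⁻¹ atm⁻¹); the
headspace is treated as an ideal gas of dry-air mixing ratios.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "R_GAS",
    "HeadspaceRecord",
    "N2OResult",
    "n2o_solubility",
    "equilibrium_concentration",
    "headspace_to_cwater",
    "mass_balance_residual",
    "compute_delta_n2o",
    "average_replicates",
]

#: Ideal-gas constant, L atm mol⁻¹ K⁻¹.
R_GAS = 0.0820573

# Weiss & Price (1980) K0 coefficients for N2O, mol L-1 atm-1 form:
# ln K0 = A1 + A2*(100/T) + A3*ln(T/100) + S*(B1 + B2*(T/100) + B3*(T/100)^2)
_WP_A1, _WP_A2, _WP_A3 = -62.7062, 97.3066, 24.1406
_WP_B1, _WP_B2, _WP_B3 = -0.05842, 0.033193, -0.0051313


@dataclass
class HeadspaceRecord:
    """One headspace-equilibration measurement (replicate vials already averaged).

    Mixing ratios are dry ppm; temperatures °C; pressure atm; volumes L.
    """

    sample_id: str
    date: _dt.date
    depth_label: str
    x_headspace: float
    x_air: float
    temp_equil: float
    temp_insitu: float
    pressure: float = 1.0
    v_bottle: float = 1.12
    v_headspace: float = 0.12
    under_ice: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.v_headspace < self.v_bottle:
            raise ValueError("need 0 < v_headspace < v_bottle")
        if self.x_headspace < 0 or self.x_air < 0:
            raise ValueError("mixing ratios must be >= 0")
        for t in (self.temp_equil, self.temp_insitu):
            if not -5 < t < 40:
                raise ValueError(f"temperature {t} outside (-5, 40) degC")
        if self.pressure <= 0:
            raise ValueError("pressure must be > 0")

    @property
    def v_water(self) -> float:
        return self.v_bottle - self.v_headspace


@dataclass
class N2OResult:
    """Derived dissolved-N₂O quantities for one sample (nmol L⁻¹, plus the
    ppm-equivalent anomaly)."""

    sample_id: str
    date: _dt.date
    c_water: float
    c_eq: float
    delta_n2o: float
    delta_n2o_ppm: float
    winter_ceq_used: bool
    first_winter_reference: bool = False


def n2o_solubility(temp: float, salinity: float = 0.0) -> float:
    """N₂O solubility K₀ (mol L⁻¹ atm⁻¹) after Weiss & Price (1980).

    ``temp`` in °C (valid −2…40), ``salinity`` in PSU (0 for lake water).
    """
    if not -2 <= temp <= 40:
        raise ValueError(f"temperature {temp} outside valid range [-2, 40] degC")
    t_k = temp + 273.15
    ln_k0 = (
        _WP_A1
        + _WP_A2 * (100.0 / t_k)
        + _WP_A3 * math.log(t_k / 100.0)
        + salinity * (_WP_B1 + _WP_B2 * (t_k / 100.0) + _WP_B3 * (t_k / 100.0) ** 2)
    )
    return math.exp(ln_k0)


def equilibrium_concentration(
    x_air: float, temp: float, pressure: float = 1.0
) -> float:
    """Air-equilibrium dissolved N₂O (nmol L⁻¹) for mixing ratio ``x_air`` (ppm)
    at water temperature ``temp`` (°C) and total pressure (atm)."""
    return n2o_solubility(temp) * x_air * 1e-6 * pressure * 1e9


def headspace_to_cwater(rec: HeadspaceRecord, k0: Optional[float] = None) -> float:
    """Original dissolved N₂O concentration (nmol L⁻¹) by bottle mole balance.

    Before equilibration the bottle holds C_water·V_w dissolved plus ambient
    air (x_air) in the headspace; after equilibration the water is at
    solubility equilibrium with the measured headspace (x_headspace). Both
    headspace states are taken at the equilibration temperature and ambient
    pressure. ``k0`` overrides the solubility (mol L⁻¹ atm⁻¹) for testing.
    """
    if k0 is None:
        k0 = n2o_solubility(rec.temp_equil)
    t_k = rec.temp_equil + 273.15
    p_final = rec.x_headspace * 1e-6 * rec.pressure
    p_air = rec.x_air * 1e-6 * rec.pressure
    # mol: dissolved after + headspace after - headspace before, over V_w
    dissolved_after = k0 * p_final * rec.v_water
    headspace_net = (p_final - p_air) * rec.v_headspace / (R_GAS * t_k)
    c_water_mol = (dissolved_after + headspace_net) / rec.v_water
    c_water = c_water_mol * 1e9
    if c_water < 0:
        raise ValueError(
            f"nonphysical negative C_water ({c_water:.3g} nmol/L) for "
            f"{rec.sample_id}: headspace lost more N2O than air supplied"
        )
    return c_water


def mass_balance_residual(rec: HeadspaceRecord, c_water: float) -> float:
    """Forward-check residual (mol) of the bottle N₂O balance for a solved
    record; exactly solvable records give ~1e-12·total or smaller."""
    k0 = n2o_solubility(rec.temp_equil)
    t_k = rec.temp_equil + 273.15
    p_final = rec.x_headspace * 1e-6 * rec.pressure
    p_air = rec.x_air * 1e-6 * rec.pressure
    before = c_water * 1e-9 * rec.v_water + p_air * rec.v_headspace / (R_GAS * t_k)
    after = k0 * p_final * rec.v_water + p_final * rec.v_headspace / (R_GAS * t_k)
    return before - after


def compute_delta_n2o(series: Sequence[HeadspaceRecord]) -> list[N2OResult]:
    """ΔN₂O = C_water − C_eq for a chronologically ordered series.

    Open-water samples use their own C_eq (ambient air, in-situ temperature).
    Under-ice samples reuse the C_eq of the first under-ice sample of that
    winter (no air–water exchange through ice); the first sample of a winter
    run is its own reference and is flagged. The anomaly is also reported as
    a ppm-equivalent partial-pressure deviation, ΔN₂O/(K₀(T_insitu)·pressure).
    """
    dates = [r.date for r in series]
    if any(d2 < d1 for d1, d2 in zip(dates, dates[1:])):
        raise ValueError("series must be sorted chronologically")
    results: list[N2OResult] = []
    winter_ceq: Optional[float] = None
    for rec in series:
        c_water = headspace_to_cwater(rec)
        own_ceq = equilibrium_concentration(rec.x_air, rec.temp_insitu, rec.pressure)
        first_ref = False
        if rec.under_ice:
            if winter_ceq is None:
                winter_ceq = own_ceq
                first_ref = True
            c_eq = winter_ceq
            winter_used = True
        else:
            winter_ceq = None  # winter run ended; next ice-on starts a new one
            c_eq = own_ceq
            winter_used = False
        delta = c_water - c_eq
        k0_insitu = n2o_solubility(rec.temp_insitu)
        delta_ppm = delta * 1e-3 / (k0_insitu * rec.pressure)
        results.append(
            N2OResult(
                sample_id=rec.sample_id,
                date=rec.date,
                c_water=c_water,
                c_eq=c_eq,
                delta_n2o=delta,
                delta_n2o_ppm=delta_ppm,
                winter_ceq_used=winter_used,
                first_winter_reference=first_ref,
            )
        )
    return results


def average_replicates(records: Sequence[HeadspaceRecord]) -> HeadspaceRecord:
    """Average replicate vials of one sample (same bottle, same conditions)
    into a single record before solving the mole balance."""
    if not records:
        raise ValueError("no records to average")
    first = records[0]
    for r in records[1:]:
        if r.sample_id != first.sample_id:
            raise ValueError("replicates must share a sample_id")
    mean = lambda attr: float(np.mean([getattr(r, attr) for r in records]))
    return HeadspaceRecord(
        sample_id=first.sample_id,
        date=first.date,
        depth_label=first.depth_label,
        x_headspace=mean("x_headspace"),
        x_air=mean("x_air"),
        temp_equil=mean("temp_equil"),
        temp_insitu=mean("temp_insitu"),
        pressure=mean("pressure"),
        v_bottle=first.v_bottle,
        v_headspace=first.v_headspace,
        under_ice=first.under_ice,
    )
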