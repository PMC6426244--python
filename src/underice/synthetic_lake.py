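"""Forward simulation of ¹⁵N tracer incubations and a seasonal ice-covered lake.

Two generators make every stage of the pipeline verifiable without field data:

* :func:`simulate_incubation` inverts the end-point rate equation under a
  planted true ammonia-oxidation rate, with optional methodological biases —
  NH₄⁺ regeneration (unlabelled influx dilutes the labelled fraction during
  the incubation, biasing estimates low) and over-spike stimulation (tracer
  additions large relative to ambient substrate stimulate the community,
  biasing estimates high) — and analytical noise at realistic precisions.
* :func:`simulate_year` draws a 13-month series of environmental samples with
  the seasonal structure of a small dimictic, seasonally ice-covered
  oligotrophic lake: NH₄⁺ accumulating under ice (winter mean 2.8 µmol L⁻¹)
  and drawn down in summer (0.4 µmol L⁻¹), nitrate ramping under ice to a
  spring peak (3.3 µmol L⁻¹), chlorophyll inverse to nutrients (0.4 vs
  4.0 µg L⁻¹), under-ice N₂O accumulation, and an AO rate that is a monotone
  (saturating or threshold) function of NH₄⁺.

The generator is statistical, not process-based: it reproduces seasonal means,
contrasts and noise levels, not lake hydrodynamics.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .ao_rates import (
    IncubationRecord,
    atom_fraction_to_delta,
    delta_to_atom_fraction,
    design_spike,
)
from .drivers_stats import SeasonalSample
from .n2o_headspace import HeadspaceRecord, R_GAS, n2o_solubility

__all__ = [
    "NoiseConfig",
    "SeasonalConfig",
    "SimulationConfig",
    "assign_season",
    "simulate_incubation",
    "simulate_year",
    "make_fixture_suite",
]


@dataclass
class NoiseConfig:
    """Analytical 1σ noise levels (instrument precisions)."""

    d15n: float = 6.8  # ‰
    nh4: float = 0.2  # µmol L⁻¹
    no2: float = 0.06  # µmol L⁻¹
    chla: float = 0.3  # µg L⁻¹

    def off(self) -> "NoiseConfig":
        return NoiseConfig(0.0, 0.0, 0.0, 0.0)


@dataclass
class SeasonalConfig:
    """Seasonal structure of the simulated lake year."""

    ice_on: _dt.date = _dt.date(2011, 12, 10)
    ice_off: _dt.date = _dt.date(2012, 4, 13)
    nh4_winter_mean: float = 2.8  # µmol L⁻¹
    nh4_summer_mean: float = 0.4
    nh4_spring_mean: float = 1.5
    nh4_autumn_mean: float = 1.2
    nh4_sd: float = 0.5  # within-season scatter
    no3_spring_peak: float = 3.3  # µmol L⁻¹, reached at ice-off
    chla_winter: float = 0.4  # µg L⁻¹
    chla_summer: float = 4.0
    rate_nh4_threshold: float = 2.6  # µmol L⁻¹, threshold-link change point
    rate_link: str = "saturation"  # or "threshold"
    rate_max: float = 400.0  # nmol L⁻¹ d⁻¹, saturation asymptote
    rate_km: float = 2.0  # µmol L⁻¹, half-saturation
    rate_low: float = 50.0  # nmol L⁻¹ d⁻¹, threshold link below change point
    rate_high: float = 231.0  # nmol L⁻¹ d⁻¹, above change point
    rate_noise_sd: float = 40.0  # nmol L⁻¹ d⁻¹

    def __post_init__(self) -> None:
        if self.rate_link not in ("saturation", "threshold"):
            raise ValueError("rate_link must be saturation|threshold")


@dataclass
class SimulationConfig:
    """Planted truths and noise for the synthetic generators."""

    seed: int = 0
    r_true: float = 100.0  # nmol L⁻¹ d⁻¹
    nh4_ambient: float = 1.0  # µmol L⁻¹
    no2_ambient: float = 0.05  # µmol L⁻¹
    spike_rule: str = "five_percent"  # five_percent | floor | explicit
    spike_explicit: float = 0.05  # µmol L⁻¹, used when spike_rule == explicit
    carrier: float = 0.25  # µmol L⁻¹
    t_incubation: float = 4.0  # h
    d15n_no2_baseline: float = 0.0  # ‰, natural abundance of the NO₂⁻ pool
    regeneration_rate: float = 0.0  # µmol L⁻¹ h⁻¹ of unlabelled NH₄⁺ influx
    no2_consumption_rate: float = 0.0  # fraction h⁻¹ (isotope-neutral)
    overspike_stimulation: float = 0.0  # rate multiplier per unit spike/ambient
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seasonal: SeasonalConfig = field(default_factory=SeasonalConfig)

    def __post_init__(self) -> None:
        if self.r_true < 0 or self.regeneration_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.spike_rule not in ("five_percent", "floor", "explicit"):
            raise ValueError("bad spike_rule")
        if self.seasonal.ice_on >= self.seasonal.ice_off:
            raise ValueError("ice_on must precede ice_off across the new year")


def assign_season(date: _dt.date, seasonal: SeasonalConfig) -> tuple[str, bool]:
    """Season label and under-ice flag for a date.

    winter = ice-covered; spring = ice-out to stratification onset (May 31);
    summer = stratified (June–September); autumn = overturn to ice-on.
    """
    ice_on, ice_off = seasonal.ice_on, seasonal.ice_off
    under_ice = (
        (date.month, date.day) >= (ice_on.month, ice_on.day)
        or (date.month, date.day) <= (ice_off.month, ice_off.day)
    )
    if under_ice:
        return "winter", True
    if date.month in (4, 5):
        return "spring", False
    if date.month in (6, 7, 8, 9):
        return "summer", False
    return "autumn", False


def _spike_for(cfg: SimulationConfig) -> float:
    if cfg.spike_rule == "five_percent":
        return design_spike(cfg.nh4_ambient)
    if cfg.spike_rule == "floor":
        return 0.05
    return cfg.spike_explicit


def simulate_incubation(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
):
    """Simulate one tracer bottle experiment; returns (record, truth dict).

    The labelled fraction evolves as α(t) = spike/(P₀ + ρt) under a constant
    unlabelled regeneration influx ρ (instantaneous mixing), giving the
    closed-form labelled-substrate exposure ∫α dt = (spike/ρ)·ln(1 + ρt/P₀)
    (= α₀·t when ρ = 0). The effective oxidation rate is
    r_true·(1 + stimulation·spike/ambient). NO₂⁻ consumption is modelled as
    isotope-neutral (pool shrinks, δ¹⁵N unchanged), matching the assumption
    under which initial NO₂⁻ is used in the rate equation.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    spike = _spike_for(cfg)
    no2_initial = cfg.no2_ambient + cfg.carrier
    p0 = cfg.nh4_ambient + spike
    alpha0 = spike / p0
    ratio = spike / cfg.nh4_ambient if cfg.nh4_ambient > 0 else 1.0
    r_eff = cfg.r_true * (1.0 + cfg.overspike_stimulation * ratio)

    t = cfg.t_incubation
    if cfg.regeneration_rate > 0:
        exposure = (spike / cfg.regeneration_rate) * np.log(
            1.0 + cfg.regeneration_rate * t / p0
        )
    else:
        exposure = alpha0 * t
    excess_15n = (r_eff / 24.0) * exposure  # nmol L⁻¹ added to the NO₂⁻ pool
    d_af_no2 = excess_15n / (no2_initial * 1000.0)

    af_base = delta_to_atom_fraction(cfg.d15n_no2_baseline)
    af_azide = delta_to_atom_fraction(0.0)
    af_n2o_t0 = (af_base + af_azide) / 2.0
    af_n2o_tf = (af_base + d_af_no2 + af_azide) / 2.0
    d_t0 = atom_fraction_to_delta(af_n2o_t0)
    d_tf = atom_fraction_to_delta(af_n2o_tf)

    d15n_t0 = [d_t0 + rng.normal(0.0, cfg.noise.d15n) for _ in range(2)]
    d15n_tf = [d_tf + rng.normal(0.0, cfg.noise.d15n) for _ in range(2)]
    nh4_meas = max(cfg.nh4_ambient + rng.normal(0.0, cfg.noise.nh4), 0.0)
    # measured total nitrite cannot fall below the (exactly known) carrier
    no2_floor = cfg.carrier if cfg.carrier > 0 else 1e-6
    no2_meas = max(no2_initial + rng.normal(0.0, cfg.noise.no2), no2_floor)

    rec = IncubationRecord(
        sample_id=f"sim-{cfg.seed}",
        date=_dt.date(2012, 1, 15),
        depth_label="top",
        diel="day",
        nh4_ambient=nh4_meas,
        no2_initial=no2_meas,
        spike_15n=spike,
        carrier_no2=cfg.carrier,
        t_incubation=t,
        d15n_t0=d15n_t0,
        d15n_tf=d15n_tf,
    )
    truth = {
        "r_true": cfg.r_true,
        "r_effective": r_eff,
        "alpha0": alpha0,
        "exposure": exposure,
        "spike": spike,
        "no2_initial": no2_initial,
        # the noise-free value the end-point estimator converges to
        "r_expected_estimate": r_eff * exposure / (alpha0 * t),
    }
    return rec, truth


def _rate_from_nh4(nh4: float, s: SeasonalConfig) -> float:
    if s.rate_link == "threshold":
        return s.rate_low if nh4 < s.rate_nh4_threshold else s.rate_high
    return s.rate_max * nh4 / (s.rate_km + nh4)


def simulate_year(cfg: SimulationConfig, n_dates: int = 26) -> list[SeasonalSample]:
    """Draw a 13-month seasonal series (one sample per date, alternating
    depth and, in open water, diel phase)."""
    if n_dates < 12:
        raise ValueError("need n_dates >= 12")
    rng = np.random.default_rng(cfg.seed)
    s = cfg.seasonal
    start = _dt.date(2011, 10, 1)
    end = _dt.date(2012, 10, 31)
    span = (end - start).days
    samples: list[SeasonalSample] = []
    nh4_means = {
        "winter": s.nh4_winter_mean,
        "spring": s.nh4_spring_mean,
        "summer": s.nh4_summer_mean,
        "autumn": s.nh4_autumn_mean,
    }
    ice_days = (
        _dt.date(2012, s.ice_off.month, s.ice_off.day)
        - _dt.date(2011, s.ice_on.month, s.ice_on.day)
    ).days
    for i in range(n_dates):
        date = start + _dt.timedelta(days=round(i * span / (n_dates - 1)))
        season, under_ice = assign_season(date, s)
        depth = "top" if i % 2 == 0 else "bottom"
        diel = "day" if under_ice or i % 4 < 2 else "night"

        nh4 = max(rng.normal(nh4_means[season], s.nh4_sd), 0.0)
        # November overturn pulse
        if date.month == 11:
            nh4 += abs(rng.normal(0.5, 0.2))

        if under_ice:
            into_ice = (date - _dt.date(2011, s.ice_on.month, s.ice_on.day)).days
            frac = np.clip(into_ice / max(ice_days, 1), 0.0, 1.0)
            no3_mean = 0.2 + (s.no3_spring_peak - 0.2) * frac
        elif season == "spring":
            no3_mean = s.no3_spring_peak * 0.9
        elif season == "summer":
            no3_mean = 0.6
        else:
            no3_mean = 0.15
        no3no2 = max(rng.normal(no3_mean, 0.15) + rng.normal(0.0, cfg.noise.no2), 0.0)

        temp_mean = {"winter": 2.0, "spring": 6.0, "summer": 18.0, "autumn": 8.0}[season]
        if depth == "bottom" and season == "summer":
            temp_mean = 8.0
        temp = rng.normal(temp_mean, 1.0)
        o2_mean = {"winter": 11.0, "spring": 11.0, "summer": 8.5, "autumn": 10.0}[season]
        if depth == "bottom" and season == "summer":
            o2_mean = 5.0
        o2 = max(rng.normal(o2_mean, 0.7), 2.8)

        light = 0.0 if under_ice else (0.10 if depth == "top" else 0.01)
        chla_mean = {
            "winter": s.chla_winter,
            "spring": 2.0,
            "summer": s.chla_summer,
            "autumn": 1.5,
        }[season]
        chla = max(rng.normal(chla_mean, cfg.noise.chla), 0.0)

        rate = _rate_from_nh4(nh4, s)
        if s.rate_noise_sd > 0:
            rate = max(rate + rng.normal(0.0, s.rate_noise_sd), 0.0)

        if under_ice:
            into_ice = (date - _dt.date(2011, s.ice_on.month, s.ice_on.day)).days
            frac = np.clip(into_ice / max(ice_days, 1), 0.0, 1.0)
            dn2o = 6.6 * frac + rng.normal(0.0, 0.5)
        else:
            dn2o = rng.normal(0.5, 0.8)

        samples.append(
            SeasonalSample(
                date=date,
                season=season,
                depth_label=depth,
                diel=diel,
                nh4=nh4,
                no3no2=no3no2,
                o2=o2,
                temp=temp,
                light_fraction=light,
                under_ice=under_ice,
                chla=chla,
                ao_rate=rate,
                delta_n2o=dn2o,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

_STANDARDS_KNOWN = (-76.9, -35.6, 1.7, 36.7)


def make_fixture_suite(seed: int, out_dir) -> dict:
    """Write a deterministic CSV bundle exercising every pipeline stage.

    Files: ``standards.csv``, ``incubations.csv`` (long format, one row per
    bottle), ``headspace.csv``, ``chla.csv``, ``seasonal.csv`` and
    ``manifest.json`` holding the planted truths. Identical seeds produce
    byte-identical bundles.
    """
    from . import io_cli  # deferred to avoid an import cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": int(seed)}

    # -- calibration standards: planted instrument line known = a*measured + b
    slope_true, intercept_true = 0.97, 1.5
    measured = [
        (k - intercept_true) / slope_true + rng.normal(0.0, 0.2)
        for k in _STANDARDS_KNOWN
    ]
    io_cli.write_standards(
        out_dir / "standards.csv", measured, list(_STANDARDS_KNOWN)
    )
    manifest["calibration"] = {"slope": slope_true, "intercept": intercept_true}

    # -- incubations across the year (rate driven by seasonal NH4)
    seasonal = SeasonalConfig()
    records = []
    truths = {}
    base_date = _dt.date(2011, 10, 15)
    for i in range(12):
        date = _dt.date(
            base_date.year + (base_date.month + i - 1) // 12,
            (base_date.month + i - 1) % 12 + 1,
            15,
        )
        season, _ = assign_season(date, seasonal)
        nh4 = max(
            rng.normal(
                {
                    "winter": seasonal.nh4_winter_mean,
                    "spring": seasonal.nh4_spring_mean,
                    "summer": seasonal.nh4_summer_mean,
                    "autumn": seasonal.nh4_autumn_mean,
                }[season],
                0.3,
            ),
            0.05,
        )
        cfg = SimulationConfig(
            seed=seed + i,
            r_true=_rate_from_nh4(nh4, seasonal),
            nh4_ambient=nh4,
        )
        rec, truth = simulate_incubation(cfg, rng)
        # re-express the bottle deltas on the instrument scale so that the
        # shipped standards calibrate them back
        rec.d15n_t0 = [(d - intercept_true) / slope_true for d in rec.d15n_t0]
        rec.d15n_tf = [(d - intercept_true) / slope_true for d in rec.d15n_tf]
        rec.sample_id = f"inc-{i:02d}"
        rec.date = date
        records.append(rec)
        truths[rec.sample_id] = truth
    io_cli.write_incubations(out_dir / "incubations.csv", records)
    manifest["incubations"] = {
        k: {kk: float(vv) for kk, vv in v.items()} for k, v in truths.items()
    }

    # -- headspace records constructed from planted dissolved concentrations
    hs_records = []
    hs_truth = {}
    for i in range(8):
        date = _dt.date(2012, 1 + i, 10)
        season, under_ice = assign_season(date, seasonal)
        temp_insitu = 2.0 if under_ice else 15.0
        temp_equil = 20.0
        x_air = 0.328
        k0_eq = n2o_solubility(temp_equil)
        c_eq_insitu = n2o_solubility(temp_insitu) * x_air * 1e-6 * 1e9
        c_water_true = c_eq_insitu * (1.25 if under_ice else rng.uniform(0.95, 1.1))
        v_w, v_h = 1.0, 0.12
        t_k = temp_equil + 273.15
        p_air = x_air * 1e-6
        p_final = (c_water_true * 1e-9 * v_w + p_air * v_h / (R_GAS * t_k)) / (
            k0_eq * v_w + v_h / (R_GAS * t_k)
        )
        hs_records.append(
            HeadspaceRecord(
                sample_id=f"hs-{i:02d}",
                date=date,
                depth_label="top",
                x_headspace=p_final * 1e6,
                x_air=x_air,
                temp_equil=temp_equil,
                temp_insitu=temp_insitu,
                pressure=1.0,
                v_bottle=v_w + v_h,
                v_headspace=v_h,
                under_ice=under_ice,
            )
        )
        hs_truth[f"hs-{i:02d}"] = float(c_water_true)
    io_cli.write_headspace(out_dir / "headspace.csv", hs_records)
    manifest["headspace_c_water"] = hs_truth

    # -- chl a triplicates with replicate noise at the stated precision
    from .pigments import ChlaRecord

    chla_records = []
    chla_truth = {}
    for i, target in enumerate([0.4, 2.0, 4.0]):
        for rep in range(3):
            noisy = target + rng.normal(0.0, 0.3)
            # construct absorbances that evaluate exactly to `noisy`
            v_extract, v_filtered, path = 10.0, 0.5, 1.0
            diff = noisy * v_filtered * path / (26.7 * v_extract)
            chla_records.append(
                ChlaRecord(
                    a665_before=max(0.03 + diff, 0.0),
                    a750_before=0.001,
                    a665_after=0.03,
                    a750_after=0.001,
                    v_extract=v_extract,
                    v_filtered=v_filtered,
                    path_length=path,
                    replicate_id=f"chla-{i}-{rep}",
                )
            )
        chla_truth[f"chla-{i}"] = target
    io_cli.write_chla(out_dir / "chla.csv", chla_records)
    manifest["chla_targets"] = chla_truth

    # -- seasonal series for the drivers analysis
    year_cfg = SimulationConfig(seed=seed)
    samples = simulate_year(year_cfg, n_dates=48)
    io_cli.write_seasonal(out_dir / "seasonal.csv", samples)
    manifest["seasonal"] = {
        "n": len(samples),
        "rate_link": year_cfg.seasonal.rate_link,
        "nh4_winter_mean": year_cfg.seasonal.nh4_winter_mean,
    }

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
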