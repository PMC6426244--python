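"""Ammonia-oxidation (AO) rates from single end-point ¹⁵NH₄⁺ tracer incubations.

The chain implemented here mirrors the standard azide-method workflow: raw
δ¹⁵N values of N₂O (chemically derived from the NO₂⁻ pool) are calibrated
against internal NO₂⁻ isotope standards, converted to ¹⁵N atom fractions,
doubled to undo the 1:1 dilution by unenriched azide nitrogen, and inserted
into the end-point rate equation

    r [nmol L⁻¹ d⁻¹] = 2 · (n¹⁵NO₂⁻(f) − n¹⁵NO₂⁻(i)) · NO₂⁻(i) / (t · α)

where NO₂⁻(i) is the initial nitrite pool (after tracer and carrier
additions), t the incubation time in days and α = spike/(spike + ambient NH₄⁺)
the labelled fraction of the substrate pool. Negative raw estimates (¹⁵NO₂⁻
depleted relative to background) are reported as non-detects with rate 0,
never as negative rates.

All isotope arithmetic is done on the atom-fraction scale (0–1); δ¹⁵N values
are per mil relative to atmospheric N₂.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "R_AIR",
    "IncubationRecord",
    "RateEstimate",
    "DeltaCalibration",
    "calibrate_delta",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "compute_alpha",
    "azide_correction",
    "compute_ao_rate",
    "design_spike",
    "overspike_ratio",
    "propagate_uncertainty",
]

#: ¹⁵N/¹⁴N isotope ratio of atmospheric N₂ (the δ¹⁵N reference).
R_AIR = 0.0036765

#: Default analytical 1σ precisions: δ¹⁵N (‰), NH₄⁺ (µmol L⁻¹), NO₂⁻ (µmol L⁻¹).
SIGMA_D15N = 6.8
SIGMA_NH4 = 0.2
SIGMA_NO2 = 0.06

#: Tracer additions above this fraction of ambient NH₄⁺ are flagged as
#: potentially rate-stimulating over-spikes.
OVERSPIKE_THRESHOLD = 0.15


@dataclass
class IncubationRecord:
    """One ¹⁵N tracer bottle experiment (duplicate t₀ and end-point bottles).

    Concentrations are µmol L⁻¹; ``no2_initial`` is the nitrite pool in the
    bottle immediately after tracer and carrier additions; ``t_incubation``
    is hours; δ¹⁵N lists hold per-bottle values on the N₂O measurement scale.
    """

    sample_id: str
    date: _dt.date
    depth_label: str  # {"top", "bottom"}
    diel: str  # {"day", "night"}
    nh4_ambient: float
    no2_initial: float
    spike_15n: float
    carrier_no2: float
    t_incubation: float
    d15n_t0: Sequence[float]
    d15n_tf: Sequence[float]

    def __post_init__(self) -> None:
        if self.depth_label not in ("top", "bottom"):
            raise ValueError(f"depth_label must be top|bottom, got {self.depth_label!r}")
        if self.diel not in ("day", "night"):
            raise ValueError(f"diel must be day|night, got {self.diel!r}")
        if self.nh4_ambient < 0:
            raise ValueError("nh4_ambient must be >= 0")
        if self.no2_initial <= 0:
            raise ValueError("no2_initial must be > 0")
        if self.spike_15n <= 0:
            raise ValueError("spike_15n must be > 0")
        if self.carrier_no2 < 0:
            raise ValueError("carrier_no2 must be >= 0")
        if self.no2_initial < self.carrier_no2:
            raise ValueError("no2_initial must be >= carrier_no2")
        if not 0 < self.t_incubation <= 24:
            raise ValueError("t_incubation must be in (0, 24] hours")
        if len(self.d15n_t0) == 0 or len(self.d15n_tf) == 0:
            raise ValueError("d15n_t0 and d15n_tf must be non-empty")


@dataclass
class RateEstimate:
    """A calibrated AO rate with QC flags.

    ``rate`` is nmol L⁻¹ d⁻¹ and is 0 whenever ``detected`` is False (the
    signed pre-truncation value is kept in ``raw_rate``). ``rate_sd`` is the
    Monte-Carlo propagated standard deviation (NaN until computed).
    """

    sample_id: str
    rate: float
    detected: bool
    alpha: float
    overspike_flag: bool
    overspike_ratio: float
    raw_rate: float
    rate_sd: float = float("nan")


@dataclass
class DeltaCalibration:
    """Ordinary-least-squares δ¹⁵N calibration against internal NO₂⁻ standards.

    The line ``known = slope · measured + intercept`` is fitted on the
    standards and then applied to sample values.
    """

    slope: float
    intercept: float
    standards_known: tuple
    standards_measured: tuple
    residual_sd: float

    @classmethod
    def fit(
        cls, standards_measured: Sequence[float], standards_known: Sequence[float]
    ) -> "DeltaCalibration":
        meas = np.asarray(standards_measured, dtype=float)
        known = np.asarray(standards_known, dtype=float)
        if meas.shape != known.shape:
            raise ValueError("known and measured standard lists must be the same length")
        if meas.size < 2:
            raise ValueError("insufficient standards: need at least 2")
        if np.ptp(meas) == 0:
            raise ValueError("zero variance in measured standards")
        slope, intercept = np.polyfit(meas, known, 1)
        resid = known - (slope * meas + intercept)
        dof = max(meas.size - 2, 1)
        residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
        return cls(
            slope=float(slope),
            intercept=float(intercept),
            standards_known=tuple(known),
            standards_measured=tuple(meas),
            residual_sd=residual_sd,
        )

    def apply(self, d15n):
        """Correct measured δ¹⁵N value(s) onto the standard scale."""
        arr = np.asarray(d15n, dtype=float)
        out = self.slope * arr + self.intercept
        return float(out) if np.isscalar(d15n) else out

    @classmethod
    def identity(cls) -> "DeltaCalibration":
        """A no-op calibration (slope 1, intercept 0)."""
        return cls(1.0, 0.0, (), (), 0.0)


def calibrate_delta(
    measured: Sequence[float],
    standards_measured: Sequence[float],
    standards_known: Sequence[float],
):
    """Calibrate sample δ¹⁵N values against internal isotope standards.

    Returns the corrected sample values and the fitted :class:`DeltaCalibration`.
    """
    calib = DeltaCalibration.fit(standards_measured, standards_known)
    corrected = calib.apply(np.asarray(measured, dtype=float))
    return corrected, calib


def delta_to_atom_fraction(d15n: float) -> float:
    """Convert δ¹⁵N (‰ vs. atmospheric N₂) to ¹⁵N atom fraction."""
    d15n = np.asarray(d15n, dtype=float)
    if np.any(d15n < -1000):
        raise ValueError("below physical limit: d15n < -1000 per mil")
    r = R_AIR * (d15n / 1000.0 + 1.0)
    af = r / (1.0 + r)
    return float(af) if af.ndim == 0 else af


def atom_fraction_to_delta(af: float) -> float:
    """Convert ¹⁵N atom fraction to δ¹⁵N (‰); exact inverse of
    :func:`delta_to_atom_fraction`."""
    af = np.asarray(af, dtype=float)
    if np.any(af >= 1) or np.any(af < 0):
        raise ValueError("atom fraction must be in [0, 1)")
    r = af / (1.0 - af)
    d = (r / R_AIR - 1.0) * 1000.0
    return float(d) if d.ndim == 0 else d


def compute_alpha(spike_15n: float, nh4_ambient: float) -> float:
    """Labelled fraction α of the NH₄⁺ substrate pool: spike/(spike+ambient)."""
    if spike_15n <= 0:
        raise ValueError("no tracer added: spike_15n must be > 0")
    if nh4_ambient < 0:
        raise ValueError("nh4_ambient must be >= 0")
    return spike_15n / (spike_15n + nh4_ambient)


def azide_correction(delta_excess_n2o: float) -> float:
    """Map atom-fraction excess measured on N₂O onto the NO₂⁻ scale (×2).

    Each N₂O molecule produced by the azide reaction carries one N atom from
    unenriched azide and one from the nitrite pool, halving the enrichment;
    the correction doubles it back. Sign is preserved (noise can make the
    excess negative).
    """
    if delta_excess_n2o < -1:
        raise ValueError("atom-fraction excess cannot be below -1")
    return 2.0 * delta_excess_n2o


def design_spike(nh4_prior: float) -> float:
    """Tracer addition rule: 5% of the expected ambient NH₄⁺, with a
    0.05 µmol L⁻¹ floor when ambient is too low (< 1 µmol L⁻¹)."""
    if nh4_prior < 0:
        raise ValueError("nh4_prior must be >= 0")
    return max(0.05 * nh4_prior, 0.05)


def overspike_ratio(spike_15n: float, nh4_ambient: float) -> float:
    """Spike-to-ambient ratio; infinite when ambient NH₄⁺ is zero."""
    if nh4_ambient == 0:
        return math.inf
    return spike_15n / nh4_ambient


def _raw_rate(
    af_t0_mean: float,
    af_tf_mean: float,
    no2_initial_umol: float,
    t_hours: float,
    alpha: float,
) -> float:
    """Signed end-point rate (nmol L⁻¹ d⁻¹) from mean atom fractions on the
    N₂O measurement scale."""
    excess_no2 = azide_correction(af_tf_mean - af_t0_mean)
    no2_nmol = no2_initial_umol * 1000.0
    t_days = t_hours / 24.0
    return excess_no2 * no2_nmol / (t_days * alpha)


def compute_ao_rate(rec: IncubationRecord, calib: DeltaCalibration) -> RateEstimate:
    """Compute the AO rate for one incubation.

    Duplicate bottles are averaged on the atom-fraction scale after
    calibration; the initial (not final) NO₂⁻ concentration is used; negative
    raw estimates are reported as non-detects with rate 0.
    """
    if rec.no2_initial <= 0:
        raise ValueError("no2_initial must be > 0")
    if rec.t_incubation <= 0:
        raise ValueError("t_incubation must be > 0")
    af_t0 = delta_to_atom_fraction(calib.apply(np.asarray(rec.d15n_t0, dtype=float)))
    af_tf = delta_to_atom_fraction(calib.apply(np.asarray(rec.d15n_tf, dtype=float)))
    alpha = compute_alpha(rec.spike_15n, rec.nh4_ambient)
    raw = _raw_rate(
        float(np.mean(af_t0)),
        float(np.mean(af_tf)),
        rec.no2_initial,
        rec.t_incubation,
        alpha,
    )
    detected = raw >= 0
    ratio = overspike_ratio(rec.spike_15n, rec.nh4_ambient)
    return RateEstimate(
        sample_id=rec.sample_id,
        rate=raw if detected else 0.0,
        detected=detected,
        alpha=alpha,
        overspike_flag=ratio > OVERSPIKE_THRESHOLD,
        overspike_ratio=ratio,
        raw_rate=raw,
    )


def propagate_uncertainty(
    rec: IncubationRecord,
    calib: DeltaCalibration,
    n_draws: int = 1000,
    seed: int = 0,
    sigma_d15n: float = SIGMA_D15N,
    sigma_nh4: float = SIGMA_NH4,
    sigma_no2: float = SIGMA_NO2,
) -> float:
    """Monte-Carlo standard deviation of the raw rate under analytical noise.

    Independent Gaussian perturbations are applied per bottle to δ¹⁵N and to
    the NH₄⁺ and NO₂⁻ concentrations at the stated 1σ precisions, truncated at
    physical bounds (concentrations cannot go non-positive). The SD is taken
    over the signed (pre-non-detect) rates so that truncation at zero does not
    bias it.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng = np.random.default_rng(seed)
    d0 = calib.apply(np.asarray(rec.d15n_t0, dtype=float))
    df = calib.apply(np.asarray(rec.d15n_tf, dtype=float))
    # calibrated delta noise: measurement noise passes through the slope
    d0_draws = d0 + rng.normal(0.0, sigma_d15n * abs(calib.slope), (n_draws, d0.size))
    df_draws = df + rng.normal(0.0, sigma_d15n * abs(calib.slope), (n_draws, df.size))
    nh4 = np.clip(rng.normal(rec.nh4_ambient, sigma_nh4, n_draws), 0.0, None)
    no2 = np.clip(rng.normal(rec.no2_initial, sigma_no2, n_draws), 1e-9, None)
    af0 = delta_to_atom_fraction(np.clip(d0_draws, -1000.0, None)).mean(axis=1)
    aff = delta_to_atom_fraction(np.clip(df_draws, -1000.0, None)).mean(axis=1)
    alpha = rec.spike_15n / (rec.spike_15n + nh4)
    rates = (
        2.0 * (aff - af0) * no2 * 1000.0 / ((rec.t_incubation / 24.0) * alpha)
    )
    if sigma_d15n == 0 and sigma_nh4 == 0 and sigma_no2 == 0:
        return 0.0
    return float(np.std(rates, ddof=1))
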