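"""Radiotracer weak-acid uptake analysis.

Passive diffusion of a weak acid (acetic acid, pKa 4.8) into cells is
measured by mixing a carbon-14 labelled tracer with unlabelled acid,
sampling the cell suspension over time, and counting the retained
radioactivity on filters.  The analysis chain is:

scintillation counts (CPM)
  -> blank/background-corrected nmol via a linear calibration with standards
  -> intracellular amount (nmol per mg cell dry weight)
  -> intracellular concentration (mM; cell volume 2 uL per mg dry weight)
  -> accumulation factor A = c_in / c_out
  -> intracellular pH via the Henderson-Hasselbalch relation.

At diffusion equilibrium the undissociated acid concentration is equal on
both sides of the membrane, so the accumulation factor of *total* acid
implies the intracellular pH:

    pH_i = pKa + log10(A / f_out - 1),   f_out = 1 / (1 + 10**(pH_out - pKa))

where f_out is the undissociated fraction outside.  Initial diffusion rates
are zero-intercept slopes over early time points, and the diffusion
constant of a condition is the zero-intercept slope of rate versus the
extracellular acid amount.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import AnalysisError, CalibrationError


@dataclass(frozen=True)
class AcidConstants:
    """Weak-acid and assay constants.

    ``cell_volume_uL_per_mg`` converts amounts per mg dry weight into
    intracellular concentrations: nmol/mg divided by uL/mg is mM exactly.
    """

    pka: float = 4.8
    ph_out: float = 5.0
    cell_volume_uL_per_mg: float = 2.0

    def __post_init__(self):
        if not 0 < self.pka < 14:
            raise AnalysisError("pKa must lie in (0, 14)")


@dataclass
class UptakeSample:
    """One filtered aliquot of the uptake assay."""

    condition_id: str
    time_s: float
    cpm: float
    cell_dry_weight_mg: float
    extracellular_mM: float
    replicate: int = 0

    def __post_init__(self):
        if self.cpm < 0 or self.time_s < 0:
            raise AnalysisError("cpm and time must be non-negative")
        if self.cell_dry_weight_mg <= 0:
            raise AnalysisError("cell dry weight must be positive")


@dataclass
class CalibrationCurve:
    """Linear CPM-vs-nmol calibration with per-condition blank corrections.

    Counting efficiency and the labelled:total dilution of the acid mixture
    are folded into the slope because the standards are prepared from the
    same mixture and counted in the same counter.
    """

    slope_cpm_per_nmol: float
    intercept_cpm: float
    r_squared: float
    background_cpm: float = 0.0
    blanks: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.slope_cpm_per_nmol <= 0:
            raise CalibrationError("calibration slope must be positive")


def calibrate(standards, background_cpm: float = 0.0, blanks=None) -> CalibrationCurve:
    """Least-squares line through background-corrected (nmol, cpm) standards.

    Warns when r^2 < 0.99 — the counting response is expected to be linear
    over the evaluated range.
    """
    pairs = list(standards)
    if len(pairs) < 2:
        raise CalibrationError("at least 2 calibration standards required")
    nmol = np.array([p[0] for p in pairs], dtype=float)
    cpm = np.array([p[1] for p in pairs], dtype=float) - background_cpm
    if np.unique(nmol).size < 2:
        raise CalibrationError("standards must span at least 2 distinct amounts")
    fit = stats.linregress(nmol, cpm)
    r2 = float(fit.rvalue**2)
    if r2 < 0.99:
        warnings.warn(
            f"calibration r^2 = {r2:.4f} < 0.99: counting response may be "
            "non-linear",
            stacklevel=2,
        )
    return CalibrationCurve(
        slope_cpm_per_nmol=float(fit.slope),
        intercept_cpm=float(fit.intercept),
        r_squared=r2,
        background_cpm=background_cpm,
        blanks=dict(blanks or {}),
    )


def intracellular_amount(sample: UptakeSample, cal: CalibrationCurve) -> float:
    """Intracellular acid in nmol per mg dry weight for one sample.

    Counts are corrected for background and for adsorption on filter and
    cell surface (the condition's blank); a correction overshooting the
    signal floors at zero with a warning, since blanks can exceed small
    signals at the earliest time points.
    """
    if sample.condition_id not in cal.blanks:
        raise CalibrationError(f"missing blank for condition {sample.condition_id!r}")
    corrected = sample.cpm - cal.background_cpm - cal.blanks[sample.condition_id]
    if corrected < 0:
        warnings.warn(
            f"corrected counts negative ({corrected:.1f} cpm) for condition "
            f"{sample.condition_id!r} at t={sample.time_s:g}s; flooring at 0",
            stacklevel=2,
        )
        corrected = 0.0
    nmol = corrected / cal.slope_cpm_per_nmol
    return nmol / sample.cell_dry_weight_mg


def to_concentration(amount_nmol_per_mg: float, k: AcidConstants = AcidConstants()) -> float:
    """Convert nmol per mg dry weight to intracellular mM."""
    if amount_nmol_per_mg < 0:
        raise AnalysisError("amount must be non-negative")
    return amount_nmol_per_mg / k.cell_volume_uL_per_mg


def accumulation_factor(c_in_mM: float, c_out_mM: float) -> float:
    """Fold accumulation: intracellular over extracellular total acid."""
    if c_out_mM <= 0:
        raise AnalysisError("extracellular concentration must be positive")
    return c_in_mM / c_out_mM


def undissociated_fraction(ph: float, pka: float) -> float:
    """Fraction of the acid in the protonated (membrane-permeant) form."""
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def intracellular_ph(
    accumulation: float,
    ph_out: float | None = None,
    k: AcidConstants = AcidConstants(),
) -> float:
    """Intracellular pH implied by a fold accumulation of total acid.

    Solves the equilibrium condition [HA]_in = [HA]_out for pH_i.  An
    accumulation of 1 returns pH_out exactly; values at or below the
    undissociated fraction outside have no real solution (the acid cannot
    be *less* concentrated inside than the permeant form alone allows).
    """
    if ph_out is None:
        ph_out = k.ph_out
    f_out = undissociated_fraction(ph_out, k.pka)
    if accumulation <= f_out:
        raise AnalysisError(
            f"accumulation {accumulation:g} at or below the equilibrium floor "
            f"{f_out:.3f}: no real pH solution"
        )
    return k.pka + math.log10(accumulation / f_out - 1.0)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


def _zero_intercept_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin with its standard error."""
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise AnalysisError("degenerate regressor: all x are zero")
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    if len(x) > 1:
        se = math.sqrt(float(np.dot(resid, resid)) / (len(x) - 1) / sxx)
    else:
        se = float("nan")
    return slope, se


def initial_rate(times_s, amounts_nmol_per_mg, t_max_s: float = 30.0) -> float:
    """Initial uptake rate (nmol per mg dry weight per second).

    Passive diffusion has zero uptake at time zero, so the early points are
    fit with a zero-intercept line; a single early point reduces to
    amount/time.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(amounts_nmol_per_mg, dtype=float)
    mask = (t > 0) & (t <= t_max_s)
    if not mask.any():
        raise AnalysisError(f"no points at or before t = {t_max_s:g} s")
    slope, _ = _zero_intercept_slope(t[mask], y[mask])
    return slope


def diffusion_constant(extracellular_nmol, rates) -> tuple[float, float]:
    """Zero-intercept slope of rate vs extracellular acid amount, with SE."""
    x = np.asarray(extracellular_nmol, dtype=float)
    y = np.asarray(rates, dtype=float)
    if len(x) < 2:
        raise AnalysisError("at least 2 extracellular amounts required")
    return _zero_intercept_slope(x, y)


def compare_conditions(a, b, alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided Welch t-test between replicate rates of two conditions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("at least 2 replicates per condition required")
    if np.ptp(a) == 0 and np.ptp(b) == 0:  # two exactly-constant samples
        p = 1.0 if a[0] == b[0] else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p, p < alpha


def fit_first_order(times_s, values) -> tuple[float, float]:
    """Fit y(t) = plateau * (1 - exp(-k t)); returns (plateau, k).

    The first-order approach to diffusion equilibrium; used to recover the
    equilibrium level and rate constant from a full time course.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 3:
        raise AnalysisError("at least 3 time points required for a kinetic fit")
    plateau0 = float(y.max()) if y.max() > 0 else 1.0
    k0 = 1.0 / max(float(t[np.argmax(y > 0.5 * plateau0)]), 1e-6)
    popt, _ = optimize.curve_fit(
        lambda tt, plateau, k: plateau * (1.0 - np.exp(-k * tt)),
        t,
        y,
        p0=(plateau0, k0),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# Condition-level analysis
# ---------------------------------------------------------------------------


@dataclass
class UptakeResult:
    """Full analysis of one condition's uptake time course."""

    condition_id: str
    times_s: np.ndarray
    amounts_nmol_per_mg: np.ndarray  # replicate-averaged per time point
    concentrations_mM: np.ndarray
    accumulation: float
    ph_i: float | None
    initial_rate_nmol_per_mg_s: float
    plateau_mM: float
    rate_constant_per_s: float


def analyze_condition(
    samples,
    cal: CalibrationCurve,
    constants: AcidConstants = AcidConstants(),
    t_max_s: float = 30.0,
) -> UptakeResult:
    """Run the whole count-to-pH chain for one condition's samples."""
    samples = list(samples)
    if not samples:
        raise AnalysisError("no samples provided")
    cond = samples[0].condition_id
    if any(s.condition_id != cond for s in samples):
        raise AnalysisError("samples span multiple conditions")
    c_out = samples[0].extracellular_mM
    by_time: dict[float, list[float]] = {}
    for s in samples:
        by_time.setdefault(s.time_s, []).append(intracellular_amount(s, cal))
    times = np.array(sorted(by_time))
    amounts = np.array([float(np.mean(by_time[t])) for t in times])
    concs = amounts / constants.cell_volume_uL_per_mg
    plateau, k_rate = fit_first_order(times, concs)
    acc = accumulation_factor(plateau, c_out)
    try:
        ph_i = intracellular_ph(acc, k=constants)
    except AnalysisError:
        ph_i = None
    rate = initial_rate(times, amounts, t_max_s)
    return UptakeResult(
        condition_id=cond,
        times_s=times,
        amounts_nmol_per_mg=amounts,
        concentrations_mM=concs,
        accumulation=acc,
        ph_i=ph_i,
        initial_rate_nmol_per_mg_s=rate,
        plateau_mM=plateau,
        rate_constant_per_s=k_rate,
    )
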