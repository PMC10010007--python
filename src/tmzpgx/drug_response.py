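"""Growth-rate-inhibition (GR) dose-response metrics and sensitivity calls.

Conventional potency metrics (IC50, Emax) confound drug effect with division
rate, which differs widely between patient-derived glioma stem-like cell (GSC)
cultures.  GR metrics normalise the treated endpoint against both the vehicle
control and the treatment-start cell count, so that GR = 1 means no effect,
GR = 0 complete cytostasis and GR < 0 net cell loss:

    GR(c) = 2^( log2(x(c)/x0) / log2(x_ctrl/x0) ) - 1

A four-parameter sigmoid is fitted to the per-concentration GR values,

    GR(c) = GRinf + (1 - GRinf) / (1 + (c / GEC50)^h),

and GR50 — the concentration at which GR crosses 0.5 — follows in closed form

    GR50 = GEC50 * ((1 - GRinf)/(0.5 - GRinf) - 1)^(1/h)     (GRinf < 0.5),

or is infinite when the curve never reaches 0.5.  Samples with infinite GR50
fall back to the traditional area under the relative-viability curve (AUC).
A screening cohort is then split into resistant / sensitive groups by
standard scores: z of log10(GR50) among finite-GR50 samples, z of AUC for the
rest, resistant when the governing z exceeds a threshold (default 0; higher
GR50 or higher AUC means more resistant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponsePlate",
    "GrMetrics",
    "SensitivityCall",
    "GrCurveModel",
    "compute_gr_values",
    "fit_gr_curve",
    "gr50_from_fit",
    "traditional_auc",
    "classify_sensitivity",
    "DEFAULT_CONCENTRATIONS_UM",
]

#: Seven-point fourfold serial dilution, 500 uM down to 0.122 uM.
DEFAULT_CONCENTRATIONS_UM = tuple(500.0 / 4.0 ** k for k in range(7))[::-1]

#: Default seeding density (cells/well) used as the time-zero reference when
#: no day-0 plate was measured.
DEFAULT_SEEDING_SIGNAL = 500.0


class DegenerateGrowthError(ValueError):
    """Control did not grow past the time-zero reference; GR is undefined."""


class InsufficientDataError(ValueError):
    """Too few concentrations for the requested computation."""


@dataclass(frozen=True)
class DoseResponsePlate:
    """Replicate-averaged endpoint readout for one sample.

    Parameters
    ----------
    sample_id : str
    concentrations : array-like
        Tested drug concentrations in uM, strictly positive and increasing.
    viability : array-like
        Endpoint signal at each concentration (e.g. luminescence).
    control_signal : float
        Vehicle-control endpoint signal.
    t0_signal : float
        Treatment-start reference signal; defaults to the seeding density.
    """

    sample_id: str
    concentrations: np.ndarray
    viability: np.ndarray
    control_signal: float
    t0_signal: float = DEFAULT_SEEDING_SIGNAL

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        viab = np.asarray(self.viability, dtype=float)
        if conc.ndim != 1 or viab.shape != conc.shape:
            raise ValueError("concentrations and viability must be 1-D and aligned")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(viab <= 0) or self.control_signal <= 0 or self.t0_signal <= 0:
            raise ValueError("all signals must be positive")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "viability", viab)


@dataclass(frozen=True)
class GrMetrics:
    """Fitted GR curve parameters and derived potency metrics for one sample."""

    sample_id: str
    concentrations: np.ndarray
    gr_values: np.ndarray
    gec50: float
    grinf: float
    hill: float
    gr50: float  # uM, or math.inf when the curve never crosses GR = 0.5
    auc_traditional: float
    fit_converged: bool = True

    @property
    def gr50_is_finite(self) -> bool:
        return math.isfinite(self.gr50)


@dataclass(frozen=True)
class SensitivityCall:
    """Cohort z-scores and the resistant/sensitive label for one sample."""

    sample_id: str
    z_gr50: float  # NaN when GR50 is infinite
    z_auc: float
    metric_used: str  # "gr50" or "auc"
    label: str  # "resistant" or "sensitive"


def compute_gr_values(plate: DoseResponsePlate) -> np.ndarray:
    """GR value at each tested concentration.

    Raises
    ------
    DegenerateGrowthError
        If the vehicle control did not exceed the time-zero signal.
    """
    if plate.control_signal <= plate.t0_signal:
        raise DegenerateGrowthError(
            f"{plate.sample_id}: control signal {plate.control_signal} did not "
            f"exceed t0 signal {plate.t0_signal}; growth rate is undefined"
        )
    log_growth = np.log2(plate.viability / plate.t0_signal)
    log_ctrl = np.log2(plate.control_signal / plate.t0_signal)
    return 2.0 ** (log_growth / log_ctrl) - 1.0


def _gr_sigmoid(c, gec50, grinf, hill):
    return grinf + (1.0 - grinf) / (1.0 + (c / gec50) ** hill)


def gr50_from_fit(gec50: float, grinf: float, hill: float) -> float:
    """Closed-form GR50 of the fitted sigmoid; ``inf`` if GR never reaches 0.5."""
    if grinf >= 0.5:
        return math.inf
    ratio = (1.0 - grinf) / (0.5 - grinf) - 1.0
    if ratio <= 0:
        return math.inf
    return gec50 * ratio ** (1.0 / hill)


def fit_gr_curve(
    concentrations,
    gr_values,
    sample_id: str = "",
    auc: float = np.nan,
) -> GrMetrics:
    """Least-squares fit of the GR sigmoid to per-concentration GR values.

    Bounds keep the Hill slope in [0.1, 10] and GEC50 within 100x of the
    tested concentration range; the fit is initialised at the median tested
    concentration, the minimum observed GR and a unit slope.  If the
    optimiser fails, a flat-curve summary (GRinf = mean GR, infinite GR50)
    is returned with ``fit_converged=False``.
    """
    conc = np.asarray(concentrations, dtype=float)
    gr = np.asarray(gr_values, dtype=float)
    if np.unique(conc).size < 4:
        raise InsufficientDataError("GR curve fitting needs >= 4 distinct concentrations")

    lo = np.array([conc.min() / 100.0, -1.0, 0.1])
    hi = np.array([conc.max() * 100.0, 1.0, 10.0])
    p0 = np.array([np.median(conc), float(np.clip(gr.min(), -1.0, 1.0)), 1.0])
    p0 = np.clip(p0, lo, hi)
    try:
        popt, _ = curve_fit(
            _gr_sigmoid, conc, gr, p0=p0, bounds=(lo, hi), maxfev=10000
        )
        gec50, grinf, hill = (float(v) for v in popt)
        converged = True
    except (RuntimeError, ValueError):
        gec50, grinf, hill = math.inf, float(np.mean(gr)), 1.0
        converged = False

    return GrMetrics(
        sample_id=sample_id,
        concentrations=conc,
        gr_values=gr,
        gec50=gec50,
        grinf=grinf,
        hill=hill,
        gr50=gr50_from_fit(gec50, grinf, hill) if converged else math.inf,
        auc_traditional=float(auc),
        fit_converged=converged,
    )


def traditional_auc(plate: DoseResponsePlate) -> float:
    """Normalised area under the relative-viability curve.

    Trapezoidal area of treated/control viability over log10 concentration,
    divided by the log-concentration span, so a no-effect curve scores 1 and
    complete kill at every dose scores 0.
    """
    if plate.concentrations.size < 2:
        raise InsufficientDataError("AUC needs at least two concentrations")
    rel = plate.viability / plate.control_signal
    logc = np.log10(plate.concentrations)
    area = np.trapezoid(rel, logc)
    return float(area / (logc[-1] - logc[0]))


class GrCurveModel:
    """Model object tying a plate to its GR metrics (fit() -> GrMetrics)."""

    def __init__(self, plate: DoseResponsePlate):
        self.plate = plate

    def fit(self) -> GrMetrics:
        gr = compute_gr_values(self.plate)
        auc = traditional_auc(self.plate)
        return fit_gr_curve(
            self.plate.concentrations, gr, sample_id=self.plate.sample_id, auc=auc
        )


def _zscores(values: np.ndarray) -> np.ndarray:
    """Standard scores; a constant series collapses to all-zero z."""
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def classify_sensitivity(
    metrics: list[GrMetrics], z_threshold: float = 0.0
) -> list[SensitivityCall]:
    """Split a screening cohort into resistant / sensitive by standard scores.

    z of log10(GR50) is computed over samples with finite GR50 (GR50 spans
    decades, hence the log scale); z of AUC over all samples.  A sample is
    labelled resistant when its governing z — z_gr50 for finite-GR50 samples,
    z_auc otherwise — strictly exceeds ``z_threshold``.  Higher AUC means
    more surviving cells, so the AUC z needs no sign flip.
    """
    finite = [m for m in metrics if m.gr50_is_finite]
    if len(finite) < 2:
        raise ValueError("need >= 2 samples with finite GR50 to standardise")
    gr50_vals = np.log10([m.gr50 for m in finite])
    auc_vals = np.array([m.auc_traditional for m in metrics])
    if gr50_vals.std(ddof=1) == 0 and auc_vals.std(ddof=1) == 0:
        raise ValueError(
            "zero variance in both metrics: the cohort carries no ordering"
        )
    log_gr50 = _zscores(gr50_vals)
    z_gr50 = {m.sample_id: z for m, z in zip(finite, log_gr50)}
    z_auc_all = _zscores(auc_vals)

    calls = []
    for m, z_auc in zip(metrics, z_auc_all):
        if m.gr50_is_finite:
            metric_used, governing = "gr50", z_gr50[m.sample_id]
        else:
            metric_used, governing = "auc", z_auc
        calls.append(
            SensitivityCall(
                sample_id=m.sample_id,
                z_gr50=z_gr50.get(m.sample_id, math.nan),
                z_auc=float(z_auc),
                metric_used=metric_used,
                label="resistant" if governing > z_threshold else "sensitive",
            )
        )
    return calls
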