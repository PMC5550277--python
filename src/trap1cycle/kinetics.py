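"""First-order kinetic fitting and rate arithmetic for chaperone ATPase assays.

This module holds the shared currency of all assay analysis in the package:
timestamped signal traces (:class:`KineticTrace`), exponential fits with an
optional linear steady-state term, Hill titration fits, initial-rate
estimation in the linear regime of a trace, phosphate-sensor calibration with
a detector-linearity cap, the NADH-coupled absorbance-to-rate conversion, and
derived quantities such as the time to hydrolyze a given fraction of substrate
(t90 = ln(10)/k) and per-site <-> per-dimer rate-basis conversion.

All fits are unweighted least squares (via lmfit) with documented initial
guesses: the rate constant from the half-rise time, the amplitude from the
signal range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np

from .units import TIME_UNITS, check_time_unit, convert_rate, convert_time

SIGNAL_KINDS = {
    "fret_ratio",
    "delta_fret",
    "rfu",
    "absorbance",
    "fraction_hydrolyzed",
    "concentration_uM",
}


@dataclass
class KineticTrace:
    """A timestamped signal series with declared units and signal kind."""

    times: np.ndarray
    values: np.ndarray
    time_unit: str = "min"
    kind: str = "rfu"
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        check_time_unit(self.time_unit)
        if self.kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have the same length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_unit(self, unit: str) -> "KineticTrace":
        """Return a copy with times expressed in ``unit``."""
        return KineticTrace(
            convert_time(self.times, self.time_unit, unit),
            self.values.copy(),
            time_unit=unit,
            kind=self.kind,
            label=self.label,
        )


@dataclass
class ExpFit:
    """Result of a single-exponential fit, optionally with a linear term.

    The model is ``offset + amplitude*(1 - exp(-k*t))`` for buildup
    (``direction='rise'``) or ``offset + amplitude*exp(-k*t)`` for decay,
    plus ``linear_slope*t`` when the linear term is enabled.  ``k`` is in
    the trace's declared time unit.
    """

    amplitude: float
    k: float
    offset: float
    linear_slope: Optional[float]
    amplitude_se: float
    k_se: float
    offset_se: float
    linear_slope_se: Optional[float]
    converged: bool
    rss: float
    direction: str
    time_unit: str


@dataclass
class HillFit:
    half_max: float
    hill_n: float
    response_max: float
    baseline: float
    half_max_se: float
    hill_n_se: float
    response_max_se: float
    baseline_se: float
    converged: bool
    rss: float


@dataclass
class RateConstant:
    """A first-order rate constant with declared time unit and site basis."""

    value: float
    unit: str = "per_hr"  # "per_hr" | "per_min" | "per_s" | "per_day"
    basis: str = "none"  # "per_site" | "per_dimer" | "none"

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("rate constant must be >= 0")
        if not self.unit.startswith("per_") or self.unit[4:] not in TIME_UNITS:
            raise ValueError(f"unknown rate unit {self.unit!r}")
        if self.basis not in ("per_site", "per_dimer", "none"):
            raise ValueError(f"unknown basis {self.basis!r}")

    @property
    def time_unit(self) -> str:
        return self.unit[4:]

    def to_unit(self, unit: str) -> "RateConstant":
        u = unit[4:] if unit.startswith("per_") else unit
        return RateConstant(convert_rate(self.value, self.time_unit, u), f"per_{u}", self.basis)


@dataclass
class Calibration:
    """Linear phosphate-sensor standard curve, RFU = intercept + slope * [Pi].

    Only standards below the detector-linearity cap enter the fit.
    """

    slope: float  # RFU per µM
    intercept: float  # RFU at zero analyte
    linear_cap: float  # RFU
    points_used: int
    excluded: int = 0
    slope_se: float = float("nan")
    intercept_se: float = float("nan")


@dataclass
class InitialRate:
    """Linear-regime slope of a trace (signal units per time unit)."""

    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    window: tuple[int, int]  # [start, stop) indices of the fitted prefix
    fallback: bool
    time_unit: str


def _stderr(param) -> float:
    return float(param.stderr) if param.stderr is not None else float("nan")


def _guess_k(t: np.ndarray, y: np.ndarray, direction: str) -> float:
    """Rate guess from the half-change time of the trace."""
    y0, yend = y[0], y[-1]
    half = 0.5 * (y0 + yend)
    crossing = np.nonzero((y - half) * (y0 - half) <= 0)[0]
    span = t[-1] - t[0]
    if len(crossing) == 0 or t[crossing[0]] <= t[0]:
        return 3.0 / span if span > 0 else 1.0
    t_half = t[crossing[0]] - t[0]
    return math.log(2.0) / t_half if t_half > 0 else 3.0 / span


def fit_exponential(
    trace: KineticTrace,
    with_linear_term: bool = False,
    direction: str = "rise",
) -> ExpFit:
    """Fit ``offset + A*(1-exp(-k t)) [+ slope*t]`` (or the decay form) to a trace.

    Requires at least one more point than free parameters (>=4 points, >=5
    with the linear term).  Non-convergence is flagged on the result, with the
    parameters still reported and a warning emitted.
    """
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be 'rise' or 'decay'")
    n_par = 4 if with_linear_term else 3
    if len(trace) < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} points for this fit, got {len(trace)}")

    t, y = trace.times, trace.values

    def base(t, amplitude, k, offset):
        if direction == "rise":
            return offset + amplitude * (1.0 - np.exp(-k * t))
        return offset + amplitude * np.exp(-k * t)

    if with_linear_term:
        def model(t, amplitude, k, offset, linear_slope):
            return base(t, amplitude, k, offset) + linear_slope * t
    else:
        model = base

    params = lmfit.Parameters()
    rng_y = float(y[-1] - y[0])
    amp0 = rng_y if direction == "rise" else -rng_y
    params.add("amplitude", value=amp0)
    params.add("k", value=_guess_k(t, y, direction), min=0.0)
    params.add("offset", value=float(y[0]) if direction == "rise" else float(y[-1]))
    if with_linear_term:
        params.add("linear_slope", value=0.0)

    mod = lmfit.Model(model, independent_vars=["t"])
    result = mod.fit(y, params=params, t=t)
    if not result.success:
        warnings.warn("exponential fit did not converge; parameters reported anyway")
    p = result.params
    return ExpFit(
        amplitude=float(p["amplitude"].value),
        k=float(p["k"].value),
        offset=float(p["offset"].value),
        linear_slope=float(p["linear_slope"].value) if with_linear_term else None,
        amplitude_se=_stderr(p["amplitude"]),
        k_se=_stderr(p["k"]),
        offset_se=_stderr(p["offset"]),
        linear_slope_se=_stderr(p["linear_slope"]) if with_linear_term else None,
        converged=bool(result.success),
        rss=float(np.sum(result.residual**2)),
        direction=direction,
        time_unit=trace.time_unit,
    )


def fit_hill(concentrations, responses) -> HillFit:
    """Fit ``baseline + Rmax * c^n / (K^n + c^n)`` to a titration.

    ``K`` is the half-max concentration.  Degenerate (flat) responses are
    rejected with a diagnostic.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(c) != len(y):
        raise ValueError("concentrations and responses must have the same length")
    if len(c) < 5:
        raise ValueError("need at least 5 points for a Hill fit")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if np.allclose(c, c[0]):
        raise ValueError("concentrations must not all be equal")
    y_span = float(np.max(y) - np.min(y))
    if y_span <= 1e-12 * max(1.0, abs(float(np.max(y)))):
        raise ValueError("flat response: no titration signal to fit")

    def model(c, half_max, hill_n, response_max, baseline):
        cn = np.power(np.clip(c, 0, None), hill_n)
        return baseline + response_max * cn / (np.power(half_max, hill_n) + cn)

    order = np.argsort(c)
    cs, ys = c[order], y[order]
    half_level = ys[0] + 0.5 * (ys[-1] - ys[0])
    # concentration where the response first crosses half its span
    idx = np.nonzero((ys - half_level) * (ys[0] - half_level) <= 0)[0]
    k0 = float(cs[idx[0]]) if len(idx) and cs[idx[0]] > 0 else float(np.median(cs[cs > 0]))

    params = lmfit.Parameters()
    params.add("half_max", value=k0, min=1e-12)
    params.add("hill_n", value=1.0, min=1e-6)
    params.add("response_max", value=float(ys[-1] - ys[0]))
    params.add("baseline", value=float(ys[0]))
    result = lmfit.Model(model, independent_vars=["c"]).fit(y, params=params, c=c)
    if not result.success:
        warnings.warn("Hill fit did not converge; parameters reported anyway")
    p = result.params
    return HillFit(
        half_max=float(p["half_max"].value),
        hill_n=float(p["hill_n"].value),
        response_max=float(p["response_max"].value),
        baseline=float(p["baseline"].value),
        half_max_se=_stderr(p["half_max"]),
        hill_n_se=_stderr(p["hill_n"]),
        response_max_se=_stderr(p["response_max"]),
        baseline_se=_stderr(p["baseline"]),
        converged=bool(result.success),
        rss=float(np.sum(result.residual**2)),
    )


def _linfit(t: np.ndarray, y: np.ndarray):
    """Least-squares line; returns slope, intercept, slope SE, R^2."""
    n = len(t)
    A = np.vstack([t, np.ones(n)]).T
    coef, res, _, _ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    if n > 2 and ss_res > 0:
        sxx = float(np.sum((t - np.mean(t)) ** 2))
        se = math.sqrt(ss_res / (n - 2) / sxx)
    else:
        se = 0.0
    return float(coef[0]), float(coef[1]), se, r2


def initial_rate(
    trace: KineticTrace, r2_threshold: float = 0.995, min_points: int = 5
) -> InitialRate:
    """Slope of the longest prefix of a trace that is still linear.

    The linear regime is taken as the longest prefix (at least ``min_points``
    long) whose linear fit has R^2 >= ``r2_threshold``.  If no prefix
    qualifies, the first ``min_points`` points are used and a warning emitted.
    """
    if len(trace) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(trace)}")
    t, y = trace.times, trace.values
    best = None
    for n in range(min_points, len(t) + 1):
        slope, intercept, se, r2 = _linfit(t[:n], y[:n])
        if r2 >= r2_threshold:
            best = (n, slope, intercept, se, r2)
    if best is None:
        warnings.warn(
            "no prefix satisfies the linearity threshold; "
            f"falling back to the first {min_points} points"
        )
        slope, intercept, se, r2 = _linfit(t[:min_points], y[:min_points])
        best = (min_points, slope, intercept, se, r2)
        fallback = True
    else:
        fallback = False
    n, slope, intercept, se, r2 = best
    return InitialRate(slope, se, intercept, r2, (0, n), fallback, trace.time_unit)


def t_fraction(k, fraction: float) -> float:
    """Time for a first-order process to consume ``fraction`` of its substrate.

    ``t = -ln(1 - fraction) / k``; for fraction 0.9 this is the familiar
    t90 = ln(10)/k.  ``k`` may be a number or a :class:`RateConstant`; the
    returned time is in k's time unit.
    """
    k_value = k.value if isinstance(k, RateConstant) else float(k)
    if k_value <= 0:
        raise ValueError("rate constant must be > 0")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be strictly between 0 and 1")
    return -math.log1p(-fraction) / k_value


def round_to_unit(time_value: float, from_unit: str, to_unit: str) -> int:
    """Reporting helper: convert a time and round half-to-even to an integer."""
    converted = convert_time(time_value, from_unit, to_unit)
    return int(round(converted))


def convert_rate_basis(rate: RateConstant, sites_per_dimer: int = 2) -> RateConstant:
    """Convert a rate between per-active-site and per-dimer bases.

    per_dimer = per_site * sites_per_dimer (two ATPase sites per homodimer).
    """
    if rate.basis == "per_site":
        return RateConstant(rate.value * sites_per_dimer, rate.unit, "per_dimer")
    if rate.basis == "per_dimer":
        return RateConstant(rate.value / sites_per_dimer, rate.unit, "per_site")
    raise ValueError("rate basis must be per_site or per_dimer for conversion")


def fret_ratio_trace(donor: KineticTrace, acceptor: KineticTrace) -> KineticTrace:
    """Change in FRET: acceptor/donor ratio relative to the first time point.

    The donor and acceptor channels must share an identical time grid; the
    output value at the first time point is exactly 0.
    """
    if donor.time_unit != acceptor.time_unit or not np.array_equal(donor.times, acceptor.times):
        raise ValueError("donor and acceptor traces must share an identical time grid")
    if np.any(donor.values <= 0):
        raise ValueError("donor values must be strictly positive")
    ratio = acceptor.values / donor.values
    return KineticTrace(
        donor.times.copy(),
        ratio - ratio[0],
        time_unit=donor.time_unit,
        kind="delta_fret",
        label=donor.label or acceptor.label,
    )


def fit_phosphate_calibration(
    pi_concentrations, rfu, linear_cap: float = 20000.0
) -> Calibration:
    """Fit the phosphate standard curve on points below the linearity cap.

    Standards at or above ``linear_cap`` RFU are excluded from the fit and
    counted in ``excluded``; at least 3 usable points are required.
    """
    c = np.asarray(pi_concentrations, dtype=float)
    f = np.asarray(rfu, dtype=float)
    if len(c) != len(f):
        raise ValueError("concentration and RFU arrays must have the same length")
    usable = f < linear_cap
    if int(np.sum(usable)) < 3:
        raise ValueError("need at least 3 standards below the linearity cap")
    slope, intercept, se, _ = _linfit(c[usable], f[usable])
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    # intercept SE from the same least-squares fit
    n = int(np.sum(usable))
    resid = f[usable] - (intercept + slope * c[usable])
    if n > 2 and np.sum(resid**2) > 0:
        sxx = float(np.sum((c[usable] - np.mean(c[usable])) ** 2))
        s2 = float(np.sum(resid**2)) / (n - 2)
        int_se = math.sqrt(s2 * (1.0 / n + np.mean(c[usable]) ** 2 / sxx))
    else:
        int_se = 0.0
    return Calibration(
        slope=slope,
        intercept=intercept,
        linear_cap=linear_cap,
        points_used=n,
        excluded=int(np.sum(~usable)),
        slope_se=se,
        intercept_se=int_se,
    )


def apply_calibration(cal: Calibration, trace: KineticTrace) -> KineticTrace:
    """Invert the standard curve: RFU trace -> phosphate concentration (µM)."""
    if trace.kind != "rfu":
        raise ValueError("calibration applies to RFU traces")
    conc = (trace.values - cal.intercept) / cal.slope
    return KineticTrace(
        trace.times.copy(), conc, time_unit=trace.time_unit,
        kind="concentration_uM", label=trace.label,
    )


def nadh_slope_to_atpase(
    slope_au_per_min: float, pathlength_cm: float, extinction: float = 6220.0
) -> float:
    """Convert an NADH absorbance slope (AU/min) to µM ATP hydrolyzed per min.

    The enzyme-coupled assay consumes one NADH per ATP; NADH absorbance at
    340 nm decreases, so the rate is reported positive.  The default
    extinction coefficient is the standard 6220 M^-1 cm^-1.
    """
    if pathlength_cm <= 0:
        raise ValueError("pathlength must be > 0")
    return abs(slope_au_per_min) / (extinction * pathlength_cm) * 1e6
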