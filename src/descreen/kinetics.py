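"""First-order deactivation/degradation kinetics and initial-rate arithmetic.

Enzyme inactivation and coenzyme (NADH) degradation in the screened solvent
systems both follow first-order kinetics: a signal A(t) — residual activity
in percent, or absorbance at 340 nm — decays as ``A(t) = A0 * exp(-k t)``.
The rate constant k and the half-life ``t_half = ln(2) / k`` are the
module's central quantities.

The single-time-point estimator ``k = ln(A0 / A(t)) / t`` is kept as a
diagnostic; the fit itself is nonlinear least squares with A0 estimated
jointly, which is robust to noise in the first observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DecayTimeSeries",
    "KineticFit",
    "FitError",
    "fit_first_order_decay",
    "half_life_from_rate",
    "rate_from_half_life",
    "single_point_rate",
    "initial_rate",
    "relative_activity",
    "MINUTES_PER_DAY",
]

MINUTES_PER_DAY = 1440.0

_TIME_UNITS = ("day", "minute")
_SIGNAL_KINDS = ("activity", "absorbance")


class FitError(RuntimeError):
    """The series cannot support a kinetic fit."""


@dataclass
class DecayTimeSeries:
    """A decaying (or rising, for initial-rate assays) signal over time."""

    times: np.ndarray
    values: np.ndarray
    time_unit: str = "day"
    signal_kind: str = "activity"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_unit not in _TIME_UNITS:
            raise ValueError(f"time_unit must be one of {_TIME_UNITS}")
        if self.signal_kind not in _SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {_SIGNAL_KINDS}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and the same length")
        if len(self.times) < 3:
            raise ValueError("need at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(self.values < 0):
            raise ValueError("signal values must be non-negative")


@dataclass
class KineticFit:
    """Result of a first-order decay fit.

    ``rate_constant`` is per the series' declared time unit; ``half_life``
    is in that unit (``math.inf`` when the rate constant is zero).
    """

    rate_constant: float
    half_life: float
    amplitude_at_zero: float
    goodness: float
    time_unit: str = "day"


def half_life_from_rate(rate_constant: float) -> float:
    """ln(2) / k, with +inf for k == 0; the unit is the reciprocal of k's."""
    if rate_constant < 0:
        raise ValueError("rate constant must be >= 0")
    if rate_constant == 0:
        return math.inf
    return math.log(2.0) / rate_constant


def rate_from_half_life(half_life: float) -> float:
    """ln(2) / t_half (inverse of :func:`half_life_from_rate`)."""
    if not half_life > 0:
        raise ValueError("half-life must be > 0")
    return math.log(2.0) / half_life


def single_point_rate(a0: float, a_t: float, t: float) -> float:
    """Single-time-point first-order estimator ``k = ln(a0 / a_t) / t``.

    Diagnostic oracle only; requires both signals strictly positive.
    """
    if a0 <= 0 or a_t <= 0:
        raise ValueError("signals must be strictly positive")
    if t <= 0:
        raise ValueError("t must be > 0")
    return math.log(a0 / a_t) / t


def fit_first_order_decay(series: DecayTimeSeries) -> KineticFit:
    """Fit ``A(t) = A0 exp(-k t)`` by nonlinear least squares with k >= 0.

    Initialisation uses the log-linear slope over strictly positive values;
    A0 is estimated jointly with k. Raises :class:`FitError` if the signal
    is identically zero.
    """
    t, y = series.times, series.values
    if not np.any(y > 0):
        raise FitError("signal identically zero")
    if np.ptp(y) == 0:
        # exactly constant signal: no decay, k is identically zero
        return KineticFit(
            rate_constant=0.0,
            half_life=math.inf,
            amplitude_at_zero=float(y[0]),
            goodness=1.0,
            time_unit=series.time_unit,
        )

    # log-linear initial guess on the positive part
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        k0 = max(-slope, 0.0)
        a0 = float(np.exp(intercept))
    else:
        k0, a0 = 0.0, float(y.max())
    a0 = max(a0, float(np.max(y)) * 1e-3, 1e-12)

    popt, _ = curve_fit(
        lambda tt, a, k: a * np.exp(-k * tt),
        t,
        y,
        p0=[a0, k0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    a_hat, k_hat = float(popt[0]), float(popt[1])

    resid = y - a_hat * np.exp(-k_hat * t)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0

    return KineticFit(
        rate_constant=k_hat,
        half_life=half_life_from_rate(k_hat),
        amplitude_at_zero=a_hat,
        goodness=r2,
        time_unit=series.time_unit,
    )


def initial_rate(series: DecayTimeSeries, window: float | None = 5.0) -> float:
    """Ordinary least-squares slope over the initial assay window.

    ``window`` is in the series' time unit (default 5, matching a 5-min
    plate-reader assay for series declared in minutes); ``None`` uses all
    points. At least 3 points must fall inside the window.
    """
    t, y = series.times, series.values
    if window is not None:
        mask = t <= t[0] + window
        t, y = t[mask], y[mask]
    if len(t) < 3:
        raise ValueError("fewer than 3 points in the assay window")
    slope = np.polyfit(t, y, 1)[0]
    return float(slope)


def relative_activity(rate: float, rate_reference: float) -> float:
    """Activity as a percentage of a reference rate: ``100 * rate / ref``."""
    if rate_reference <= 0:
        raise ValueError("reference rate must be > 0")
    return 100.0 * rate / rate_reference


def read_time_series(path) -> DecayTimeSeries:
    """Read a two-column (time, value) CSV with '# unit=' / '# signal=' headers."""
    import csv as _csv
    from pathlib import Path as _Path

    unit, signal = "day", "activity"
    rows: list[tuple[float, float]] = []
    with _Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta = line.lstrip("#").strip()
                if meta.startswith("unit="):
                    unit = meta.split("=", 1)[1].strip()
                elif meta.startswith("signal="):
                    signal = meta.split("=", 1)[1].strip()
                continue
            parts = next(_csv.reader([line]))
            if parts[0].lower() in ("time", "t"):
                continue
            rows.append((float(parts[0]), float(parts[1])))
    times, values = zip(*rows)
    return DecayTimeSeries(
        times=np.array(times), values=np.array(values), time_unit=unit, signal_kind=signal
    )


def write_time_series(series: DecayTimeSeries, path) -> None:
    from pathlib import Path as _Path

    lines = [f"# unit={series.time_unit}", f"# signal={series.signal_kind}", "time,value"]
    lines += [f"{float(t)!r},{float(v)!r}" for t, v in zip(series.times, series.values)]
    _Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
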