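"""Piecewise linear regression (PLR) with a response breakpoint, plus
chemometric validation metrics.

The QSAR model is two multiple-linear segments joined at a breakpoint b_n
defined on the *response*: observations with y <= b_n follow one
hyperplane, those with y > b_n another. Because segment membership during
fitting is determined by the observed response, the least-squares
coefficients for any fixed breakpoint are exactly the per-segment OLS
solutions; the joint nonlinear least-squares problem therefore profiles
down to a one-dimensional search over b_n, and the profile SSE is
piecewise constant between consecutive observed responses. Searching the
midpoints of consecutive sorted responses solves the joint problem
exactly — no iterative optimizer is needed.

At prediction time the observed response is unavailable: both segments are
evaluated and the self-consistent one (low-segment value <= b_n, or
high-segment value > b_n) is returned; if neither or both are consistent,
the value closest to the breakpoint wins (configurable, documented
tie-break).

Validation follows standard chemometric practice on a random
calibration/prediction split: R^2, adjusted R^2, RMSE on both sets, plus
RPD (prediction-set SD over RMSEP) and RER (prediction-set range over
RMSEP) with their conventional qualitative thresholds.
"""

from __future__ import annotations

import json
import math
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLRModel",
    "ModelMetrics",
    "split_calibration_prediction",
    "fit_plr",
    "predict_plr",
    "evaluate_model",
    "interpret_metrics",
    "published_model",
    "PUBLISHED_MODEL_NAMES",
]

PUBLISHED_MODEL_NAMES = ("fdh_activity", "fdh_half_life", "nadh_half_life")


@dataclass
class PLRModel:
    """Two coefficient vectors (intercept first) joined at a response breakpoint."""

    input_names: list[str]
    coef_low: np.ndarray       # segment y <= breakpoint
    coef_high: np.ndarray      # segment y > breakpoint
    breakpoint: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coef_low = np.asarray(self.coef_low, dtype=float)
        self.coef_high = np.asarray(self.coef_high, dtype=float)
        want = 1 + len(self.input_names)
        if self.coef_low.shape != (want,) or self.coef_high.shape != (want,):
            raise ValueError(
                f"coefficient vectors must have length {want} (intercept + inputs)"
            )
        if not math.isfinite(self.breakpoint):
            raise ValueError("breakpoint must be finite")

    def segment_values(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate both hyperplanes on a design matrix (rows = samples)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.input_names):
            raise ValueError("design matrix width does not match input_names")
        design = np.hstack([np.ones((X.shape[0], 1)), X])
        return design @ self.coef_low, design @ self.coef_high

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_names": self.input_names,
                "coef_low": self.coef_low.tolist(),
                "coef_high": self.coef_high.tolist(),
                "breakpoint": self.breakpoint,
                "provenance": self.provenance,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PLRModel":
        d = json.loads(text)
        return cls(
            input_names=list(d["input_names"]),
            coef_low=np.asarray(d["coef_low"]),
            coef_high=np.asarray(d["coef_high"]),
            breakpoint=float(d["breakpoint"]),
            provenance=d.get("provenance", ""),
        )


@dataclass
class ModelMetrics:
    """Calibration/prediction R^2 (plain and adjusted), RMSEs, RPD and RER."""

    r2_cal: float
    r2_cal_adj: float
    rmsec: float
    r2_pred: float = math.nan
    r2_pred_adj: float = math.nan
    rmsep: float = math.nan
    rpd: float = math.nan
    rer: float = math.nan


def split_calibration_prediction(
    table: pd.DataFrame, ratio: float = 0.7, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reproducible random row split; calibration gets floor(ratio * n) rows."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly inside (0, 1)")
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    n_cal = int(math.floor(ratio * n))
    if n_cal == 0 or n_cal == n:
        raise ValueError("split leaves an empty partition")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    cal = table.iloc[np.sort(order[:n_cal])]
    pred = table.iloc[np.sort(order[n_cal:])]
    return cal, pred


def _segment_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    design = np.hstack([np.ones((X.shape[0], 1)), X])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    sse = float(np.sum((y - design @ coef) ** 2))
    return coef, sse


def fit_plr(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    input_names: list[str] | None = None,
    min_segment_fraction: float = 0.1,
) -> tuple[PLRModel, ModelMetrics]:
    """Fit both segments and the breakpoint by exact profiled least squares.

    Candidate breakpoints are the midpoints of consecutive sorted unique
    observed responses (the profile SSE is constant between them); each
    candidate must leave at least ``max(p + 1, min_segment_fraction * n)``
    rows per segment. Returns the model plus calibration metrics.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = input_names or [f"x{i + 1}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < 2 * (p + 2):
        raise ValueError(f"need at least {2 * (p + 2)} rows for {p} predictors")
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise ValueError("response is constant")

    min_rows = max(p + 1, int(math.ceil(min_segment_fraction * n)))
    candidates = (uniq[:-1] + uniq[1:]) / 2.0

    best: tuple[float, float, np.ndarray, np.ndarray] | None = None
    for b in candidates:
        low = y <= b
        high = ~low
        if low.sum() < min_rows or high.sum() < min_rows:
            continue
        c_lo, sse_lo = _segment_ols(Xm[low], y[low])
        c_hi, sse_hi = _segment_ols(Xm[high], y[high])
        sse = sse_lo + sse_hi
        if best is None or sse < best[0] - 1e-15:
            best = (sse, float(b), c_lo, c_hi)
    if best is None:
        raise ValueError("no admissible breakpoint: segments too small")

    sse, b_hat, c_lo, c_hi = best
    model = PLRModel(
        input_names=names, coef_low=c_lo, coef_high=c_hi, breakpoint=b_hat,
        provenance="fitted by profiled least squares over observed-response midpoints",
    )
    yhat = np.where(y <= b_hat, model.segment_values(Xm)[0], model.segment_values(Xm)[1])
    metrics = evaluate_model(y, yhat, None, None, p)
    return model, metrics


def predict_plr(
    model: PLRModel, X: pd.DataFrame | np.ndarray, tie_break: str = "closest"
) -> np.ndarray:
    """Evaluate the self-consistent segment for each row.

    A low-segment value is consistent if it is <= the breakpoint, a
    high-segment value if it is > the breakpoint. With zero or two
    consistent candidates the tie-break applies: "closest" (default)
    returns the value nearest the breakpoint, "low"/"high" force a segment.
    """
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.input_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing predictor column(s): {missing}")
        X = X[model.input_names].to_numpy(dtype=float)
    lo, hi = model.segment_values(X)
    b = model.breakpoint
    lo_ok = lo <= b
    hi_ok = hi > b
    out = np.empty_like(lo)
    one = lo_ok ^ hi_ok
    out[one & lo_ok] = lo[one & lo_ok]
    out[one & hi_ok] = hi[one & hi_ok]
    amb = ~one
    if np.any(amb):
        if tie_break == "closest":
            pick_lo = np.abs(lo - b) <= np.abs(hi - b)
            out[amb & pick_lo] = lo[amb & pick_lo]
            out[amb & ~pick_lo] = hi[amb & ~pick_lo]
        elif tie_break == "low":
            out[amb] = lo[amb]
        elif tie_break == "high":
            out[amb] = hi[amb]
        else:
            raise ValueError("tie_break must be 'closest', 'low' or 'high'")
    return out


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst if sst > 0 else math.nan


def evaluate_model(
    y_cal: np.ndarray,
    yhat_cal: np.ndarray,
    y_pred: np.ndarray | None,
    yhat_pred: np.ndarray | None,
    p: int,
) -> ModelMetrics:
    """Chemometric metrics; RPD and RER are computed on the prediction set's
    reference values. Perfect prediction flags them infinite."""
    if p < 1:
        raise ValueError("p must be >= 1")
    y_cal = np.asarray(y_cal, dtype=float)
    yhat_cal = np.asarray(yhat_cal, dtype=float)
    if y_cal.size == 0:
        raise ValueError("empty calibration set")
    n_cal = len(y_cal)
    r2c = _r2(y_cal, yhat_cal)
    r2c_adj = 1.0 - (1.0 - r2c) * (n_cal - 1) / (n_cal - p - 1) if n_cal > p + 1 else math.nan
    rmsec = float(np.sqrt(np.mean((y_cal - yhat_cal) ** 2)))
    m = ModelMetrics(r2_cal=r2c, r2_cal_adj=r2c_adj, rmsec=rmsec)

    if y_pred is None:
        return m
    y_pred = np.asarray(y_pred, dtype=float)
    yhat_pred = np.asarray(yhat_pred, dtype=float)
    if y_pred.size == 0:
        raise ValueError("empty prediction set")
    n_pred = len(y_pred)
    m.r2_pred = _r2(y_pred, yhat_pred)
    m.r2_pred_adj = (
        1.0 - (1.0 - m.r2_pred) * (n_pred - 1) / (n_pred - p - 1)
        if n_pred > p + 1
        else math.nan
    )
    m.rmsep = float(np.sqrt(np.mean((y_pred - yhat_pred) ** 2)))
    sd = float(np.std(y_pred, ddof=1)) if n_pred > 1 else math.nan
    rng = float(np.ptp(y_pred))
    if m.rmsep == 0.0:
        m.rpd = math.inf
        m.rer = math.inf
    elif sd == 0.0 or rng == 0.0:
        m.rpd = math.nan
        m.rer = math.nan
    else:
        m.rpd = sd / m.rmsep
        m.rer = rng / m.rmsep
    return m


def interpret_metrics(metrics: ModelMetrics) -> dict[str, str]:
    """Conventional qualitative labels for predictive R^2, RPD and RER.

    R^2 >= 0.75 significant, >= 0.50 moderate, >= 0.26 weak; RPD < 1.4
    non-reliable, 1.4-2 fair, > 2 excellent; RER > 15 quantification,
    > 10 quality-control, > 4 screening.
    """
    r2 = metrics.r2_pred if math.isfinite(metrics.r2_pred) else metrics.r2_cal
    if r2 >= 0.75:
        r2_label = "significant"
    elif r2 >= 0.50:
        r2_label = "moderate"
    elif r2 >= 0.26:
        r2_label = "weak"
    else:
        r2_label = "not predictive"
    if metrics.rpd > 2:
        rpd_label = "excellent"
    elif metrics.rpd >= 1.4:
        rpd_label = "fair"
    else:
        rpd_label = "non-reliable"
    if metrics.rer > 15:
        rer_label = "quantification"
    elif metrics.rer > 10:
        rer_label = "quality-control"
    elif metrics.rer > 4:
        rer_label = "screening"
    else:
        rer_label = "inadequate"
    return {"r2": r2_label, "rpd": rpd_label, "rer": rer_label}


def _published_raw() -> dict:
    path = importlib.resources.files("descreen.data").joinpath("table3_models.json")
    return json.loads(path.read_text(encoding="utf-8"))


def published_model(name: str) -> tuple[PLRModel, ModelMetrics]:
    """Return a published QSAR model fixture plus its reported metrics.

    Names: "fdh_activity", "fdh_half_life", "nadh_half_life".
    """
    raw = _published_raw()
    if name not in PUBLISHED_MODEL_NAMES:
        raise KeyError(f"unknown published model {name!r}; choose from {PUBLISHED_MODEL_NAMES}")
    d = raw[name]
    model = PLRModel(
        input_names=list(d["input_names"]),
        coef_low=np.asarray(d["coef_low"]),
        coef_high=np.asarray(d["coef_high"]),
        breakpoint=float(d["breakpoint"]),
        provenance=raw["provenance"],
    )
    met = d["metrics"]
    metrics = ModelMetrics(
        r2_cal=met["r2_cal"],
        r2_cal_adj=met["r2_cal_adj"],
        rmsec=met["rmsec"],
        r2_pred=met["r2_pred"],
        r2_pred_adj=met["r2_pred_adj"],
        rmsep=met["rmsep"],
        rpd=met["rpd"],
        rer=met["rer"],
    )
    return model, metrics
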