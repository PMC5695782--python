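"""Cut-point classifiers: SVM, IMA and TM metrics with MET-anchored cut-offs.

Each 10-s window of the dynamic acceleration stream is summarised by one
of three movement metrics:

* ``SVM`` — sum of vector magnitudes, Σ_d √(x_d²+y_d²+z_d²) over the 600
  window samples (g);
* ``IMA`` — integrated moduli of acceleration, Σ_axes ∫|a| dt over the
  10-s window (g·s), integrated with a rectangle rule at the sample rate;
* ``TM`` — total movement, √(SD_x²+SD_y²+SD_z²) of the per-axis sample
  SDs (g).

Cut-offs on each metric are calibrated by regressing the minute MET
values on the metric, choosing the best of five trend-line families by
explained variance (R²), and inverting the fitted curve at MET 1.5 and
MET 3.  Classification then compares a window's metric with the two
cut-offs; windows below the lower cut-off are split into Sedentary vs
Standing by posture detection on the window-mean static Y acceleration
(upright iff \\|static Y mean\\| > 0.5 g by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from . import SAMPLE_RATE_HZ, WINDOW_SAMPLES
from .signal_processing import WindowFrame

__all__ = [
    "WindowMetrics",
    "CutpointModel",
    "compute_svm",
    "compute_ima",
    "compute_tm",
    "compute_metrics",
    "detect_posture",
    "calibrate",
    "classify_cutpoint",
    "TREND_FAMILIES",
]

DEFAULT_POSTURE_THRESHOLD_G = 0.5


@dataclass(frozen=True)
class WindowMetrics:
    """The three movement metrics plus the posture variable for one window."""

    svm: float
    ima: float
    tm: float
    static_y_mean: float


def _dynamic(window: WindowFrame | np.ndarray) -> np.ndarray:
    arr = window.dynamic_samples if isinstance(window, WindowFrame) else np.asarray(window, float)
    if arr.shape != (WINDOW_SAMPLES, 3):
        raise ValueError(f"expected ({WINDOW_SAMPLES}, 3) dynamic samples, got {arr.shape}")
    return arr


def compute_svm(window: WindowFrame | np.ndarray) -> float:
    """Sum of vector magnitudes of the dynamic stream (g)."""
    d = _dynamic(window)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def compute_ima(window: WindowFrame | np.ndarray, method: str = "rectangle") -> float:
    """Integrated moduli of acceleration over the 10-s window (g·s)."""
    d = np.abs(_dynamic(window))
    dt = 1.0 / SAMPLE_RATE_HZ
    if method == "rectangle":
        return float(d.sum() * dt)
    if method == "trapezoid":
        return float(sum(np.trapezoid(d[:, i], dx=dt) for i in range(3)))
    raise ValueError(f"unknown quadrature {method!r}")


def compute_tm(window: WindowFrame | np.ndarray) -> float:
    """Euclidean norm of the per-axis sample SDs of the dynamic stream (g)."""
    d = _dynamic(window)
    return float(np.linalg.norm(d.std(axis=0, ddof=1)))


def compute_metrics(window: WindowFrame, ima_method: str = "rectangle") -> WindowMetrics:
    """All three metrics plus the window-mean static Y for one window."""
    return WindowMetrics(
        svm=compute_svm(window),
        ima=compute_ima(window, method=ima_method),
        tm=compute_tm(window),
        static_y_mean=float(window.static_samples[:, 1].mean()),
    )


def detect_posture(static_y_mean: float, threshold: float = DEFAULT_POSTURE_THRESHOLD_G) -> str:
    """Upright iff |static Y mean| strictly exceeds the threshold.

    The absolute value makes detection robust to a flipped device
    (Y ≈ -1 g when upright).  0.5 g is the midpoint between the
    horizontal-thigh (≈0 g) and vertical-thigh (≈1 g) gravity
    projections.
    """
    if not np.isfinite(static_y_mean):
        raise ValueError("static_y_mean must be finite")
    return "upright" if abs(static_y_mean) > threshold else "not_upright"


# ---------------------------------------------------------------------------
# trend-line calibration

def _fit_linear(m, y):
    b, a = np.polyfit(m, y, 1)
    return {"a": a, "b": b}, lambda x, a=a, b=b: a + b * x


def _fit_quadratic(m, y):
    c, b, a = np.polyfit(m, y, 2)
    return {"a": a, "b": b, "c": c}, lambda x, a=a, b=b, c=c: a + b * x + c * x**2


def _fit_logarithmic(m, y):
    if np.any(m <= 0):
        raise ValueError("logarithmic family needs positive metric values")
    b, a = np.polyfit(np.log(m), y, 1)
    return {"a": a, "b": b}, lambda x, a=a, b=b: a + b * np.log(x)


def _fit_power(m, y):
    if np.any(m <= 0) or np.any(y <= 0):
        raise ValueError("power family needs positive values")
    b, la = np.polyfit(np.log(m), np.log(y), 1)
    a = np.exp(la)
    return {"a": a, "b": b}, lambda x, a=a, b=b: a * x**b


def _fit_exponential(m, y):
    if np.any(y <= 0):
        raise ValueError("exponential family needs positive MET values")
    b, la = np.polyfit(m, np.log(y), 1)
    a = np.exp(la)
    return {"a": a, "b": b}, lambda x, a=a, b=b: a * np.exp(b * x)


# order = tie-break preference: fewer parameters first, then this fixed order
TREND_FAMILIES = {
    "linear": _fit_linear,
    "logarithmic": _fit_logarithmic,
    "exponential": _fit_exponential,
    "power": _fit_power,
    "quadratic": _fit_quadratic,
}

_R2_TIE_TOL = 1e-9


@dataclass
class CutpointModel:
    """A fitted metric→MET trend line with the two inverted cut-offs."""

    metric_name: str
    trend_family: str
    coefficients: dict[str, float]
    r_squared: float
    cutoff_lipa: float  # metric value at MET 1.5
    cutoff_mvpa: float  # metric value at MET 3
    posture_threshold: float = DEFAULT_POSTURE_THRESHOLD_G
    metric_range: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("R² must lie in [0, 1]")
        if not self.cutoff_lipa < self.cutoff_mvpa:
            raise ValueError("LIPA cut-off must lie below MVPA cut-off")

    def predict_met(self, metric: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the fitted trend line at the given metric value(s)."""
        return _family_curve(self.trend_family, self.coefficients)(metric)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "metric_name": self.metric_name,
                "trend_family": self.trend_family,
                "coefficients": self.coefficients,
                "r_squared": self.r_squared,
                "cutoff_lipa": self.cutoff_lipa,
                "cutoff_mvpa": self.cutoff_mvpa,
                "posture_threshold": self.posture_threshold,
                "metric_range": list(self.metric_range),
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str | Path) -> "CutpointModel":
        p = Path(payload)
        text = p.read_text() if p.exists() else str(payload)
        d = json.loads(text)
        d["metric_range"] = tuple(d.get("metric_range", (0.0, 0.0)))
        return cls(**d)


def _family_curve(family: str, coef: dict[str, float]):
    a, b = coef["a"], coef["b"]
    if family == "linear":
        return lambda x: a + b * x
    if family == "quadratic":
        c = coef["c"]
        return lambda x: a + b * x + c * np.asarray(x, float) ** 2
    if family == "logarithmic":
        return lambda x: a + b * np.log(x)
    if family == "power":
        return lambda x: a * np.asarray(x, float) ** b
    if family == "exponential":
        return lambda x: a * np.exp(b * np.asarray(x, float))
    raise ValueError(f"unknown family {family!r}")


def _is_monotone_increasing(fn, lo: float, hi: float, n: int = 512) -> bool:
    grid = np.linspace(lo, hi, n)
    vals = fn(grid)
    return bool(np.all(np.diff(vals) > 0) and np.all(np.isfinite(vals)))


def calibrate(
    metric_values: np.ndarray,
    met_values: np.ndarray,
    metric_name: str = "metric",
    posture_threshold: float = DEFAULT_POSTURE_THRESHOLD_G,
) -> CutpointModel:
    """Fit the best MET-on-metric trend line and invert it at MET 1.5 and 3.

    Candidate families are linear, logarithmic, exponential, power and
    quadratic; the family with the highest R² on the MET scale wins (ties
    within 1e-9 go to the family with fewer parameters).  Only curves
    monotone increasing over the observed metric range are invertible; if
    no candidate is monotone, the linear fit is used with a warning.  The
    two cut-offs must fall inside the observed metric range.
    """
    m = np.asarray(metric_values, dtype=float)
    y = np.asarray(met_values, dtype=float)
    if m.shape != y.shape or m.ndim != 1:
        raise ValueError("metric and MET arrays must be 1-D and aligned")
    if np.unique(m).size < 2:
        raise ValueError("need at least 2 distinct metric values")
    lo, hi = float(m.min()), float(m.max())
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    fits = {}
    for family, fitter in TREND_FAMILIES.items():
        try:
            coef, fn = fitter(m, y)
        except (ValueError, np.linalg.LinAlgError):
            continue
        resid = y - fn(m)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        fits[family] = (coef, fn, max(0.0, min(1.0, r2)))

    if not fits:
        raise ValueError("no trend family could be fitted")

    monotone = {
        fam: v for fam, v in fits.items() if _is_monotone_increasing(v[1], lo, hi)
    }
    if monotone:
        best_r2 = max(v[2] for v in monotone.values())
        # dict preserves the preference order of TREND_FAMILIES
        family = next(
            fam for fam, v in monotone.items() if v[2] >= best_r2 - _R2_TIE_TOL
        )
        coef, fn, r2 = monotone[family]
    else:
        warnings.warn(
            "no monotone-increasing trend line over the observed metric range; "
            "falling back to the linear fit",
            RuntimeWarning,
            stacklevel=2,
        )
        if "linear" not in fits:
            raise ValueError("linear fallback could not be fitted")
        family = "linear"
        coef, fn, r2 = fits["linear"]

    cutoffs = []
    for target in (1.5, 3.0):
        f_lo, f_hi = float(fn(lo)), float(fn(hi))
        if not f_lo <= target <= f_hi:
            raise ValueError(
                f"MET {target} is outside the fitted range "
                f"[{f_lo:.3g}, {f_hi:.3g}] of the observed metric values"
            )
        cutoffs.append(float(brentq(lambda x: fn(x) - target, lo, hi)))

    return CutpointModel(
        metric_name=metric_name,
        trend_family=family,
        coefficients={k: float(v) for k, v in coef.items()},
        r_squared=r2,
        cutoff_lipa=cutoffs[0],
        cutoff_mvpa=cutoffs[1],
        posture_threshold=posture_threshold,
        metric_range=(lo, hi),
    )


def classify_cutpoint(metrics: WindowMetrics, model: CutpointModel) -> str:
    """Classify one window by its metric value with posture gating.

    metric ≤ LIPA cut-off → Sedentary/Standing by posture; between the
    cut-offs → LIPA; at or above the MVPA cut-off → MVPA (the ≥ boundary
    mirrors the MET ≥ 3 rule).
    """
    value = getattr(metrics, model.metric_name)
    if value >= model.cutoff_mvpa:
        return "MVPA"
    if value > model.cutoff_lipa:
        return "LIPA"
    posture = detect_posture(metrics.static_y_mean, model.posture_threshold)
    return "Standing" if posture == "upright" else "Sedentary"
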