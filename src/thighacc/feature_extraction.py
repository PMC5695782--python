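"""Time- and frequency-domain features per 10-s window.

For every window, 16 per-axis features are computed on each axis of both
the static and dynamic streams, plus 3 cross-axis correlations per
stream, 3 orientation angles (static stream only) and 2 resultant
vectors per stream (one over the axis means, one over the axis SDs).

Conventions (fixed here; the schema below is the source of truth):

* sd / skewness / kurtosis: sample (n-1) SD, adjusted Fisher-Pearson
  skewness, excess kurtosis (normal -> 0); both 0 on a constant window.
* rms on the raw window values (not mean-removed).
* peak_to_peak = max - min; peak_intensity = count of strict local maxima
  of the mean-removed signal exceeding 50% of its maximum absolute value.
* zero crossings counted on the mean-removed series as sign changes, a
  zero sample inheriting the previous sign.
* spectral features from the one-sided periodogram of the mean-removed,
  Hann-windowed signal; DC excluded; entropy normalised to [0, 1].
* orientation from the window-mean static vector:
  roll = atan2(x, sqrt(y^2+z^2)), pitch = atan2(y, sqrt(x^2+z^2)),
  yaw = atan2(z, sqrt(x^2+y^2)), degrees.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from . import SAMPLE_RATE_HZ, WINDOW_SAMPLES
from .signal_processing import WindowFrame

__all__ = [
    "AXES",
    "STREAMS",
    "PER_AXIS_FEATURES",
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "time_domain_features",
    "frequency_domain_features",
    "orientation_angles",
    "cross_correlations",
    "build_feature_matrix",
    "write_schema",
]

AXES = ("x", "y", "z")
STREAMS = ("static", "dynamic")

PER_AXIS_FEATURES = (
    "mean",
    "sd",
    "min",
    "max",
    "median",
    "iqr",
    "skewness",
    "kurtosis",
    "rms",
    "peak_to_peak",
    "peak_intensity",
    "zero_crossings",
    "lag1_autocorrelation",
    "dominant_frequency",
    "dominant_frequency_amplitude",
    "spectral_entropy",
)

META_COLUMNS = ("participant_id", "activity_code", "minute_id", "window_index", "posture")


def _feature_columns() -> list[str]:
    cols: list[str] = []
    for stream in STREAMS:
        for axis in AXES:
            cols += [f"{stream}_{axis}_{feat}" for feat in PER_AXIS_FEATURES]
        cols += [f"{stream}_crosscorr_{p}" for p in ("xy", "xz", "yz")]
    cols += ["static_roll", "static_pitch", "static_yaw"]
    for stream in STREAMS:
        cols += [f"{stream}_resultant_mean", f"{stream}_resultant_sd"]
    return cols


FEATURE_COLUMNS = _feature_columns()


# ---------------------------------------------------------------------------
# vectorised kernels: x has shape (n_windows, n_samples)

def _zero_crossings(xc: np.ndarray) -> np.ndarray:
    # sign with zeros inheriting the previous sign (leading zeros count +)
    s = np.where(xc > 0, 1, np.where(xc < 0, -1, 0))
    idx = np.arange(s.shape[1])[None, :] * (s != 0)
    last = np.maximum.accumulate(idx, axis=1)
    filled = np.take_along_axis(s, last, axis=1)
    filled[filled == 0] = 1
    return np.sum(filled[:, 1:] != filled[:, :-1], axis=1).astype(float)


def _peak_intensity(xc: np.ndarray) -> np.ndarray:
    thresh = 0.5 * np.max(np.abs(xc), axis=1, keepdims=True)
    interior = xc[:, 1:-1]
    is_peak = (interior > xc[:, :-2]) & (interior > xc[:, 2:]) & (interior > thresh)
    return np.sum(is_peak, axis=1).astype(float)


def _lag1_autocorr(xc: np.ndarray) -> np.ndarray:
    denom = np.sum(xc**2, axis=1)
    num = np.sum(xc[:, :-1] * xc[:, 1:], axis=1)
    out = np.zeros(xc.shape[0])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def _time_domain_matrix(x: np.ndarray) -> dict[str, np.ndarray]:
    """Time-domain features for a (n_windows, n_samples) matrix."""
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    xc = x - mean[:, None]
    q75, q25 = np.percentile(x, [75, 25], axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # near-constant windows trip scipy's catastrophic-cancellation warning;
        # those cases are overridden by the constant-window convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(x, axis=1, bias=False)
        kurt = stats.kurtosis(x, axis=1, bias=False)
    constant = sd == 0
    skew = np.where(constant | ~np.isfinite(skew), 0.0, skew)
    kurt = np.where(constant | ~np.isfinite(kurt), 0.0, kurt)
    return {
        "mean": mean,
        "sd": sd,
        "min": x.min(axis=1),
        "max": x.max(axis=1),
        "median": np.median(x, axis=1),
        "iqr": q75 - q25,
        "skewness": skew,
        "kurtosis": kurt,
        "rms": np.sqrt(np.mean(x**2, axis=1)),
        "peak_to_peak": x.max(axis=1) - x.min(axis=1),
        "peak_intensity": _peak_intensity(xc),
        "zero_crossings": _zero_crossings(xc),
        "lag1_autocorrelation": _lag1_autocorr(xc),
    }


def _frequency_domain_matrix(x: np.ndarray) -> dict[str, np.ndarray]:
    """Spectral features for a (n_windows, n_samples) matrix."""
    freqs, pxx = sps.periodogram(
        x, fs=SAMPLE_RATE_HZ, window="hann", detrend="constant", axis=-1
    )
    df = freqs[1] - freqs[0]
    p = pxx[:, 1:]  # DC excluded
    total = p.sum(axis=1)
    k = np.argmax(p, axis=1)
    rows = np.arange(x.shape[0])
    dom_freq = freqs[1:][k]
    dom_amp = np.sqrt(2.0 * p[rows, k] * df)
    with np.errstate(divide="ignore", invalid="ignore"):
        pn = p / total[:, None]
        plogp = np.where(pn > 0, pn * np.log2(pn), 0.0)
    entropy = -plogp.sum(axis=1) / np.log2(p.shape[1])
    silent = total <= 0
    dom_freq[silent] = 0.0
    dom_amp[silent] = 0.0
    entropy[silent] = 0.0
    return {
        "dominant_frequency": dom_freq,
        "dominant_frequency_amplitude": dom_amp,
        "spectral_entropy": entropy,
    }


def _cross_corr_matrix(windows: np.ndarray) -> dict[str, np.ndarray]:
    """Pearson lag-0 correlations per axis pair; 0 where an axis is constant."""
    out: dict[str, np.ndarray] = {}
    centred = windows - windows.mean(axis=1, keepdims=True)
    sd = windows.std(axis=1, ddof=1)
    for name, (i, j) in {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}.items():
        denom = sd[:, i] * sd[:, j]
        num = np.sum(centred[:, :, i] * centred[:, :, j], axis=1) / (
            windows.shape[1] - 1
        )
        r = np.zeros(windows.shape[0])
        ok = denom > 0
        r[ok] = num[ok] / denom[ok]
        out[name] = np.clip(r, -1.0, 1.0)
    return out


def _orientation_matrix(static: np.ndarray) -> dict[str, np.ndarray]:
    m = static.mean(axis=1)  # (n, 3) window-mean gravity vector
    norm = np.linalg.norm(m, axis=1)
    if np.any(norm == 0):
        raise ValueError("zero static gravity vector (free fall is unphysical)")
    x, y, z = m[:, 0], m[:, 1], m[:, 2]
    return {
        "roll": np.degrees(np.arctan2(x, np.hypot(y, z))),
        "pitch": np.degrees(np.arctan2(y, np.hypot(x, z))),
        "yaw": np.degrees(np.arctan2(z, np.hypot(x, y))),
    }


# ---------------------------------------------------------------------------
# single-window public operations

def _as_window_axis(window_axis: np.ndarray) -> np.ndarray:
    arr = np.asarray(window_axis, dtype=float)
    if arr.shape != (WINDOW_SAMPLES,):
        raise ValueError(f"expected {WINDOW_SAMPLES} samples, got {arr.shape}")
    return arr[None, :]


def time_domain_features(window_axis: np.ndarray) -> dict[str, float]:
    """Time-domain features of one 600-sample axis series."""
    return {k: float(v[0]) for k, v in _time_domain_matrix(_as_window_axis(window_axis)).items()}


def frequency_domain_features(window_axis: np.ndarray) -> dict[str, float]:
    """Dominant frequency, its amplitude and normalised spectral entropy."""
    return {
        k: float(v[0])
        for k, v in _frequency_domain_matrix(_as_window_axis(window_axis)).items()
    }


def orientation_angles(static_window: np.ndarray) -> tuple[float, float, float]:
    """(roll, pitch, yaw) in degrees from the window-mean static vector."""
    arr = np.asarray(static_window, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("static window must be an (n, 3) array")
    ang = _orientation_matrix(arr[None, :, :])
    return float(ang["roll"][0]), float(ang["pitch"][0]), float(ang["yaw"][0])


def cross_correlations(window: np.ndarray) -> tuple[float, float, float]:
    """(r_xy, r_xz, r_yz) Pearson correlations at lag 0."""
    arr = np.asarray(window, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("window must be an (n, 3) array")
    cc = _cross_corr_matrix(arr[None, :, :])
    return float(cc["xy"][0]), float(cc["xz"][0]), float(cc["yz"][0])


def build_feature_matrix(windows: list[WindowFrame]) -> pd.DataFrame:
    """Feature table with one row per window and the documented schema.

    Columns are :data:`META_COLUMNS` followed by :data:`FEATURE_COLUMNS`.
    """
    if not windows:
        raise ValueError("no windows to featurise")
    static = np.stack([w.static_samples for w in windows])
    dynamic = np.stack([w.dynamic_samples for w in windows])
    data: dict[str, np.ndarray] = {}
    for stream, arr in (("static", static), ("dynamic", dynamic)):
        for ai, axis in enumerate(AXES):
            x = arr[:, :, ai]
            feats = _time_domain_matrix(x)
            feats.update(_frequency_domain_matrix(x))
            for feat in PER_AXIS_FEATURES:
                data[f"{stream}_{axis}_{feat}"] = feats[feat]
        for pair, r in _cross_corr_matrix(arr).items():
            data[f"{stream}_crosscorr_{pair}"] = r
        means = arr.mean(axis=1)
        sds = arr.std(axis=1, ddof=1)
        data[f"{stream}_resultant_mean"] = np.linalg.norm(means, axis=1)
        data[f"{stream}_resultant_sd"] = np.linalg.norm(sds, axis=1)
    for angle, values in _orientation_matrix(static).items():
        data[f"static_{angle}"] = values

    table = pd.DataFrame({c: data[c] for c in FEATURE_COLUMNS})
    table.insert(0, "posture", [w.posture for w in windows])
    table.insert(0, "window_index", [w.window_index for w in windows])
    table.insert(0, "minute_id", [w.minute_id for w in windows])
    table.insert(0, "activity_code", [w.activity_code for w in windows])
    table.insert(0, "participant_id", [w.participant_id for w in windows])
    if table[FEATURE_COLUMNS].isna().any().any():
        bad = table[FEATURE_COLUMNS].isna().any()
        raise ValueError(f"NaN features: {list(bad[bad].index)}")
    return table


def write_schema(path: str | Path) -> None:
    """Write the JSON schema side-car describing the feature columns."""
    entries = []
    for col in FEATURE_COLUMNS:
        parts = col.split("_", 2)
        stream = parts[0]
        if len(parts) > 2 and parts[1] in AXES:
            axis, feat = parts[1], parts[2]
        else:
            axis, feat = None, "_".join(parts[1:])
        unit = "degrees" if feat in ("roll", "pitch", "yaw") else (
            "Hz" if feat == "dominant_frequency" else "g"
        )
        if feat in ("zero_crossings", "peak_intensity", "spectral_entropy",
                    "skewness", "kurtosis") or feat.startswith("crosscorr"):
            unit = "dimensionless"
        entries.append({"name": col, "stream": stream, "axis": axis,
                        "feature": feat, "unit": unit})
    Path(path).write_text(json.dumps(entries, indent=1))
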