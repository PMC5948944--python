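"""Sliding-window time-domain feature extraction and min-max normalization.

Fourteen scalars are computed per channel per window (the classical sEMG
time-domain set, applied here to force-myography signals):

========  ==================================================================
RMS       root mean square, ``sqrt(mean(x^2))``
SAV       sum of absolute values, ``sum(|x|)``
MAV       mean absolute deviation about the window mean
VAR       unbiased variance
WL        waveform length, ``sum(|x[i+1] - x[i]|)``
SSC       slope sign changes: count of interior samples with
          ``(x[i] - x[i-1]) * (x[i] - x[i+1]) > threshold``
SSI       simple square integral, ``sum(x^2)``
DB7       mean of the level-1 detail coefficients of a Daubechies-7 DWT
DASDV     ``sqrt(mean(diff(x)^2))``
AAC       average amplitude change, ``mean(|diff(x)|)``
LD        log detector, ``exp(mean(log(|x|)))`` with ``|x|`` floored at
          machine epsilon
LF        least-squares slope of x against sample index
PF_A      quadratic coefficient of the least-squares parabolic fit
PF_B      linear coefficient of the least-squares parabolic fit
========  ==================================================================

The parabolic fit contributes its two leading coefficients, bringing the
per-channel total to 14; with 8 channels the default feature vector has
112 columns.

Features are scaled with training-referenced min-max normalization,
``(x - min_train) / (max_train - min_train)``: test-set values may fall
outside [0, 1] and are deliberately not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view

from .io import FMGRecording, RunConfig

FEATURE_NAMES = ("RMS", "SAV", "MAV", "VAR", "WL", "SSC", "SSI",
                 "DB7", "DASDV", "AAC", "LD", "LF", "PF_A", "PF_B")

_EPS = np.finfo(float).eps


class FeatureError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Per-window feature vectors with column names and window timing."""

    values: np.ndarray               # (n_windows, n_channels * n_features)
    window_centers: np.ndarray       # seconds
    feature_names: tuple             # "chC_FEAT", column order
    subject_id: str = ""
    trial_id: str = ""
    speed_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.feature_names = tuple(self.feature_names)
        if self.values.shape != (self.window_centers.size, len(self.feature_names)):
            raise FeatureError("values shape inconsistent with centers/names")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "time_s", self.window_centers)
        return df


@dataclass
class NormalizationStats:
    """Per-column training min/max for the min-max transform."""

    col_min: np.ndarray
    col_max: np.ndarray

    def __post_init__(self) -> None:
        self.col_min = np.asarray(self.col_min, dtype=float)
        self.col_max = np.asarray(self.col_max, dtype=float)
        if self.col_min.shape != self.col_max.shape or self.col_min.ndim != 1:
            raise FeatureError("min/max must be equal-length 1-D")
        if np.any(self.col_max < self.col_min):
            raise FeatureError("max must be >= min per column")

    @property
    def n_columns(self) -> int:
        return self.col_min.size


# ---------------------------------------------------------------------------
# Per-window reference implementation
# ---------------------------------------------------------------------------

def _dwt_detail(x: np.ndarray, level: int, axis: int) -> np.ndarray:
    """Detail coefficients of a depth-``level`` db7 DWT (symmetric
    extension); level 1 by default, deeper levels cascade on approximations."""
    approx = x
    for _ in range(level):
        approx, detail = pywt.dwt(approx, "db7", mode="symmetric", axis=axis)
    return detail

def window_features(window, ssc_threshold: float = 0.0,
                    wavelet_level: int = 1) -> np.ndarray:
    """Compute the 14 time-domain features of a single channel window.

    This scalar implementation is the reference; :func:`sliding_features`
    computes the same quantities vectorized over all windows.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise FeatureError("window must be 1-D with at least 3 samples")
    n = x.size
    d = np.diff(x)
    rms = np.sqrt(np.mean(x ** 2))
    sav = np.sum(np.abs(x))
    mav = np.mean(np.abs(x - x.mean()))
    var = np.var(x, ddof=1)
    wl = np.sum(np.abs(d))
    ssc = np.count_nonzero(d[:-1] * (-d[1:]) > ssc_threshold)
    ssi = np.sum(x ** 2)
    db7 = float(np.mean(_dwt_detail(x, wavelet_level, axis=0)))
    dasdv = np.sqrt(np.mean(d ** 2))
    aac = np.mean(np.abs(d))
    ld = np.exp(np.mean(np.log(np.maximum(np.abs(x), _EPS))))
    t = np.arange(n, dtype=float)
    lf = np.polyfit(t, x, 1)[0]
    pf_a, pf_b = np.polyfit(t, x, 2)[:2]
    return np.array([rms, sav, mav, var, wl, ssc, ssi,
                     db7, dasdv, aac, ld, lf, pf_a, pf_b])


# ---------------------------------------------------------------------------
# Vectorized sliding extraction
# ---------------------------------------------------------------------------

def n_sliding_windows(n_samples: int, window_len: int, step_len: int) -> int:
    """Closed-form number of full windows: floor((n - w)/s) + 1."""
    if n_samples < window_len:
        return 0
    return (n_samples - window_len) // step_len + 1


def _poly_projectors(n: int):
    """Least-squares projectors onto slope and (quad, lin) coefficients."""
    t = np.arange(n, dtype=float)
    lin = np.vstack([t, np.ones(n)]).T
    quad = np.vstack([t ** 2, t, np.ones(n)]).T
    lin_p = np.linalg.pinv(lin)[0]            # slope row
    quad_p = np.linalg.pinv(quad)[:2]         # a and b rows
    return lin_p, quad_p


def _windows_features(w: np.ndarray, ssc_threshold: float,
                      wavelet_level: int) -> np.ndarray:
    """All 14 features for a stack of windows, shape (n_windows, wlen)."""
    n = w.shape[1]
    d = np.diff(w, axis=1)
    out = np.empty((w.shape[0], len(FEATURE_NAMES)))
    out[:, 0] = np.sqrt(np.mean(w ** 2, axis=1))                      # RMS
    out[:, 1] = np.sum(np.abs(w), axis=1)                             # SAV
    out[:, 2] = np.mean(np.abs(w - w.mean(axis=1, keepdims=True)), axis=1)
    out[:, 3] = np.var(w, axis=1, ddof=1)                             # VAR
    out[:, 4] = np.sum(np.abs(d), axis=1)                             # WL
    out[:, 5] = np.count_nonzero(d[:, :-1] * (-d[:, 1:]) > ssc_threshold,
                                 axis=1)                              # SSC
    out[:, 6] = np.sum(w ** 2, axis=1)                                # SSI
    out[:, 7] = np.mean(_dwt_detail(w, wavelet_level, axis=1), axis=1)  # DB7
    out[:, 8] = np.sqrt(np.mean(d ** 2, axis=1))                      # DASDV
    out[:, 9] = np.mean(np.abs(d), axis=1)                            # AAC
    out[:, 10] = np.exp(np.mean(np.log(np.maximum(np.abs(w), _EPS)), axis=1))
    lin_p, quad_p = _poly_projectors(n)
    out[:, 11] = w @ lin_p                                            # LF
    out[:, 12:14] = w @ quad_p.T                                      # PF_A, PF_B
    return out


def sliding_features(rec: FMGRecording, cfg: RunConfig) -> FeatureMatrix:
    """Extract per-window features for every channel of a recording.

    Windows of ``round(window_ms * fs / 1000)`` samples advance by
    ``round(step_ms * fs / 1000)`` samples starting at sample 0; a window's
    timestamp is its center.  Columns are ordered channel-major:
    ``ch1_RMS ... ch1_PF_B, ch2_RMS, ...``.
    """
    wlen, step = cfg.window_len, cfg.step_len
    if rec.n_samples < wlen:
        raise FeatureError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{wlen}-sample window")
    nw = n_sliding_windows(rec.n_samples, wlen, step)
    names = tuple(cfg.feature_set) if cfg.feature_set else FEATURE_NAMES
    sel = [FEATURE_NAMES.index(f) for f in names]
    cols = []
    for c in range(rec.n_channels):
        view = sliding_window_view(rec.signal[:, c], wlen)[::step][:nw]
        cols.append(_windows_features(view, cfg.ssc_threshold,
                                      cfg.wavelet_level)[:, sel])
    values = np.hstack(cols)
    starts = np.arange(nw) * step
    centers = (starts + (wlen - 1) / 2.0) / rec.fs
    col_names = tuple(f"ch{c+1}_{f}" for c in range(rec.n_channels) for f in names)
    return FeatureMatrix(values, centers, col_names,
                         subject_id=rec.subject_id, trial_id=rec.trial_id,
                         speed_label=rec.speed_label)


# ---------------------------------------------------------------------------
# Training-referenced min-max normalization
# ---------------------------------------------------------------------------

def fit_normalizer(train: FeatureMatrix | np.ndarray) -> NormalizationStats:
    """Per-column min and max over the training rows."""
    X = train.values if isinstance(train, FeatureMatrix) else np.atleast_2d(train)
    if X.shape[0] == 0:
        raise FeatureError("cannot fit normalizer on an empty training set")
    return NormalizationStats(X.min(axis=0), X.max(axis=0))


def normalize(X_ori: FeatureMatrix | np.ndarray,
              stats: NormalizationStats):
    """Apply ``(x - min_train) / (max_train - min_train)`` per column.

    Columns that were constant in training (max == min) map to 0.  No
    clipping: out-of-range test values land outside [0, 1].
    """
    is_fm = isinstance(X_ori, FeatureMatrix)
    X = X_ori.values if is_fm else np.atleast_2d(np.asarray(X_ori, float))
    if X.shape[1] != stats.n_columns:
        raise FeatureError(
            f"feature dimension {X.shape[1]} != normalizer dimension "
            f"{stats.n_columns}")
    span = stats.col_max - stats.col_min
    safe = np.where(span > 0, span, 1.0)
    out = (X - stats.col_min) / safe
    out[:, span == 0] = 0.0
    if is_fm:
        return FeatureMatrix(out, X_ori.window_centers, X_ori.feature_names,
                             subject_id=X_ori.subject_id,
                             trial_id=X_ori.trial_id,
                             speed_label=X_ori.speed_label)
    return out
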