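"""Single-cell reporter trace processing and oscillation features.

A raw trace holds two channels sampled on a uniform time grid (default 5-min
spacing over 5 h, i.e. 60 frames): the signal reporter (mCherry fused to the
oscillating gene) and a constitutive volume/segmentation marker (GFP).  The
correction pipeline is

1. **normalize** — divide reporter by marker, cancelling illumination and
   laser-exposure bias that affects both channels proportionally;
2. **detrend** — subtract a 100-min centred moving mean, removing slow drift
   such as photobleaching;
3. **smooth** — 20-min centred moving mean, suppressing frame-to-frame noise;
4. **peak calling** — local maxima of the smoothed signal with topographic
   prominence of at least 0.1 times the dynamic range of the recording
   (max - min of the normalized signal).

From the corrected signal, five per-cell oscillator-robustness features are
extracted: completed cycles, mean squared autocorrelation, autocorrelation
range, mean peak-to-peak interval, and mean amplitude (peak prominence).  For
all five, larger means a more robust oscillator.  Autocorrelation coefficients
below 0.3 in magnitude are treated as no correlation and zeroed before the ACF
features are formed, so small fluctuations do not inflate them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import DegenerateSeriesError, SchemaError

__all__ = [
    "Trace",
    "CorrectedTrace",
    "AutocorrResult",
    "FeatureVector",
    "FEATURE_NAMES",
    "normalize",
    "moving_mean",
    "detrend",
    "smooth",
    "detect_peaks",
    "autocorrelation",
    "extract_features",
    "align_to_first_peak",
    "process_trace",
    "read_traces_csv",
    "write_traces_csv",
]

DEFAULT_DT = 5.0  # min
DEFAULT_DETREND_WINDOW = 100.0  # min
DEFAULT_SMOOTH_WINDOW = 20.0  # min
DEFAULT_PEAK_FRACTION = 0.1
DEFAULT_ACF_CUTOFF = 0.3

FEATURE_NAMES = [
    "n_cycles",
    "acf_mean_square",
    "acf_range",
    "mean_p2p_interval",
    "mean_amplitude",
]


@dataclass
class Trace:
    """Raw two-channel trace for one cell (times in minutes)."""

    cell_id: str
    t: np.ndarray
    mcherry: np.ndarray
    gfp: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        n = len(self.t)
        if n < 2 or len(self.mcherry) != n or len(self.gfp) != n:
            raise ValueError(f"{self.cell_id}: channels and time grid must share length >= 2")
        steps = np.diff(self.t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise SchemaError(f"{self.cell_id}: non-uniform time grid")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class CorrectedTrace:
    """Processed trace: normalized, detrended, smoothed, with peak calls.

    ``dynamic_range`` is the max - min of the normalized signal (the full
    excursion of the recording, including any slow trend); the peak-calling
    prominence threshold is ``peak_fraction * dynamic_range``.
    """

    cell_id: str
    t: np.ndarray
    normalized: np.ndarray
    detrended: np.ndarray
    smoothed: np.ndarray
    dynamic_range: float
    peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    prominences: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def peak_times(self) -> np.ndarray:
        return self.t[self.peaks]


@dataclass(frozen=True)
class AutocorrResult:
    """Sample autocorrelation at lags 1..n-1 (59 lags for a 60-point trace)."""

    lags: np.ndarray
    r: np.ndarray

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class FeatureVector:
    """The five oscillator-robustness features of one cell."""

    cell_id: str
    n_cycles: int
    acf_mean_square: float
    acf_range: float
    mean_p2p_interval: float
    mean_amplitude: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.n_cycles,
                self.acf_mean_square,
                self.acf_range,
                self.mean_p2p_interval,
                self.mean_amplitude,
            ],
            dtype=float,
        )


def normalize(trace: Trace) -> np.ndarray:
    """Pointwise reporter/marker ratio; rejects non-positive marker values."""
    bad = np.flatnonzero(trace.gfp <= 0)
    if bad.size:
        raise ValueError(
            f"{trace.cell_id}: GFP <= 0 at timepoint index {int(bad[0])}; "
            "normalization undefined"
        )
    return trace.mcherry / trace.gfp


def moving_mean(series: np.ndarray, n_samples: int) -> np.ndarray:
    """Centred moving mean with an odd window, shrinking symmetrically at the
    boundaries (the first/last points average progressively fewer samples)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n_samples % 2 == 0:
        raise ValueError("window must be an odd number of samples")
    half = n_samples // 2
    out = np.empty(n)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        k = min(i, n - 1 - i, half)
        out[i] = (cs[i + k + 1] - cs[i - k]) / (2 * k + 1)
    return out


def _window_samples(window_min: float, dt: float) -> int:
    w = int(round(window_min / dt)) + 1
    if w % 2 == 0:
        w += 1
    return w


def detrend(series: np.ndarray, window: float = DEFAULT_DETREND_WINDOW, dt: float = DEFAULT_DT) -> np.ndarray:
    """Subtract the centred moving-mean trend (window in minutes)."""
    if len(series) < 3:
        raise ValueError("series must have at least 3 samples")
    if window < 2 * dt:
        raise ValueError("detrend window must span at least two sampling steps")
    return np.asarray(series, dtype=float) - moving_mean(series, _window_samples(window, dt))


def smooth(series: np.ndarray, window: float = DEFAULT_SMOOTH_WINDOW, dt: float = DEFAULT_DT) -> np.ndarray:
    """Centred moving-mean smoothing (window in minutes)."""
    if len(series) < 3:
        raise ValueError("series must have at least 3 samples")
    return moving_mean(series, _window_samples(window, dt))


def detect_peaks(
    corrected: CorrectedTrace,
    peak_fraction: float = DEFAULT_PEAK_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Call peaks on the smoothed signal.

    A peak is an interior local maximum with topographic prominence of at
    least ``peak_fraction * dynamic_range``; on a plateau the leftmost sample
    is reported.  Returns (indices, prominences) and stores them on
    ``corrected``.
    """
    threshold = peak_fraction * corrected.dynamic_range
    idx, props = find_peaks(
        corrected.smoothed, prominence=max(threshold, 0.0), plateau_size=(1, None)
    )
    left = props.get("left_edges", idx)
    prom = props.get("prominences", np.zeros(len(idx)))
    corrected.peaks = np.asarray(left, dtype=int)
    corrected.prominences = np.asarray(prom, dtype=float)
    return corrected.peaks, corrected.prominences


def autocorrelation(series: np.ndarray) -> AutocorrResult:
    """Sample ACF with biased normalization, lags 1..n-1.

    ``r(k) = sum_t (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2`` —
    a 60-point series yields exactly 59 lag coefficients.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("series must have at least 2 samples")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise DegenerateSeriesError("constant series has undefined autocorrelation")
    full = np.correlate(xc, xc, mode="full")[n - 1 :]  # lags 0..n-1
    r = full[1:] / denom
    return AutocorrResult(lags=np.arange(1, n), r=r)


def extract_features(
    corrected: CorrectedTrace,
    acf: AutocorrResult,
    acf_cutoff: float = DEFAULT_ACF_CUTOFF,
) -> FeatureVector:
    """Form the five-feature robustness vector of one cell.

    Coefficients with ``|r| < acf_cutoff`` are zeroed before the ACF features
    are computed.  Cells with fewer than two peaks get a zero mean
    peak-to-peak interval; cells without peaks get zero mean amplitude.
    """
    r = np.where(np.abs(acf.r) >= acf_cutoff, acf.r, 0.0)
    n_peaks = len(corrected.peaks)
    p2p = float(np.diff(corrected.peak_times).mean()) if n_peaks >= 2 else 0.0
    amp = float(corrected.prominences.mean()) if n_peaks >= 1 else 0.0
    return FeatureVector(
        cell_id=corrected.cell_id,
        n_cycles=max(n_peaks - 1, 0),
        acf_mean_square=float((r**2).mean()),
        acf_range=float(r.max() - r.min()) if len(r) else 0.0,
        mean_p2p_interval=p2p,
        mean_amplitude=amp,
    )


def align_to_first_peak(
    cells: list[CorrectedTrace],
) -> tuple[list[CorrectedTrace], list[CorrectedTrace]]:
    """Shift each trace so its first peak sits at pseudo-time zero.

    Returns (aligned, excluded); traces without any peak cannot be aligned and
    are reported in the excluded list.
    """
    aligned: list[CorrectedTrace] = []
    excluded: list[CorrectedTrace] = []
    for c in cells:
        if len(c.peaks) == 0:
            excluded.append(c)
            continue
        shift = c.t[c.peaks[0]]
        aligned.append(
            CorrectedTrace(
                cell_id=c.cell_id,
                t=c.t - shift,
                normalized=c.normalized,
                detrended=c.detrended,
                smoothed=c.smoothed,
                dynamic_range=c.dynamic_range,
                peaks=c.peaks,
                prominences=c.prominences,
            )
        )
    return aligned, excluded


def process_trace(
    trace: Trace,
    detrend_window: float = DEFAULT_DETREND_WINDOW,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    peak_fraction: float = DEFAULT_PEAK_FRACTION,
) -> CorrectedTrace:
    """Run the full correction pipeline on one raw trace."""
    norm = normalize(trace)
    det = detrend(norm, detrend_window, trace.dt)
    sm = smooth(det, smooth_window, trace.dt)
    corrected = CorrectedTrace(
        cell_id=trace.cell_id,
        t=trace.t.copy(),
        normalized=norm,
        detrended=det,
        smoothed=sm,
        dynamic_range=float(norm.max() - norm.min()),
    )
    detect_peaks(corrected, peak_fraction)
    return corrected


def featurize_trace(
    trace: Trace,
    detrend_window: float = DEFAULT_DETREND_WINDOW,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    peak_fraction: float = DEFAULT_PEAK_FRACTION,
    acf_cutoff: float = DEFAULT_ACF_CUTOFF,
) -> tuple[CorrectedTrace, FeatureVector]:
    """Correct one trace and extract its feature vector in one call."""
    corrected = process_trace(trace, detrend_window, smooth_window, peak_fraction)
    try:
        acf = autocorrelation(corrected.smoothed)
    except DegenerateSeriesError:
        warnings.warn(f"{trace.cell_id}: constant corrected signal, ACF features set to 0")
        acf = AutocorrResult(lags=np.arange(1, len(trace)), r=np.zeros(len(trace) - 1))
    return corrected, extract_features(corrected, acf, acf_cutoff)


def read_traces_csv(path: str | Path) -> list[Trace]:
    """Read per-cell traces from a long-format CSV (cell_id, t_min, mcherry, gfp)."""
    df = pd.read_csv(path)
    required = ["cell_id", "t_min", "mcherry", "gfp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    traces = []
    for cid, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("t_min")
        traces.append(
            Trace(
                cell_id=str(cid),
                t=g["t_min"].to_numpy(),
                mcherry=g["mcherry"].to_numpy(),
                gfp=g["gfp"].to_numpy(),
            )
        )
    return traces


def write_traces_csv(traces: list[Trace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"cell_id": tr.cell_id, "t_min": tr.t, "mcherry": tr.mcherry, "gfp": tr.gfp}
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
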