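"""Sleep/wake scoring, activity traces, rasters, spectra, and periods.

The MA firing rate ``Q_m`` is the arousal proxy throughout: the model is
awake when ``Q_m`` strictly exceeds the wake threshold (default
1 s^-1) and asleep otherwise (ties score as sleep, for determinism).
Activity is ``Q_m`` time-averaged in 10-min windows, matching how
experimental activity counts are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoutSeries", "ActivityTrace", "Spectrum",
    "score_sleep_wake", "activity_trace", "raster", "raster_threshold_sweep",
    "total_sleep_fraction", "percent_wake_by_circadian_bin",
    "amplitude_spectrum", "peak_period", "free_running_period",
    "fold_average",
]


@dataclass
class BoutSeries:
    """Alternating wake/sleep intervals partitioning the analyzed span.

    ``intervals`` is a list of (start_s, end_s, state) with state
    "wake" or "sleep"; ``sampling_interval`` is the resolution of the
    underlying series.
    """

    intervals: list[tuple[float, float, str]]
    sampling_interval: float

    @property
    def span(self) -> tuple[float, float]:
        return self.intervals[0][0], self.intervals[-1][1]

    def durations(self, state: str) -> np.ndarray:
        return np.array([e - s for s, e, st in self.intervals if st == state])

    def wake_flags(self, dt: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(times, bool flags) resampled on a uniform grid of step dt."""
        dt = dt or self.sampling_interval
        t0, t1 = self.span
        t = t0 + dt * np.arange(int((t1 - t0) / dt))
        flags = np.zeros(t.size, dtype=bool)
        for s, e, st in self.intervals:
            if st == "wake":
                flags[(t >= s) & (t < e)] = True
        return t, flags


@dataclass
class ActivityTrace:
    """Windowed mean MA firing rate: the model's activity proxy."""

    window_centers: np.ndarray  #: (s)
    values: np.ndarray  #: mean Q_m per window (s^-1)
    width: float  #: window width (s)
    mode: str  #: "sliding" or "non-overlapping"

    @property
    def stride(self) -> float:
        if len(self.window_centers) < 2:
            return self.width
        return float(self.window_centers[1] - self.window_centers[0])


@dataclass
class Spectrum:
    """Area-normalized amplitude spectrum on a period axis (hours)."""

    periods: np.ndarray  #: ascending, in hours
    amplitudes: np.ndarray  #: dimensionless; trapezoid integral over periods = 1


# ---------------------------------------------------------------------------
# scoring and traces
# ---------------------------------------------------------------------------

def score_sleep_wake(Q_m: np.ndarray, threshold: float = 1.0,
                     sampling_interval: float = 30.0,
                     t0: float = 0.0) -> BoutSeries:
    """Threshold ``Q_m`` pointwise and merge runs into alternating bouts.

    Wake requires strict exceedance (``Q_m > threshold``); a sample equal
    to the threshold scores as sleep.  No smoothing is applied.
    """
    Q_m = np.asarray(Q_m, dtype=float)
    if Q_m.size == 0:
        raise ValueError("empty firing-rate series")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    awake = Q_m > threshold
    edges = np.flatnonzero(np.diff(awake.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [awake.size]))
    intervals = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        state = "wake" if awake[a] else "sleep"
        intervals.append((t0 + a * sampling_interval,
                          t0 + b * sampling_interval, state))
    return BoutSeries(intervals, sampling_interval)


def activity_trace(Q_m: np.ndarray, sampling_interval: float,
                   width: float = 600.0, mode: str = "sliding",
                   t0: float = 0.0) -> ActivityTrace:
    """Windowed time-average of ``Q_m`` (width default 10 min).

    ``sliding`` steps by one sample; ``non-overlapping`` steps by the
    window width.
    """
    Q_m = np.asarray(Q_m, dtype=float)
    w = int(round(width / sampling_interval))
    if w < 1 or width < sampling_interval:
        raise ValueError("window width must be >= the sampling interval")
    if mode == "sliding":
        kernel = np.full(w, 1.0 / w)
        vals = np.convolve(Q_m, kernel, mode="valid")
        centers = t0 + (np.arange(vals.size) + (w - 1) / 2.0) * sampling_interval
    elif mode == "non-overlapping":
        nwin = Q_m.size // w
        vals = Q_m[:nwin * w].reshape(nwin, w).mean(axis=1)
        centers = t0 + (np.arange(nwin) + 0.5) * w * sampling_interval
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ActivityTrace(centers, vals, width=w * sampling_interval, mode=mode)


def raster(source, fold_period: float = 24.0, double_plot: bool = True,
           high_threshold: float = 1.0) -> np.ndarray:
    """Day-by-phase boolean raster of high activity (or wake).

    ``source`` is an :class:`ActivityTrace` (cells true where windowed
    activity exceeds ``high_threshold``) or a :class:`BoutSeries` (cells
    true during wake).  Each row spans one ``fold_period`` (hours);
    ``double_plot`` concatenates row i with row i+1, as conventional for
    actograms.
    """
    if isinstance(source, BoutSeries):
        t, flags = source.wake_flags()
        stride = source.sampling_interval
    else:
        flags = source.values > high_threshold
        stride = source.stride
    n_cols = int(round(fold_period * 3600.0 / stride))
    n_rows = flags.size // n_cols
    if n_rows < 1:
        raise ValueError("record shorter than one fold period")
    mat = flags[:n_rows * n_cols].reshape(n_rows, n_cols)
    if double_plot:
        nxt = np.vstack([mat[1:], np.zeros((1, n_cols), dtype=bool)])
        mat = np.hstack([mat, nxt])
    return mat


def raster_threshold_sweep(trace: ActivityTrace,
                           thresholds=(0.5, 1.0, 2.0),
                           fold_period: float = 24.0,
                           double_plot: bool = True) -> dict[float, np.ndarray]:
    """Rasters of the same trace at several high-activity thresholds.

    Coverage (fraction of true cells) decreases monotonically as the
    threshold rises.
    """
    return {thr: raster(trace, fold_period, double_plot, thr)
            for thr in thresholds}


# ---------------------------------------------------------------------------
# summary metrics
# ---------------------------------------------------------------------------

def total_sleep_fraction(bouts: BoutSeries) -> float:
    """Percent of the record spent asleep."""
    if not bouts.intervals:
        raise ValueError("empty bout series")
    sleep = bouts.durations("sleep").sum()
    t0, t1 = bouts.span
    return 100.0 * sleep / (t1 - t0)


def percent_wake_by_circadian_bin(bouts: BoutSeries, period: float,
                                  n_bins: int = 24) -> np.ndarray:
    """Wake percentage per circadian bin, folded at ``period`` (hours).

    Circadian time zero is set to the first bin (scanning in phase order
    from the record start) whose average wake exceeds 50%.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    t, flags = bouts.wake_flags()
    t0, t1 = bouts.span
    if (t1 - t0) < period * 3600.0:
        raise ValueError("record shorter than one fold period")
    phase = ((t - t0) / 3600.0) % period
    idx = np.minimum((phase / period * n_bins).astype(int), n_bins - 1)
    pct = np.array([100.0 * flags[idx == i].mean() for i in range(n_bins)])
    above = np.flatnonzero(pct > 50.0)
    if above.size:
        pct = np.roll(pct, -above[0])
    return pct


# ---------------------------------------------------------------------------
# spectra and periods
# ---------------------------------------------------------------------------

def amplitude_spectrum(series: np.ndarray, sampling_interval: float,
                       band: tuple[float, float] = (2.0, 30.0)) -> Spectrum:
    """Hann-windowed DFT amplitude vs. period, area-normalized over the band.

    The mean is removed before windowing; amplitudes are mapped from
    frequency to period (hours), restricted to ``band`` and normalized so
    the trapezoidal integral over the band equals 1.
    """
    series = np.asarray(series, dtype=float)
    lo, hi = band
    if lo <= 0 or hi <= lo:
        raise ValueError("band must satisfy 0 < lo < hi")
    duration_h = series.size * sampling_interval / 3600.0
    if duration_h < 2.0 * hi:
        raise ValueError("series must cover at least twice the longest band period")
    x = series - series.mean()
    x = x * np.hanning(x.size)
    amp = np.abs(np.fft.rfft(x))
    freq = np.fft.rfftfreq(series.size, d=sampling_interval)  # Hz
    with np.errstate(divide="ignore"):
        periods_h = 1.0 / freq / 3600.0
    sel = (periods_h >= lo) & (periods_h <= hi)
    if sel.sum() < 3:
        raise ValueError("band outside resolvable range for this record")
    p = periods_h[sel][::-1]
    a = amp[sel][::-1]
    area = np.trapezoid(a, p)
    if area <= 0:
        raise ValueError("zero spectral mass in band; cannot normalize")
    return Spectrum(periods=p, amplitudes=a / area)


def peak_period(spec: Spectrum, band: tuple[float, float] | None = None) -> float:
    """Period (hours) of maximum amplitude, optionally within a sub-band."""
    p, a = spec.periods, spec.amplitudes
    if band is not None:
        sel = (p >= band[0]) & (p <= band[1])
        if not sel.any():
            raise ValueError("empty band")
        p, a = p[sel], a[sel]
    return float(p[np.argmax(a)])


def free_running_period(bouts: BoutSeries, fold_guess: float = 24.0) -> float:
    """Free-running period (hours) from the drift of main sleep onsets.

    The main sleep onset of each cycle is the onset of the longest sleep
    bout within a window one fold-period long; successive windows start
    0.8 fold-periods after the previous onset.  The period is the
    least-squares slope of onset time against cycle index.  Non-monophasic
    records (short or irregular main bouts) fall back to the spectral
    fundamental with a warning.
    """
    sleeps = [(s, e) for s, e, st in bouts.intervals if st == "sleep"]
    if not sleeps:
        raise ValueError("no sleep bouts in record")
    t0, t1 = bouts.span
    P0 = fold_guess * 3600.0
    onsets = []
    cursor = t0
    while cursor + P0 <= t1 + bouts.sampling_interval:
        window = [(s, e) for s, e in sleeps if cursor <= s < cursor + P0]
        if window:
            s_main, e_main = max(window, key=lambda se: se[1] - se[0])
            onsets.append((s_main, e_main - s_main))
            cursor = s_main + 0.8 * P0
        else:
            cursor += P0
    if len(onsets) < 10:
        raise ValueError(f"too few main sleep onsets ({len(onsets)}; need >= 10)")
    times = np.array([o for o, _ in onsets])
    durs = np.array([d for _, d in onsets])
    diffs = np.diff(times) / 3600.0
    monophasic = (np.median(durs) >= 2.0 * 3600.0
                  and np.all(np.abs(diffs - np.median(diffs)) < 0.3 * fold_guess))
    if not monophasic:
        warnings.warn("record is not cleanly monophasic; falling back to the "
                      "spectral fundamental", stacklevel=2)
        _, flags = bouts.wake_flags()
        spec = amplitude_spectrum(flags.astype(float), bouts.sampling_interval,
                                  band=(0.7 * fold_guess, 1.5 * fold_guess))
        return peak_period(spec)
    k = np.arange(times.size)
    slope = np.polyfit(k, times, 1)[0]
    return float(slope / 3600.0)


def fold_average(series: np.ndarray, sampling_interval: float,
                 fold_period: float = 24.0, n_bins: int = 144,
                 t0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Average a series over all cycles of ``fold_period`` hours.

    Returns (bin centers in hours, per-bin means); the standard daily
    waveform used for phenotype classification.
    """
    series = np.asarray(series, dtype=float)
    t = t0 + sampling_interval * np.arange(series.size)
    phase = (t / 3600.0) % fold_period
    idx = np.minimum((phase / fold_period * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=series, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    centers = (np.arange(n_bins) + 0.5) * fold_period / n_bins
    return centers, means
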