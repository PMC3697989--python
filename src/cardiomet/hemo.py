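"""Beat-to-beat analysis of arterial-pressure waveforms.

Converts a continuous pressure recording into per-beat systolic (SAP),
diastolic (DAP) and mean (MAP) pressures and heart rate, the form in
which all downstream hemodynamic quantities (Table-2-style summaries,
the systogram for spectral analysis) are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator

#: Physiologic heart-rate band for conscious rats, bpm.
DEFAULT_MIN_HR = 200.0
DEFAULT_MAX_HR = 500.0


@dataclass
class BeatSeries:
    """Per-beat hemodynamics extracted from a pressure waveform.

    A "beat" spans one systolic peak to the next, so ``n`` detected peaks
    yield ``n - 1`` complete beats; partial edge beats are discarded.
    """

    beat_times: np.ndarray  # s, time of the beat's systolic peak
    sap: np.ndarray         # mmHg
    dap: np.ndarray         # mmHg
    map: np.ndarray         # mmHg, time-average of the waveform over the beat
    rr: np.ndarray          # s
    hr: np.ndarray          # bpm
    mean_beat_rate: float   # Hz, (n_peaks - 1) / (t_last - t_first)
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.sap.size


def detect_beats(
    samples: np.ndarray,
    fs: float,
    min_hr: float = DEFAULT_MIN_HR,
    max_hr: float = DEFAULT_MAX_HR,
    prominence_frac: float = 0.3,
) -> np.ndarray:
    """Locate systolic peaks in a pressure waveform.

    Peaks are local maxima of the signal after subtraction of a rolling
    median baseline (window = one minimum-heart-rate beat period), with a
    prominence of at least ``prominence_frac`` times the signal's
    interquartile range and a refractory distance of ``60/max_hr`` seconds.
    Returns strictly increasing sample indices; a flat or featureless
    signal yields an empty array.
    """
    x = np.asarray(samples, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if not (0 < min_hr < max_hr):
        raise ValueError("require 0 < min_hr < max_hr")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")

    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return np.empty(0, dtype=int)

    win = max(3, int(round(fs * 60.0 / min_hr)) | 1)
    baseline = ndimage.median_filter(x, size=win, mode="nearest")
    refractory = max(1, int(round(fs * 60.0 / max_hr)))
    peaks, _ = signal.find_peaks(
        x - baseline, height=0.0, prominence=prominence_frac * iqr,
        distance=refractory,
    )
    return peaks


def beat_series(samples: np.ndarray, fs: float, peaks: np.ndarray) -> BeatSeries:
    """Per-beat SAP/DAP/MAP/HR from systolic peak indices.

    SAP is the maximum of the waveform over the beat window, DAP the
    minimum strictly between successive peaks, and MAP the time-average of
    the waveform over the beat (measured from the signal, not the
    DAP + PP/3 approximation).
    """
    x = np.asarray(samples, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2:
        raise ValueError("need at least 2 systolic peaks for one beat")
    n = peaks.size - 1
    sap = np.empty(n)
    dap = np.empty(n)
    map_ = np.empty(n)
    for i in range(n):
        w = x[peaks[i]:peaks[i + 1]]
        # systolic max over the beat's own systole (up to mid-beat), so the
        # next beat's upstroke cannot masquerade as this beat's SAP
        mid = (peaks[i] + peaks[i + 1]) // 2
        sap[i] = x[peaks[i]:max(mid, peaks[i] + 1)].max()
        dap[i] = x[peaks[i] + 1:peaks[i + 1]].min()
        map_[i] = w.mean()
    rr = np.diff(peaks) / fs
    hr = 60.0 / rr
    rate = (peaks.size - 1) / ((peaks[-1] - peaks[0]) / fs)
    return BeatSeries(
        beat_times=peaks[:-1] / fs, sap=sap, dap=dap, map=map_,
        rr=rr, hr=hr, mean_beat_rate=rate,
    )


def summarize_hemodynamics(series: BeatSeries) -> dict:
    """Recording-level means and the systogram for spectral analysis."""
    if len(series) == 0:
        raise ValueError("empty beat series")
    return {
        "sap_mmHg": float(series.sap.mean()),
        "dap_mmHg": float(series.dap.mean()),
        "map_mmHg": float(series.map.mean()),
        "hr_bpm": float(series.hr.mean()),
        "n_beats": len(series),
        "mean_beat_rate_hz": series.mean_beat_rate,
        "systogram": series.sap,
    }


class BeatSeriesExtractor(BaseEstimator):
    """Beat-to-beat extractor with a scikit-learn estimator surface.

    Parameters
    ----------
    min_hr, max_hr : float
        Physiologic heart-rate band, bpm (defaults 200-500 for rats).
    prominence_frac : float
        Peak prominence threshold as a fraction of the signal IQR.

    Attributes (after ``fit``)
    --------------------------
    peaks_ : ndarray of systolic peak sample indices
    series_ : BeatSeries
    summary_ : dict of recording-level means plus the systogram
    """

    def __init__(self, min_hr: float = DEFAULT_MIN_HR, max_hr: float = DEFAULT_MAX_HR,
                 prominence_frac: float = 0.3):
        self.min_hr = min_hr
        self.max_hr = max_hr
        self.prominence_frac = prominence_frac

    def fit(self, samples: np.ndarray, fs: float):
        self.peaks_ = detect_beats(
            samples, fs, self.min_hr, self.max_hr, self.prominence_frac)
        if self.peaks_.size < 2:
            warnings.warn("fewer than 2 beats detected", stacklevel=2)
            self.series_ = None
            self.summary_ = {"n_beats": 0}
            return self
        self.series_ = beat_series(samples, fs, self.peaks_)
        self.summary_ = summarize_hemodynamics(self.series_)
        return self
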