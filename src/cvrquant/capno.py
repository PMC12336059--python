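"""End-tidal CO2 extraction from raw capnograph traces.

A capnograph records the CO2 partial pressure of exhaled air continuously
(nominally at 20 Hz). The end-tidal value of each breath — the local maximum
reached at the end of exhalation — tracks arterial CO2 and is the quantity
the CVR models regress against. This module detects the breath-wise end-tidal
envelope, resamples it onto an MRI frame grid, and computes the scalar
summaries (mean, bottom-quartile baseline, hypercapnic delta) that the CVR
formulas consume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ParameterError, ShapeError, SignalQualityError
from .protocol import Protocol


@dataclass(frozen=True)
class CapnoTrace:
    """Raw capnograph waveform: uniform time base (s) and pCO2 (mmHg)."""

    time: np.ndarray
    pco2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        p = np.asarray(self.pco2, float)
        if t.shape != p.shape or t.ndim != 1:
            raise ShapeError("time and pco2 must be 1-D arrays of equal length")
        if t.size < 2:
            raise ParameterError("trace needs at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ParameterError("time must be strictly increasing")
        if np.ptp(dt) > 0.01 * np.mean(dt):
            raise ParameterError("sampling must be uniform within 1%")
        if np.any(p < 0):
            raise ParameterError("pco2 must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pco2", p)

    @property
    def rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / float(np.mean(np.diff(self.time)))

    @classmethod
    def from_csv(cls, path) -> "CapnoTrace":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "pco2_mmhg": self.pco2}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class EtCO2Curve:
    """Breath-wise end-tidal CO2 envelope.

    ``breath_times``/``breath_etco2`` hold one (time, mmHg) point per breath.
    ``resampled_times``/``resampled_etco2`` hold the envelope linearly
    interpolated onto an analysis grid (constant-extrapolated at the edges)
    after applying ``shift_s``: a resampled value at time ``t`` is the
    envelope evaluated at ``t - shift_s``.
    """

    breath_times: np.ndarray
    breath_etco2: np.ndarray
    resampled_times: np.ndarray | None = None
    resampled_etco2: np.ndarray | None = None
    shift_s: float = 0.0

    def __post_init__(self) -> None:
        bt = np.asarray(self.breath_times, float)
        be = np.asarray(self.breath_etco2, float)
        if bt.shape != be.shape or bt.ndim != 1 or bt.size == 0:
            raise ShapeError("breath arrays must be equal-length 1-D and non-empty")
        object.__setattr__(self, "breath_times", bt)
        object.__setattr__(self, "breath_etco2", be)

    def value_at(self, t, shift_s: float | None = None) -> np.ndarray:
        """Envelope at time(s) ``t`` shifted by ``shift_s`` (default: own shift)."""
        s = self.shift_s if shift_s is None else shift_s
        t = np.asarray(t, float)
        return np.interp(t - s, self.breath_times, self.breath_etco2)

    def resample(self, times, shift_s: float | None = None) -> "EtCO2Curve":
        """Return a copy resampled onto ``times`` with the given shift."""
        s = self.shift_s if shift_s is None else float(shift_s)
        times = np.asarray(times, float)
        return replace(
            self,
            resampled_times=times,
            resampled_etco2=self.value_at(times, shift_s=s),
            shift_s=s,
        )


@dataclass(frozen=True)
class EtCO2Summary:
    """Scalar summaries of an end-tidal curve (all in mmHg)."""

    mean_etco2: float
    baseline_etco2: float
    delta_etco2: float


def _refine_peak_times(trace: CapnoTrace, peaks: np.ndarray, window: float) -> np.ndarray:
    """Sub-sample peak times from a local parabola fit around each maximum.

    The sampled waveform is flat near an end-tidal plateau, so the discrete
    argmax jitters by a sample or two under instrument noise; a least-squares
    quadratic over ``+-window`` seconds pins the vertex far more precisely.
    The refined time is clamped to the window around the discrete peak.
    """
    fs = trace.rate
    half = max(2, int(round(window * fs)))
    times = trace.time[peaks].copy()
    for j, p in enumerate(peaks):
        lo, hi = max(0, p - half), min(trace.time.size, p + half + 1)
        t = trace.time[lo:hi] - trace.time[p]
        y = trace.pco2[lo:hi]
        a, b, _ = np.polyfit(t, y, 2)
        if a < 0:
            vertex = -b / (2.0 * a)
            if abs(vertex) <= window:
                times[j] = trace.time[p] + vertex
    return times


def detect_envelope(
    trace: CapnoTrace,
    min_breath_interval: float = 2.0,
    prominence_frac: float = 0.25,
    min_prominence: float = 1.0,
    refine_window: float = 0.5,
    grid_times: np.ndarray | None = None,
) -> EtCO2Curve:
    """Detect the breath-wise end-tidal envelope of a capnograph trace.

    Breaths are local maxima of the waveform separated by at least
    ``min_breath_interval`` seconds, with prominence of at least
    ``max(min_prominence, prominence_frac * peak-to-peak)`` mmHg. One
    end-tidal value is reported per breath (the maximum sample); breath
    times are refined to sub-sample precision with a local parabola fit
    (``refine_window`` seconds, 0 disables). Fewer than three detected
    breaths raises :class:`SignalQualityError`.
    """
    if min_breath_interval <= 0:
        raise ParameterError("min_breath_interval must be > 0")
    fs = trace.rate
    distance = max(1, int(round(min_breath_interval * fs)))
    prom = max(min_prominence, prominence_frac * float(np.ptp(trace.pco2)))
    peaks, _ = find_peaks(trace.pco2, distance=distance, prominence=prom)
    if peaks.size < 3:
        raise SignalQualityError(
            f"only {peaks.size} breaths detected; need at least 3"
        )
    times = trace.time[peaks]
    if refine_window > 0:
        times = _refine_peak_times(trace, peaks, refine_window)
    curve = EtCO2Curve(times, trace.pco2[peaks])
    if grid_times is not None:
        curve = curve.resample(grid_times)
    return curve


def _bottom_quartile_mean(values: np.ndarray, fraction: float = 0.25) -> float:
    """Mean of the lowest ``fraction`` of samples (at least one sample)."""
    v = np.sort(np.asarray(values, float))
    k = max(1, int(np.ceil(fraction * v.size)))
    return float(v[:k].mean())


def summarize(
    curve: EtCO2Curve,
    protocol: Protocol | None = None,
    baseline_fraction: float = 0.25,
) -> EtCO2Summary:
    """Mean, baseline and delta of an end-tidal curve.

    ``mean_etco2`` is the arithmetic mean and ``baseline_etco2`` the mean of
    the lowest ``baseline_fraction`` of the resampled (duration-weighted)
    samples; breath-wise values are used when the curve has not been
    resampled. Without a protocol, ``delta_etco2 = mean - baseline`` (the
    quantity entering the map-referencing denominator). With a protocol, the
    delta is the mean over hypercapnic-block samples minus the baseline — the
    physiological rise driven by the gas challenge.
    """
    if curve.resampled_etco2 is not None and len(curve.resampled_etco2):
        values = np.asarray(curve.resampled_etco2, float)
        times = np.asarray(curve.resampled_times, float)
    else:
        values = np.asarray(curve.breath_etco2, float)
        times = np.asarray(curve.breath_times, float)
    if values.size == 0:
        raise ParameterError("empty curve")
    mean = float(values.mean())
    baseline = _bottom_quartile_mean(values, baseline_fraction)
    if protocol is not None:
        hc = protocol.is_hypercapnic(times)
        if not hc.any():
            raise ParameterError("protocol has no hypercapnic samples in curve")
        delta = float(values[hc].mean()) - baseline
    else:
        delta = mean - baseline
    return EtCO2Summary(mean, baseline, delta)


def etco2_during_scan(curve: EtCO2Curve, window: tuple[float, float]) -> float:
    """Mean breath-wise EtCO2 within ``window = (start_s, end_s)``.

    Used to obtain the per-scan EtCO2 values entering the flow-based CVR
    ratio (room-air scan and steady-state hypercapnic scan).
    """
    start, end = window
    if end <= start:
        raise ParameterError("window end must exceed start")
    sel = (curve.breath_times >= start) & (curve.breath_times < end)
    if not sel.any():
        raise SignalQualityError("no breaths inside the requested window")
    return float(curve.breath_etco2[sel].mean())
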