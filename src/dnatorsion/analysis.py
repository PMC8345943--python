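"""Observables computed from trajectories.

The primary observable is the chain-mean angular deviation
φ̄(t) = (1/n)Σᵢφᵢ(t) of a chain, summarized after discarding an initial
transient (default cutoff 0.5 ns, within which runs at different drive
frequencies are indistinguishable) by

* an oscillation amplitude — half the peak-to-trough range of the
  mean-subtracted post-cutoff segment (the signals are neither sinusoidal
  nor stationary, so a range-based amplitude matches what trajectory plots
  show better than an RMS would); alternative estimators are available for
  sensitivity reporting;
* a dominant frequency — the maximal peak of the Hann-windowed periodogram
  of that segment.  Only frequencies completing at least two full cycles
  within the segment are reportable; the zero bin and the sub-two-cycle
  bins are excluded and the resolution is ±1/(segment duration).  All
  frequencies are ordinary frequencies in cycles/s; a drive's angular
  frequency ω compares via f = ω/2π.
* optionally a time-resolved frequency track over sliding windows, a purely
  descriptive diagnostic of how the oscillation frequency wanders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .integration import Trajectory

TRANSIENT_CUTOFF_DEFAULT = 0.5e-9  # s

AMPLITUDE_METHODS = ("half_range", "rms_sqrt2", "max_abs")


@dataclass
class SeriesObservable:
    """A scalar time series (rad) with a transient cutoff for summaries."""

    times: np.ndarray
    values: np.ndarray
    transient_cutoff: float = TRANSIENT_CUTOFF_DEFAULT
    label: str = ""

    def __post_init__(self) -> None:
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.transient_cutoff < 0:
            raise ValueError("transient_cutoff must be >= 0")

    def post_transient(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.times >= self.transient_cutoff
        return self.times[mask], self.values[mask]


@dataclass
class RunSummary:
    """Post-transient amplitude and dominant frequency of one run."""

    amplitude: float
    dominant_frequency: float
    frequency_track: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def mean_angular_deviation(
    traj: Trajectory, chain: int = 1, transient_cutoff: float = TRANSIENT_CUTOFF_DEFAULT
) -> SeriesObservable:
    """The unweighted site mean of a chain's angles at each recorded time."""
    if chain == 1:
        values = traj.mean1
    elif chain == 2:
        values = traj.mean2
    else:
        raise ValueError(f"chain must be 1 or 2, got {chain}")
    if traj.times.shape[0] == 0:
        raise ValueError("trajectory is empty")
    return SeriesObservable(
        times=traj.times.copy(),
        values=values.copy(),
        transient_cutoff=transient_cutoff,
        label=f"mean_phi{chain}",
    )


def amplitude(series: SeriesObservable, method: str = "half_range") -> float:
    """Oscillation amplitude (rad) of the post-cutoff segment.

    ``half_range``  half the peak-to-trough range after mean subtraction
                    (the default, and what the trajectory figures show);
    ``rms_sqrt2``   sqrt(2)·RMS, exact for a pure sinusoid;
    ``max_abs``     maximum |deviation from the segment mean|.
    """
    if method not in AMPLITUDE_METHODS:
        raise ValueError(f"unknown amplitude method {method!r}")
    _, vals = series.post_transient()
    if vals.size == 0:
        raise ValueError("no samples beyond the transient cutoff")
    detrended = vals - vals.mean()
    if method == "half_range":
        return float((detrended.max() - detrended.min()) / 2.0)
    if method == "rms_sqrt2":
        return float(np.sqrt(2.0) * np.sqrt(np.mean(detrended**2)))
    return float(np.abs(detrended).max())


def _segment_periodogram(times: np.ndarray, vals: np.ndarray):
    dt = times[1] - times[0]
    freqs, power = periodogram(vals - vals.mean(), fs=1.0 / dt, window="hann")
    return freqs, power


def dominant_frequency(series: SeriesObservable) -> float:
    """Frequency (cycles/s) of the strongest reportable periodogram peak.

    Bin k of an N-sample periodogram completes k cycles over the segment,
    so bins 0 and 1 (fewer than two full cycles — indistinguishable from a
    trend) are never reportable.  Raises if the segment is too short to
    contain any reportable bin; resolution is ±1/(segment duration).
    """
    times, vals = series.post_transient()
    if vals.size < 8:
        dur = 0.0 if times.size < 2 else times[-1] - times[0]
        raise ValueError(
            "post-cutoff segment too short for a frequency estimate "
            f"({vals.size} samples, duration {dur:.3e} s); the resolution "
            "floor is 1/(segment duration)"
        )
    freqs, power = _segment_periodogram(times, vals)
    k = 2 + int(np.argmax(power[2:]))
    return float(freqs[k])


def time_resolved_frequency(
    series: SeriesObservable, window: float, hop: float
) -> list[tuple[float, float]]:
    """Dominant frequency on sliding windows: a descriptive drift track.

    Windows of duration ``window`` advance by ``hop`` across the
    post-cutoff segment; each contributes (window center, dominant
    frequency).  Windows too short for a reportable bin are skipped.
    """
    times, vals = series.post_transient()
    if times.size < 2:
        raise ValueError("post-cutoff segment too short")
    span = times[-1] - times[0]
    if window > span:
        raise ValueError(f"window {window:.3e} s exceeds post-cutoff span {span:.3e} s")
    sample_dt = times[1] - times[0]
    if window < 2 * sample_dt:
        raise ValueError("window must cover at least 2 samples")
    track: list[tuple[float, float]] = []
    t0 = times[0]
    while t0 + window <= times[-1] + 0.5 * sample_dt:
        mask = (times >= t0) & (times < t0 + window)
        sub_t, sub_v = times[mask], vals[mask]
        if sub_v.size >= 8:
            freqs, power = _segment_periodogram(sub_t, sub_v)
            if freqs.size > 3:
                k = 2 + int(np.argmax(power[2:]))
                track.append((float(t0 + window / 2.0), float(freqs[k])))
        t0 += hop
    return track


def amplitude_ratio(a: RunSummary, b: RunSummary) -> float:
    """a.amplitude / b.amplitude; both must use the same cutoff and estimator."""
    for key in ("transient_cutoff", "amplitude_method"):
        if key in a.metadata and key in b.metadata and a.metadata[key] != b.metadata[key]:
            raise ValueError(f"run summaries differ in {key}; ratio is not comparable")
    if b.amplitude == 0.0:
        raise ZeroDivisionError("reference amplitude is zero")
    return a.amplitude / b.amplitude


def summarize(
    traj: Trajectory,
    chain: int = 1,
    transient_cutoff: float = TRANSIENT_CUTOFF_DEFAULT,
    amplitude_method: str = "half_range",
    track_window: float | None = None,
    track_hop: float | None = None,
) -> RunSummary:
    """Amplitude + dominant frequency of a trajectory's chain-mean series."""
    series = mean_angular_deviation(traj, chain=chain, transient_cutoff=transient_cutoff)
    amp = amplitude(series, method=amplitude_method)
    freq = dominant_frequency(series)
    track = []
    if track_window is not None:
        hop = track_hop if track_hop is not None else track_window / 2.0
        track = time_resolved_frequency(series, window=track_window, hop=hop)
    meta = dict(traj.metadata)
    meta["transient_cutoff"] = transient_cutoff
    meta["amplitude_method"] = amplitude_method
    meta["chain"] = chain
    return RunSummary(
        amplitude=amp, dominant_frequency=freq, frequency_track=track, metadata=meta
    )
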