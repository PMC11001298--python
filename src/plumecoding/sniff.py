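"""Sniff detection and sniff-gated (perceived) odor statistics.

Positive deflections of the pressure trace indicate inhalation. Sniff
peaks are local maxima of the trace; each sniff onset is the last
non-positive-to-positive sign change before its peak, and the inhalation
period is the half-open interval [onset, peak). The estimated perceived
odor of a trial is the concentration sampled only during inhalation
periods inside the 6 s odor window, and the perceived intermittency is
the fraction of those samples at or above 0.1*C0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import StimulusTrace, Trace
from .stimulus import THRESHOLD_FRAC

#: Shortest plausible inter-sniff interval (12 Hz sniffing).
MIN_INTERVAL_S = 1.0 / 12.0


@dataclass
class SniffEvents:
    """Detected (or ground-truth) sniff onsets and peaks, in seconds."""

    onsets: np.ndarray
    peaks: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.onsets.size != self.peaks.size:
            raise ValueError("onsets and peaks must pair up")
        if self.onsets.size:
            if np.any(np.diff(self.onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if np.any(self.peaks <= self.onsets):
                raise ValueError("each onset must precede its peak")

    @property
    def n(self) -> int:
        return self.onsets.size

    def inhalation_intervals(self) -> np.ndarray:
        """(onset, peak) pairs as an (n, 2) array."""
        return np.column_stack((self.onsets, self.peaks)) if self.n else \
            np.empty((0, 2))


def detect_sniffs(pressure: Trace, min_interval_s: float = MIN_INTERVAL_S,
                  min_prominence: float | None = None) -> SniffEvents:
    """Find inhalation peaks and their preceding sign-change onsets.

    Peaks must exceed ``min_prominence`` (default: 1.5x the MAD-based
    robust SD of the trace — low enough that the first inhalation of a
    recording, whose prominence is edge-limited, still registers) and be
    at least ``min_interval_s`` apart. A peak with no non-positive sample
    before it is dropped.
    """
    if not min_interval_s > 0:
        raise ValueError("min_interval_s must be positive")
    v = pressure.values
    if not np.all(np.isfinite(v)):
        raise ValueError("pressure trace contains non-finite samples")
    if min_prominence is None:
        mad = np.median(np.abs(v - np.median(v)))
        min_prominence = 1.5 * 1.4826 * mad
        if min_prominence == 0:
            min_prominence = np.finfo(float).tiny
    distance = max(int(round(min_interval_s * pressure.rate)), 1)
    # bracket with the global minimum so first/last peaks are not
    # penalized by edge-limited prominence
    vp = np.concatenate(([v.min()], v, [v.min()]))
    peak_idx, _ = find_peaks(vp, prominence=min_prominence, distance=distance)
    peak_idx = peak_idx - 1
    peak_idx = peak_idx[(peak_idx >= 0) & (peak_idx < v.size)]
    peak_idx = peak_idx[v[peak_idx] > 0]
    onsets, peaks = [], []
    nonpos = v <= 0
    for p in peak_idx:
        # last index i < p with v[i] <= 0 < v[i+1]
        before = np.flatnonzero(nonpos[:p])
        if before.size == 0:
            continue
        i = before[-1]
        onsets.append(pressure.t0 + i / pressure.rate)
        peaks.append(pressure.t0 + p / pressure.rate)
    # enforce strict ordering (two peaks can share an onset if no
    # non-positive sample separates them; keep the first)
    keep_on, keep_pk, last = [], [], -np.inf
    for o, p in zip(onsets, peaks):
        if o > last:
            keep_on.append(o)
            keep_pk.append(p)
            last = o
    return SniffEvents(onsets=np.asarray(keep_on), peaks=np.asarray(keep_pk))


def _perceived_indices(stimulus: StimulusTrace, events: SniffEvents,
                       t_stop: float | None = None) -> np.ndarray:
    """Sample indices of the stimulus falling inside inhalation periods
    intersected with [odor onset, t_stop), in temporal order."""
    if t_stop is None:
        t_stop = stimulus.odor_offset
    t_on = stimulus.odor_onset
    rate = stimulus.rate
    idx = []
    for onset, peak in events.inhalation_intervals():
        a = max(onset, t_on)
        b = min(peak, t_stop)
        if b <= a:
            continue
        i0 = int(np.ceil((a - stimulus.t0) * rate - 1e-9))
        i1 = int(np.ceil((b - stimulus.t0) * rate - 1e-9))
        if i1 > i0:
            idx.append(np.arange(i0, i1))
    if not idx:
        return np.empty(0, dtype=int)
    return np.concatenate(idx)


def perceived_odor(stimulus: StimulusTrace, events: SniffEvents) -> np.ndarray:
    """Concentration samples falling inside inhalation periods within the
    6 s odor window, concatenated in order (length = T * rate with T the
    total inhalation time)."""
    idx = _perceived_indices(stimulus, events)
    if idx.size == 0:
        warnings.warn("zero total inhalation time in the odor window",
                      stacklevel=2)
    return stimulus.values[idx]


def perceived_intermittency(stimulus: StimulusTrace, events: SniffEvents,
                            threshold_frac: float = THRESHOLD_FRAC) -> float:
    """Fraction of perceived-odor samples at or above 0.1*C0.

    Returns NaN (with a warning) when no inhalation falls inside the
    odor window; such trials are excluded from aggregates.
    """
    samples = perceived_odor(stimulus, events)
    if samples.size == 0:
        return float("nan")
    return float(np.count_nonzero(samples >= threshold_frac * stimulus.c0)
                 / samples.size)


def cumulative_perceived_intermittency(stimulus: StimulusTrace,
                                       events: SniffEvents,
                                       t_grid: np.ndarray,
                                       threshold_frac: float = THRESHOLD_FRAC,
                                       ) -> np.ndarray:
    """Perceived intermittency of the inhaled samples from odor onset up
    to each time in ``t_grid`` (NaN where no inhalation has occurred yet).
    The value at the full window equals :func:`perceived_intermittency`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < stimulus.odor_onset) or \
            np.any(t_grid > stimulus.odor_offset + 1e-9):
        raise ValueError("t_grid must lie within the odor window")
    idx = _perceived_indices(stimulus, events)
    if idx.size == 0:
        return np.full(t_grid.shape, np.nan)
    times = stimulus.t0 + idx / stimulus.rate
    supra = (stimulus.values[idx] >= threshold_frac * stimulus.c0).astype(float)
    csum = np.cumsum(supra)
    out = np.empty(t_grid.shape)
    for k, t in enumerate(t_grid):
        m = int(np.searchsorted(times, t, side="right"))
        out[k] = csum[m - 1] / m if m > 0 else np.nan
    return out


def mean_sniff_frequency(events: SniffEvents,
                         window: tuple[float, float]) -> float:
    """Peak count inside the window divided by the window duration (Hz)."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive duration")
    n = int(np.count_nonzero((events.peaks >= t0) & (events.peaks < t1)))
    return n / (t1 - t0)
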