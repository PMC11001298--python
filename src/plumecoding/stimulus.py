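"""Stimulus quantification: intermittency, whiffs, normalization, gain, CS labels.

Intermittency gamma of a concentration trace C(t) is the probability that
the concentration exceeds a fixed detection threshold,

    gamma = Prob[C >= 0.1 * C0],

with C0 the gain-1 source (maximum) concentration. The statistic is always
evaluated over the 6 s odor presentation window, and the threshold is tied
to the gain-1 C0 so that halving the delivered gain does not move it.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional, Tuple

import numpy as np

from .core import StimulusTrace

THRESHOLD_FRAC = 0.1

#: Go/No-Go class bands: lick for gamma >= 0.2 (CS+), withhold for
#: gamma <= 0.15 (CS-); the gap is explicitly excluded.
CS_PLUS_MIN = 0.2
CS_MINUS_MAX = 0.15


def _supra(trace: StimulusTrace, window: Optional[Tuple[float, float]],
           threshold_frac: float) -> np.ndarray:
    if window is None:
        window = (trace.odor_onset, trace.odor_offset)
    vals = trace.window(*window)
    if vals.size == 0:
        raise ValueError("empty window for intermittency computation")
    return vals >= threshold_frac * trace.c0


def compute_intermittency(trace: StimulusTrace,
                          window: Optional[Tuple[float, float]] = None,
                          threshold_frac: float = THRESHOLD_FRAC) -> float:
    """Fraction of window samples with C >= threshold_frac * C0.

    The comparison is inclusive and the threshold is relative to the
    gain-1 ``c0`` stored on the trace, never to the trace's own maximum.
    """
    supra = _supra(trace, window, threshold_frac)
    return float(np.count_nonzero(supra) / supra.size)


def normalize_trace(values: np.ndarray, c0: float = 1.0) -> np.ndarray:
    """Affinely rescale so the peak equals ``c0`` (shape preserved)."""
    values = np.asarray(values, dtype=float)
    peak = values.max(initial=-np.inf)
    if not peak > 0:
        raise ValueError("cannot normalize a trace with non-positive maximum")
    return values * (c0 / peak)


def binarize_trace(trace: StimulusTrace,
                   threshold_frac: float = THRESHOLD_FRAC) -> StimulusTrace:
    """Threshold at 0.1*C0: supra-threshold samples go to the delivered
    maximum ``c0 * gain``, the rest to zero. Intermittency is preserved
    exactly because the supra-threshold sample set is unchanged."""
    supra = trace.values >= threshold_frac * trace.c0
    out = np.where(supra, trace.c0 * trace.gain, 0.0)
    return replace(trace, values=out, kind="binary")


def apply_gain(trace: StimulusTrace, gain: float) -> StimulusTrace:
    """Scale delivered concentration by ``gain``; nominal intermittency and
    the 0.1*C0 threshold are unchanged (C0 stays the gain-1 maximum)."""
    if not 0 < gain <= 1:
        raise ValueError("gain must lie in (0, 1]")
    if gain <= THRESHOLD_FRAC:
        warnings.warn(
            f"gain {gain} <= detection threshold fraction {THRESHOLD_FRAC}: "
            "whiffs of a binarized stimulus fall below 0.1*C0",
            stacklevel=2,
        )
    return replace(trace, values=trace.values * gain, gain=trace.gain * gain)


def count_whiffs(trace: StimulusTrace,
                 window: Optional[Tuple[float, float]] = None,
                 threshold_frac: float = THRESHOLD_FRAC) -> int:
    """Number of maximal contiguous supra-threshold runs in the odor window.

    Whiffs separated by even a single sub-threshold sample count as
    distinct runs (no gap merging).
    """
    supra = _supra(trace, window, threshold_frac)
    # a run starts wherever supra goes False -> True (or at sample 0)
    starts = np.flatnonzero(np.diff(np.concatenate(([False], supra)).astype(np.int8)) == 1)
    return int(starts.size)


def whiff_intervals(trace: StimulusTrace,
                    window: Optional[Tuple[float, float]] = None,
                    threshold_frac: float = THRESHOLD_FRAC) -> np.ndarray:
    """(start, stop) times in seconds of each supra-threshold run in the
    window, half-open in sample space."""
    if window is None:
        window = (trace.odor_onset, trace.odor_offset)
    sl = trace.window_indices(*window)
    supra = trace.values[sl] >= threshold_frac * trace.c0
    padded = np.concatenate(([False], supra, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    t_first = trace.t0 + sl.start / trace.rate
    return np.column_stack((t_first + starts / trace.rate,
                            t_first + stops / trace.rate))


def blank_intervals(trace: StimulusTrace,
                    window: Optional[Tuple[float, float]] = None,
                    threshold_frac: float = THRESHOLD_FRAC) -> np.ndarray:
    """Complement of :func:`whiff_intervals` inside the window."""
    if window is None:
        window = (trace.odor_onset, trace.odor_offset)
    whiffs = whiff_intervals(trace, window, threshold_frac)
    edges = [window[0]]
    for a, b in whiffs:
        edges.extend((a, b))
    edges.append(window[1])
    pairs = np.asarray(edges).reshape(-1, 2)
    return pairs[pairs[:, 1] - pairs[:, 0] > 1e-12]


def label_cs(nominal_intermittency: float) -> str:
    """Map nominal intermittency to the Go/No-Go class.

    <= 0.15 -> CSminus, >= 0.2 -> CSplus, the open gap in between ->
    'excluded' (never silently assigned to either band).
    """
    g = float(nominal_intermittency)
    if not 0 <= g <= 1:
        raise ValueError("intermittency must lie in [0, 1]")
    if g <= CS_MINUS_MAX:
        return "CSminus"
    if g >= CS_PLUS_MIN:
        return "CSplus"
    return "excluded"
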