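"""Imaging preprocessing: dF/F, bandpass, bleach correction, deconvolution,
z-scoring, first-sniff response metrics and responder detection.

The chain applied to each raw glomerular fluorescence trace is

    raw F -> dF/F -> 0.075-10 Hz Butterworth (zero-phase)
          -> quadratic bleach correction (fit on pre+post odor windows)
          -> exponential-kernel deconvolution (tau = 150 ms)
          -> z-score against the 2 s pre-odor baseline.

Deconvolution exactly inverts the discrete causal AR(1) kernel
c_t = a*c_{t-1} + (1-a)*r_t with a = exp(-dt/tau), so
convolve(deconvolve(x)) == x to numerical precision. Filtering is
zero-phase (forward-backward), which doubles the effective filter order
but keeps response latencies (T75) free of filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import ODOR_DURATION_S, ODOR_ONSET_S, Trace
from .sniff import SniffEvents
from .synthetic import exp_kernel_convolve

TAU_S = 0.150
BAND_HZ = (0.075, 10.0)
DFF_BASELINE_S = 0.100
ZSCORE_BASELINE_S = 2.0
RESPONSE_Z_THRESHOLD = 2.0       # trial responds iff amplitude > 2 (strict)
RESPONDER_TRIAL_FRAC = 0.10      # glomerulus kept iff > 10% of trials respond
FIRST_SNIFF_MAX_WINDOW_S = 1.0


@dataclass
class ProcessedResponse:
    """All derived traces and first-sniff scalars for one glomerulus-trial."""

    dff: Trace
    rate: Trace
    z: Optional[Trace]
    amplitude: float = float("nan")   # trough-to-peak of z in the window
    t75: float = float("nan")         # s from first odor sniff onset
    responded: bool = False
    valid: bool = True                # False when sigma_pre == 0 or no sniff


def compute_dff(raw: Trace, odor_onset: float = ODOR_ONSET_S,
                baseline_s: float = DFF_BASELINE_S) -> Trace:
    """(F - F0) / F0 with F0 the mean of the ``baseline_s`` window ending
    at odor onset."""
    if odor_onset - raw.t0 < baseline_s - 1e-9:
        raise ValueError("need at least the baseline window before odor onset")
    f0 = raw.window(odor_onset - baseline_s, odor_onset).mean()
    if not f0 > 0:
        raise ValueError(f"invalid dF/F baseline F0={f0!r}")
    return raw.with_values((raw.values - f0) / f0)


def bandpass(trace: Trace, band_hz: tuple[float, float] = BAND_HZ,
             order: int = 4) -> Trace:
    """Zero-phase 4th-order Butterworth bandpass (default 0.075-10 Hz).

    Implemented with second-order sections and maximal odd-extension
    padding: the 0.075 Hz corner has a ~2 s time constant, so the default
    filtfilt padding (a fraction of a second) leaves edge transients that
    bleed across a 9 s trial.
    """
    lo, hi = band_hz
    if not 0 < lo < hi < trace.rate / 2:
        raise ValueError("band edges must satisfy 0 < lo < hi < Nyquist")
    sos = butter(order, [lo, hi], btype="bandpass", fs=trace.rate,
                 output="sos")
    min_n = 3 * (2 * sos.shape[0] + 1)
    if trace.n <= min_n:
        raise ValueError("trace shorter than the filter warm-up length")
    return trace.with_values(sosfiltfilt(sos, trace.values,
                                         padlen=trace.n - 1))


def bleach_correct(trace: Trace,
                   odor_onset: float = ODOR_ONSET_S,
                   odor_duration: float = ODOR_DURATION_S,
                   degree: int = 2,
                   post_guard_s: float = 0.5) -> Trace:
    """Fit a quadratic to the pre- and post-odor samples only and subtract
    it from the whole trace (photobleaching drift removal).

    ``post_guard_s`` excludes the first part of the post-odor window from
    the fit so that the indicator's decay tail (tau = 150 ms) does not
    bias the drift estimate.
    """
    t = trace.times()
    fit_mask = (t < odor_onset) | (t >= odor_onset + odor_duration + post_guard_s)
    if not np.any(t >= odor_onset + odor_duration + post_guard_s):
        # trace too short for the guard: fall back to the plain post window
        fit_mask = (t < odor_onset) | (t >= odor_onset + odor_duration)
    if np.count_nonzero(fit_mask) < degree + 1:
        raise ValueError("too few pre/post-odor samples for the bleach fit")
    coeffs = np.polyfit(t[fit_mask], trace.values[fit_mask], degree)
    return trace.with_values(trace.values - np.polyval(coeffs, t))


def deconvolve(trace: Trace, tau_s: float = TAU_S) -> Trace:
    """Exact inverse of the discrete causal exponential kernel.

    r_t = (c_t - a * c_{t-1}) / (1 - a), a = exp(-dt/tau), with
    r_0 = c_0 (the signal is assumed at steady state before the first
    sample, matching :func:`convolve`). No non-negativity or sparsity
    constraint is imposed.
    """
    if not tau_s > 0:
        raise ValueError("tau must be positive")
    a = float(np.exp(-1.0 / (tau_s * trace.rate)))
    c = trace.values
    r = np.empty_like(c)
    r[0] = c[0]
    r[1:] = (c[1:] - a * c[:-1]) / (1.0 - a)
    return trace.with_values(r)


def convolve(trace: Trace, tau_s: float = TAU_S) -> Trace:
    """Forward counterpart of :func:`deconvolve` (for round-trip checks
    and the synthetic forward model)."""
    return trace.with_values(exp_kernel_convolve(trace.values, tau_s, trace.rate))


def zscore_response(rate: Trace, odor_onset: float = ODOR_ONSET_S,
                    baseline_s: float = ZSCORE_BASELINE_S) -> Optional[Trace]:
    """(rate - mu_pre) / sigma_pre with moments from the ``baseline_s``
    window before odor onset. Returns None (trial flagged invalid) when
    sigma_pre is zero."""
    if odor_onset - rate.t0 < baseline_s - 1e-9:
        raise ValueError("need the full pre-odor baseline window")
    base = rate.window(odor_onset - baseline_s, odor_onset)
    mu, sd = base.mean(), base.std()
    if sd == 0:
        return None
    return rate.with_values((rate.values - mu) / sd)


def first_sniff_response(z: Trace, events: SniffEvents,
                         odor_onset: float = ODOR_ONSET_S,
                         dff: Optional[Trace] = None,
                         max_window_s: float = FIRST_SNIFF_MAX_WINDOW_S,
                         amp_smooth_frames: int = 3,
                         ) -> tuple[float, float]:
    """Amplitude and T75 of the response to the first odor sniff.

    The response window runs from the first sniff onset at/after odor
    onset to the next sniff onset (capped at ``max_window_s``). Amplitude
    is the trough-to-peak range of the z-trace in the window, measured
    after a short boxcar (``amp_smooth_frames``, 120 ms at 25 Hz): exact
    kernel inversion amplifies and anti-correlates frame noise, whose
    pointwise range in a half-second window exceeds 2 z-units by chance,
    so an unsmoothed range statistic cannot separate responders from
    silent glomeruli. T75 is the time from sniff onset until the trace
    first reaches trough + 0.75 * amplitude, measured on the dF/F-scale
    trace when one is supplied, else on the z-trace. Returns (nan, nan)
    when no odor sniff exists or the window is flat.
    """
    after = events.onsets[events.onsets >= odor_onset]
    if after.size == 0:
        return (float("nan"), float("nan"))
    t_sniff = float(after[0])
    t_end = t_sniff + max_window_s
    if after.size > 1:
        t_end = min(t_end, float(after[1]))
    sl = z.window_indices(t_sniff, t_end)
    zvals = z.values
    if amp_smooth_frames > 1:
        k = np.ones(amp_smooth_frames) / amp_smooth_frames
        zvals = np.convolve(zvals, k, mode="same")
    zw = zvals[sl]
    if zw.size == 0:
        return (float("nan"), float("nan"))
    amplitude = float(zw.max() - zw.min())
    scale = dff if dff is not None else z
    sw = scale.values[scale.window_indices(t_sniff, t_end)]
    rng_ = sw.max() - sw.min()
    if rng_ == 0:
        return (amplitude, float("nan"))
    level = sw.min() + 0.75 * rng_
    hit = np.flatnonzero(sw >= level)
    t75 = float("nan") if hit.size == 0 else float(hit[0] / scale.rate)
    return (amplitude, t75)


def preprocess_trace(raw: Trace, odor_onset: float = ODOR_ONSET_S,
                     odor_duration: float = ODOR_DURATION_S,
                     tau_s: float = TAU_S,
                     events: Optional[SniffEvents] = None,
                     ) -> ProcessedResponse:
    """Run the full chain on one raw fluorescence trace; when sniff events
    are supplied the first-sniff amplitude/T75 and the trial-level
    responder flag are filled in."""
    dff = compute_dff(raw, odor_onset)
    filtered = bandpass(dff)
    corrected = bleach_correct(filtered, odor_onset, odor_duration)
    rate = deconvolve(corrected, tau_s)
    z = zscore_response(rate, odor_onset)
    resp = ProcessedResponse(dff=dff, rate=rate, z=z)
    if z is None:
        resp.valid = False
        return resp
    if events is not None:
        amp, t75 = first_sniff_response(z, events, odor_onset, dff=corrected)
        resp.amplitude, resp.t75 = amp, t75
        if np.isnan(amp):
            resp.valid = False
        else:
            resp.responded = amp > RESPONSE_Z_THRESHOLD
    return resp


def detect_responders(responded: np.ndarray,
                      valid: Optional[np.ndarray] = None,
                      min_frac: float = RESPONDER_TRIAL_FRAC) -> bool:
    """Session-level inclusion: keep a glomerulus iff it responded on
    strictly more than ``min_frac`` of its valid trials."""
    responded = np.asarray(responded, dtype=bool)
    if valid is not None:
        responded = responded[np.asarray(valid, dtype=bool)]
    if responded.size == 0:
        return False
    return float(np.count_nonzero(responded) / responded.size) > min_frac
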