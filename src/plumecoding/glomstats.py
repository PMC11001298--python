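"""Per-glomerulus encoding statistics.

Glomerular intermittency (GI) carries the plume intermittency statistic
over to the neural response: the fraction of odor-window samples at which
the z-scored deconvolved response sits at or above z = 2. The GI slope of
a glomerulus is the OLS slope of its per-trial GI against the trial's
odor intermittency; a one-way ANOVA over the 0.2 / 0.5 / 0.8
intermittency groups (p < 0.001) flags significant encoders.

Odor (and sniff) tracking is quantified with shuffle-subtracted
cross-correlograms: Pearson coefficients over lags of -500..500 ms, minus
the mean correlogram of 10 sample-permuted copies of the response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import ODOR_DURATION_S, ODOR_ONSET_S, Trace

GI_Z_THRESHOLD = 2.0            # inclusive, GI = Prob(Z >= 2)
ENCODER_ALPHA = 1e-3
ANOVA_GROUPS = (0.2, 0.5, 0.8)
ANOVA_GROUP_TOL = 0.05
XCORR_MAX_LAG_S = 0.5
XCORR_N_SHUFFLE = 10


def compute_GI(z: Trace,
               odor_window: tuple[float, float] = (ODOR_ONSET_S,
                                                   ODOR_ONSET_S + ODOR_DURATION_S),
               threshold: float = GI_Z_THRESHOLD) -> float:
    """Fraction of odor-window samples with z >= threshold (inclusive)."""
    vals = z.window(*odor_window)
    if vals.size == 0:
        raise ValueError("odor window contains no samples")
    return float(np.count_nonzero(vals >= threshold) / vals.size)


@dataclass
class GISlopeRecord:
    roi_id: int
    slope: float
    intercept: float
    r2: float
    p_slope: float
    f_anova: float = float("nan")
    p_anova: float = float("nan")
    is_encoder: bool = False


def fit_GI_slope(gi: np.ndarray, gamma: np.ndarray,
                 roi_id: int = -1) -> GISlopeRecord:
    """OLS of per-trial GI on odor intermittency across all trials."""
    gi = np.asarray(gi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    ok = np.isfinite(gi) & np.isfinite(gamma)
    gi, gamma = gi[ok], gamma[ok]
    if gi.size < 3 or np.unique(gamma).size < 2:
        raise ValueError("need >=3 trials spanning >=2 intermittency values")
    res = stats.linregress(gamma, gi)
    return GISlopeRecord(roi_id=roi_id, slope=float(res.slope),
                         intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2), p_slope=float(res.pvalue))


def assign_gamma_group(gamma: np.ndarray,
                       groups: Sequence[float] = ANOVA_GROUPS,
                       tol: float = ANOVA_GROUP_TOL) -> np.ndarray:
    """Nearest-target group index within ``tol``; -1 for out-of-band."""
    gamma = np.asarray(gamma, dtype=float)
    groups = np.asarray(groups, dtype=float)
    d = np.abs(gamma[:, None] - groups[None, :])
    idx = d.argmin(axis=1)
    idx[d.min(axis=1) > tol + 1e-12] = -1
    return idx


def encoding_anova(gi: np.ndarray, gamma: np.ndarray,
                   groups: Sequence[float] = ANOVA_GROUPS,
                   tol: float = ANOVA_GROUP_TOL,
                   alpha: float = ENCODER_ALPHA,
                   ) -> tuple[float, float, bool]:
    """One-way fixed-effects ANOVA of GI over intermittency groups.

    Trials are binned to the nearest group target within ``tol``;
    out-of-band trials are excluded. Returns (F, p, is_encoder) with
    is_encoder = (p < alpha)."""
    gi = np.asarray(gi, dtype=float)
    idx = assign_gamma_group(gamma, groups, tol)
    samples = []
    for g in range(len(groups)):
        vals = gi[(idx == g) & np.isfinite(gi)]
        if vals.size:
            samples.append(vals)
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >=2 groups with >=2 trials each")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p), bool(p < alpha)


@dataclass
class XCorrResult:
    lags: np.ndarray            # seconds, symmetric about 0
    raw: np.ndarray             # Pearson r per lag
    shuffle_mean: np.ndarray
    corrected: np.ndarray
    peak_r: float
    peak_lag: float


def _pearson_lags(x: np.ndarray, y: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """r(lag) = Pearson(x[t], y[t + lag]) on the overlapping segment.

    Positive lag means y is delayed relative to x (y lags x)."""
    n = x.size
    out = np.empty(lags.size)
    for k, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[:n - lag], y[lag:]
        else:
            a, b = x[-lag:], y[:n + lag]
        if a.size < 3 or a.std() == 0 or b.std() == 0:
            out[k] = np.nan
        else:
            out[k] = np.corrcoef(a, b)[0, 1]
    return out


def downsample_to(reference: Trace, rate: float) -> Trace:
    """Box-average downsampling of a reference signal to the imaging clock."""
    factor = reference.rate / rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("reference rate must be an integer multiple")
    factor = int(round(factor))
    n = (reference.n // factor) * factor
    vals = reference.values[:n].reshape(-1, factor).mean(axis=1)
    return Trace(values=vals, rate=rate, t0=reference.t0)


def xcorr_shuffled(rate: Trace, reference: Trace,
                   n_shuffle: int = XCORR_N_SHUFFLE,
                   max_lag_s: float = XCORR_MAX_LAG_S,
                   rng: Optional[np.random.Generator] = None,
                   seed: int = 0) -> XCorrResult:
    """Shuffle-subtracted Pearson cross-correlogram.

    Both signals are mean-subtracted (Pearson normalization); the
    reference is box-averaged onto the response clock first. The shuffle
    control is the per-lag mean correlogram of ``n_shuffle`` whole-trace
    random sample permutations of the response, subtracted pointwise.
    The peak is the maximum of the corrected curve; a positive peak lag
    means the response lags the reference.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if reference.rate != rate.rate:
        reference = downsample_to(reference, rate.rate)
    n = min(rate.n, reference.n)
    x = reference.values[:n]
    y = rate.values[:n]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: cross-correlation undefined")
    max_lag = int(round(max_lag_s * rate.rate))
    lags = np.arange(-max_lag, max_lag + 1)
    raw = _pearson_lags(x, y, lags)
    shuf = np.zeros_like(raw)
    for _ in range(n_shuffle):
        shuf += _pearson_lags(x, rng.permutation(y), lags)
    shuf /= n_shuffle
    corrected = raw - shuf
    k = int(np.nanargmax(corrected))
    return XCorrResult(lags=lags / rate.rate, raw=raw, shuffle_mean=shuf,
                       corrected=corrected, peak_r=float(corrected[k]),
                       peak_lag=float(lags[k] / rate.rate))


def spatiotemporal_map(scalars: np.ndarray, ap: np.ndarray, ml: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Correlate a per-glomerulus scalar with bulb position, per trial.

    ``scalars`` is (n_trials, n_glomeruli); rows with fewer than 3 finite
    values, or zero variance in scalar or coordinate, yield NaN and are
    excluded from the session means. Returns (r_ap per trial, r_ml per
    trial, mean r_ap, mean r_ml).
    """
    scalars = np.atleast_2d(np.asarray(scalars, dtype=float))
    ap = np.asarray(ap, dtype=float)
    ml = np.asarray(ml, dtype=float)

    def _corr(vals: np.ndarray, coord: np.ndarray) -> float:
        ok = np.isfinite(vals)
        if np.count_nonzero(ok) < 3:
            return float("nan")
        v, c = vals[ok], coord[ok]
        if v.std() == 0 or c.std() == 0:
            return float("nan")
        return float(np.corrcoef(v, c)[0, 1])

    r_ap = np.array([_corr(row, ap) for row in scalars])
    r_ml = np.array([_corr(row, ml) for row in scalars])
    mean_ap = float(np.nanmean(r_ap)) if np.any(np.isfinite(r_ap)) else float("nan")
    mean_ml = float(np.nanmean(r_ml)) if np.any(np.isfinite(r_ml)) else float("nan")
    return r_ap, r_ml, mean_ap, mean_ml
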