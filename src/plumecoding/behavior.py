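"""Go/No-Go session analytics.

Trials are scored from lick times: the decision period is the 1.5 s
window starting 0.5 s after odor offset (the tone interval), and only
licks inside it determine the outcome — anticipatory licks are recorded
but do not decide the trial. Session metrics start with the first trial
following four hit trials (engagement trimming):

    HR = correct CS+ / total CS+        FA = incorrect CS- / total CS-
    performance = HR - FA

and the learning criterion is HR > 0.75 and FA < 0.25 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import ODOR_DURATION_S, ODOR_ONSET_S, TrialRecord
from .population import LinearDiscriminant, crossval_classify
from .sniff import SniffEvents, cumulative_perceived_intermittency

log = logging.getLogger(__name__)

TONE_DELAY_S = 0.5         # 6 kHz tone between odor offset and decision
DECISION_DURATION_S = 1.5
HR_CRITERION = 0.75        # meets criterion iff HR > 0.75 (strict)
FA_CRITERION = 0.25        # and FA < 0.25 (strict)
N_ENGAGEMENT_HITS = 4


@dataclass
class TrialOutcome:
    trial_id: int
    cs_label: str
    licked_in_decision: bool
    outcome: str               # hit | miss | false_alarm | correct_rejection
    first_lick_time: float     # s from odor onset; NaN if no lick
    n_anticipatory: int


@dataclass
class SessionMetrics:
    hr: float
    fa: float
    performance: float
    n_trials_used: int
    n_cs_plus: int
    n_cs_minus: int
    meets_criterion: bool


def score_trials(trials: Sequence[TrialRecord],
                 odor_onset: float = ODOR_ONSET_S,
                 odor_duration: float = ODOR_DURATION_S,
                 tone_delay: float = TONE_DELAY_S,
                 decision_duration: float = DECISION_DURATION_S,
                 ) -> list[TrialOutcome]:
    """Assign hit / miss / false-alarm / correct-rejection per trial."""
    t_dec0 = odor_onset + odor_duration + tone_delay
    t_dec1 = t_dec0 + decision_duration
    outcomes = []
    for tr in trials:
        if tr.lick_times is None:
            raise ValueError(f"trial {tr.trial_id} is missing the lick channel")
        licks = np.asarray(tr.lick_times, dtype=float)
        in_decision = bool(np.any((licks >= t_dec0) & (licks < t_dec1)))
        odor_licks = licks[licks >= odor_onset]
        first = float(odor_licks[0] - odor_onset) if odor_licks.size else float("nan")
        n_antic = int(np.count_nonzero((licks >= odor_onset) & (licks < t_dec0)))
        if tr.cs_label == "CSplus":
            outcome = "hit" if in_decision else "miss"
        elif tr.cs_label == "CSminus":
            outcome = "false_alarm" if in_decision else "correct_rejection"
        else:
            outcome = "excluded"
        outcomes.append(TrialOutcome(
            trial_id=tr.trial_id, cs_label=tr.cs_label,
            licked_in_decision=in_decision, outcome=outcome,
            first_lick_time=first, n_anticipatory=n_antic))
    return outcomes


def trim_engagement(outcomes: Sequence[TrialOutcome],
                    n_hits: int = N_ENGAGEMENT_HITS,
                    consecutive: bool = False) -> list[TrialOutcome]:
    """Drop all trials up to and including the ``n_hits``-th hit.

    By default hits accumulate (not necessarily consecutively); with
    ``consecutive=True`` the trim point is the end of the first run of
    ``n_hits`` hits in a row. If the session never reaches the mark, all
    trials are kept (with a log note).
    """
    count = 0
    cut = None
    for i, o in enumerate(outcomes):
        if o.outcome == "hit":
            count += 1
        elif consecutive:
            count = 0
        if count >= n_hits:
            cut = i + 1
            break
    if cut is None:
        log.info("engagement mark of %d hits never reached; keeping all trials",
                 n_hits)
        return list(outcomes)
    return list(outcomes[cut:])


def session_metrics(outcomes: Sequence[TrialOutcome],
                    engagement_rule: bool = True,
                    consecutive: bool = False) -> SessionMetrics:
    """HR, FA, performance and the criterion flag for one session.

    Excluded-band trials never enter the counts; hit rate and false-alarm
    rate are exact ratios of decision-window outcomes.
    """
    if engagement_rule:
        outcomes = trim_engagement(outcomes, consecutive=consecutive)
    plus = [o for o in outcomes if o.cs_label == "CSplus"]
    minus = [o for o in outcomes if o.cs_label == "CSminus"]
    if not plus or not minus:
        raise ValueError("no CS+ or no CS- trials remain after trimming")
    hr = sum(o.outcome == "hit" for o in plus) / len(plus)
    fa = sum(o.outcome == "false_alarm" for o in minus) / len(minus)
    return SessionMetrics(
        hr=hr, fa=fa, performance=hr - fa,
        n_trials_used=len(plus) + len(minus),
        n_cs_plus=len(plus), n_cs_minus=len(minus),
        meets_criterion=bool(hr > HR_CRITERION and fa < FA_CRITERION))


@dataclass
class FirstLickFit:
    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray
    slope: float
    intercept: float
    r2: float
    p: float
    n_lickfree: int


def first_lick_by_intermittency(first_lick_times: np.ndarray,
                                gammas: np.ndarray,
                                bin_edges: Optional[np.ndarray] = None,
                                ) -> FirstLickFit:
    """Binned mean first-lick times (s from odor onset) plus an OLS fit of
    first-lick time against intermittency. Lick-free trials (NaN times)
    are excluded and counted."""
    t = np.asarray(first_lick_times, dtype=float)
    g = np.asarray(gammas, dtype=float)
    ok = np.isfinite(t) & np.isfinite(g)
    n_lickfree = int(np.count_nonzero(~np.isfinite(t)))
    t, g = t[ok], g[ok]
    if t.size == 0:
        return FirstLickFit(np.empty(0), np.empty(0), np.empty(0, int),
                            float("nan"), float("nan"), float("nan"),
                            float("nan"), n_lickfree)
    if bin_edges is None:
        bin_edges = np.arange(0.0, 1.0001, 0.1)
    which = np.clip(np.digitize(g, bin_edges) - 1, 0, len(bin_edges) - 2)
    centers = (bin_edges[:-1] + bin_edges[1:]) / 2
    means = np.full(centers.size, np.nan)
    counts = np.zeros(centers.size, dtype=int)
    for b in range(centers.size):
        m = which == b
        counts[b] = np.count_nonzero(m)
        if counts[b]:
            means[b] = t[m].mean()
    if np.unique(g).size >= 2:
        res = stats.linregress(g, t)
        slope, intercept = float(res.slope), float(res.intercept)
        r2, p = float(res.rvalue ** 2), float(res.pvalue)
    else:
        slope = intercept = r2 = p = float("nan")
    return FirstLickFit(centers, means, counts, slope, intercept, r2, p,
                        n_lickfree)


@dataclass
class PerceivedDecoding:
    t_cutoffs: np.ndarray
    accuracy: np.ndarray          # mean accuracy per cutoff
    accuracy_se: np.ndarray
    control: np.ndarray           # shuffled-label mean accuracy per cutoff
    control_se: np.ndarray
    p_corrected: np.ndarray       # Bonferroni-corrected real-vs-control p
    significant: np.ndarray


def decode_from_perceived(trials: Sequence[TrialRecord],
                          t_cutoffs: Sequence[float],
                          cs_plus_bin: Optional[float] = None,
                          bin_tol: float = 0.05,
                          n_repeats: int = 20, seed: int = 0,
                          use_truth_events: bool = True,
                          ) -> PerceivedDecoding:
    """Decode CS+ vs CS- from cumulative perceived intermittency.

    For each cutoff t, a single-feature linear discriminant on the
    cumulative perceived intermittency up to t is cross-validated
    (3-fold x ``n_repeats``); CS+ trials can be restricted to one
    intermittency bin against all CS- trials. A shuffled-label control
    runs the identical pipeline, and real-vs-control comparisons are
    Bonferroni-corrected across cutoffs.
    """
    from .sniff import detect_sniffs
    t_cutoffs = np.asarray(list(t_cutoffs), dtype=float)
    feats, labels = [], []
    for tr in trials:
        if tr.cs_label == "excluded":
            continue
        if tr.cs_label == "CSplus" and cs_plus_bin is not None and \
                abs(tr.nominal_intermittency - cs_plus_bin) > bin_tol:
            continue
        if use_truth_events and tr.sniff_truth is not None:
            events = SniffEvents(*tr.sniff_truth)
        else:
            events = detect_sniffs(tr.sniff)
        curve = cumulative_perceived_intermittency(tr.stimulus, events, t_cutoffs)
        feats.append(curve)
        labels.append(tr.cs_label)
    X = np.asarray(feats)
    y = np.asarray(labels)
    n_cut = t_cutoffs.size
    acc = np.full(n_cut, np.nan)
    acc_se = np.full(n_cut, np.nan)
    ctl = np.full(n_cut, np.nan)
    ctl_se = np.full(n_cut, np.nan)
    pvals = np.full(n_cut, np.nan)
    rng = np.random.default_rng(seed)
    for k in range(n_cut):
        col = X[:, k]
        ok = np.isfinite(col)
        yk = y[ok]
        if min((np.count_nonzero(yk == c) for c in np.unique(yk)),
               default=0) < 3 or np.unique(yk).size < 2:
            log.info("cutoff %.2f s skipped: too few trials per class",
                     t_cutoffs[k])
            continue
        xk = col[ok, None]
        real = crossval_classify(xk, yk, n_repeats=n_repeats, seed=seed + k)
        y_shuf = rng.permutation(yk)
        shuf = crossval_classify(xk, y_shuf, n_repeats=n_repeats,
                                 seed=seed + 500 + k)
        acc[k], acc_se[k] = real.mean_accuracy, real.se_accuracy
        ctl[k], ctl_se[k] = shuf.mean_accuracy, shuf.se_accuracy
        _, p = stats.ttest_ind(real.accuracy.ravel()[np.isfinite(real.accuracy.ravel())],
                               shuf.accuracy.ravel()[np.isfinite(shuf.accuracy.ravel())])
        pvals[k] = min(float(p) * n_cut, 1.0)   # Bonferroni
    return PerceivedDecoding(t_cutoffs=t_cutoffs, accuracy=acc,
                             accuracy_se=acc_se, control=ctl, control_se=ctl_se,
                             p_corrected=pvals,
                             significant=(pvals < 0.05) & (acc > ctl))
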