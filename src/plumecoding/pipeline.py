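"""Session-level driver: raw trials -> tidy per-glomerulus tables.

Chains sniff detection, imaging preprocessing and the glomerular
statistics over every trial of a session, producing the tidy tables the
population and behavior analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import glomstats, preproc
from .core import TrialRecord
from .sniff import SniffEvents, detect_sniffs


@dataclass
class SessionTables:
    """Tidy outputs of :func:`process_session`."""

    gi: pd.DataFrame          # one row per roi x trial
    glomeruli: pd.DataFrame   # one row per roi (slope, ANOVA, responder flag)
    trial_gamma: np.ndarray   # nominal intermittency per processed trial
    trial_ids: np.ndarray

    def gi_matrix(self, roi_ids: Optional[Sequence[int]] = None,
                  responders_only: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """(n_trials, n_glomeruli) GI matrix plus the roi id per column."""
        glom = self.glomeruli
        if responders_only:
            glom = glom[glom.responder]
        ids = np.asarray(roi_ids if roi_ids is not None else glom.roi_id)
        wide = self.gi.pivot(index="trial_id", columns="roi_id", values="gi")
        wide = wide.reindex(index=self.trial_ids, columns=ids)
        return wide.to_numpy(), ids


def process_session(trials: Sequence[TrialRecord],
                    use_truth_events: bool = False,
                    tau_s: float = preproc.TAU_S) -> SessionTables:
    """Preprocess every glomerulus-trial and assemble encoding statistics.

    Sniff events come from :func:`detect_sniffs` on the pressure trace
    unless ``use_truth_events`` asks for the generator's ground truth.
    """
    rows = []
    for tr in trials:
        if use_truth_events and tr.sniff_truth is not None:
            events = SniffEvents(*tr.sniff_truth)
        else:
            events = detect_sniffs(tr.sniff)
        onset = tr.stimulus.odor_onset
        dur = tr.stimulus.odor_duration
        for roi_id, raw in tr.fluorescence.items():
            resp = preproc.preprocess_trace(raw, onset, dur, tau_s,
                                            events=events)
            gi = np.nan
            if resp.z is not None:
                gi = glomstats.compute_GI(resp.z, (onset, onset + dur))
            rows.append({
                "roi_id": roi_id, "trial_id": tr.trial_id,
                "gamma": tr.nominal_intermittency, "gain": tr.gain,
                "cs_label": tr.cs_label, "gi": gi,
                "amplitude": resp.amplitude, "t75": resp.t75,
                "responded": resp.responded, "valid": resp.valid,
            })
    gi_df = pd.DataFrame(rows)
    glom_rows = []
    for roi_id, sub in gi_df.groupby("roi_id"):
        ok = sub[sub.valid & np.isfinite(sub.gi)]
        rec = {"roi_id": roi_id,
               "responder": preproc.detect_responders(sub.responded.to_numpy(),
                                                      sub.valid.to_numpy()),
               "slope": np.nan, "intercept": np.nan, "r2": np.nan,
               "f_anova": np.nan, "p_anova": np.nan, "is_encoder": False,
               "mean_amplitude": float(np.nanmean(sub.amplitude))
               if np.any(np.isfinite(sub.amplitude)) else np.nan,
               "mean_t75": float(np.nanmean(sub.t75))
               if np.any(np.isfinite(sub.t75)) else np.nan}
        if len(ok) >= 3 and ok.gamma.nunique() >= 2:
            fit = glomstats.fit_GI_slope(ok.gi.to_numpy(), ok.gamma.to_numpy(),
                                         roi_id=roi_id)
            rec.update(slope=fit.slope, intercept=fit.intercept, r2=fit.r2)
            try:
                f, p, enc = glomstats.encoding_anova(ok.gi.to_numpy(),
                                                     ok.gamma.to_numpy())
                rec.update(f_anova=f, p_anova=p, is_encoder=enc)
            except ValueError:
                pass
        glom_rows.append(rec)
    trial_ids = np.asarray([tr.trial_id for tr in trials])
    gamma = np.asarray([tr.nominal_intermittency for tr in trials])
    return SessionTables(gi=gi_df, glomeruli=pd.DataFrame(glom_rows),
                         trial_gamma=gamma, trial_ids=trial_ids)
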