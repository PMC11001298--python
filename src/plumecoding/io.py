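"""Session persistence: HDF5 for traces, CSV for trial tables, YAML config.

One session file holds groups /stimulus, /sniff, /fluorescence, /behavior
and /ground_truth; the companion trial table is a plain CSV with one row
per trial (trial_id, kind, intermittency, gain, cs_label).
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import StimulusTrace, Trace, TrialRecord
from .synthetic import (GeneratorConfig, GroundTruth, GroundTruthGlomerulus,
                        LickPolicy)


def trial_table(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = [{
        "trial_id": tr.trial_id, "kind": tr.stimulus.kind,
        "intermittency": tr.nominal_intermittency, "gain": tr.gain,
        "cs_label": tr.cs_label, "n_licks": len(tr.lick_times),
    } for tr in trials]
    return pd.DataFrame(rows)


def save_session(path: str, trials: Sequence[TrialRecord],
                 truth: Optional[GroundTruth] = None) -> None:
    with h5py.File(path, "w") as f:
        for tr in trials:
            g = f.create_group(f"trials/{tr.trial_id:04d}")
            s = g.create_group("stimulus")
            s.create_dataset("values", data=tr.stimulus.values)
            for key in ("rate", "c0", "gain", "nominal_intermittency",
                        "odor_onset", "odor_duration"):
                s.attrs[key] = getattr(tr.stimulus, key)
            s.attrs["kind"] = tr.stimulus.kind
            sn = g.create_group("sniff")
            sn.create_dataset("values", data=tr.sniff.values)
            sn.attrs["rate"] = tr.sniff.rate
            if tr.sniff_truth is not None:
                sn.create_dataset("true_onsets", data=tr.sniff_truth[0])
                sn.create_dataset("true_peaks", data=tr.sniff_truth[1])
            g.create_dataset("behavior/lick_times", data=np.asarray(tr.lick_times))
            g.attrs["cs_label"] = tr.cs_label
            fl = g.create_group("fluorescence")
            for roi_id, trace in tr.fluorescence.items():
                d = fl.create_dataset(str(roi_id), data=trace.values)
                d.attrs["rate"] = trace.rate
        if truth is not None:
            gt = f.create_group("ground_truth")
            for name in ("roi_id", "cluster", "planted_slope", "gain",
                         "latency_s", "ap", "ml"):
                gt.create_dataset(name, data=np.asarray(
                    [getattr(g_, name) for g_ in truth.glomeruli]))
            gt.create_dataset("trial_intermittency",
                              data=np.asarray(truth.trial_intermittency))
            gt.create_dataset("trial_perceived",
                              data=np.asarray(truth.trial_perceived))
            gt.attrs["config"] = yaml.safe_dump(dataclasses.asdict(truth.config))
            gt.attrs["lick_policy"] = yaml.safe_dump(
                dataclasses.asdict(truth.lick_policy))


def load_session(path: str) -> tuple[list[TrialRecord], Optional[GroundTruth]]:
    trials = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["trials"]):
            g = f[f"trials/{key}"]
            s = g["stimulus"]
            stimt = StimulusTrace(
                values=s["values"][:], rate=float(s.attrs["rate"]),
                c0=float(s.attrs["c0"]), kind=str(s.attrs["kind"]),
                gain=float(s.attrs["gain"]),
                nominal_intermittency=float(s.attrs["nominal_intermittency"]),
                odor_onset=float(s.attrs["odor_onset"]),
                odor_duration=float(s.attrs["odor_duration"]))
            sn = g["sniff"]
            sniff = Trace(values=sn["values"][:], rate=float(sn.attrs["rate"]))
            truth_ev = None
            if "true_onsets" in sn:
                truth_ev = (sn["true_onsets"][:], sn["true_peaks"][:])
            fluo = {int(k): Trace(values=d[:], rate=float(d.attrs["rate"]))
                    for k, d in g["fluorescence"].items()}
            trials.append(TrialRecord(
                trial_id=int(key), stimulus=stimt, sniff=sniff,
                lick_times=g["behavior/lick_times"][:],
                cs_label=str(g.attrs["cs_label"]), fluorescence=fluo,
                sniff_truth=truth_ev))
        truth = None
        if "ground_truth" in f:
            gt = f["ground_truth"]
            config = GeneratorConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in yaml.safe_load(gt.attrs["config"]).items()})
            policy = LickPolicy(**yaml.safe_load(gt.attrs["lick_policy"]))
            gloms = [GroundTruthGlomerulus(
                roi_id=int(gt["roi_id"][i]), cluster=int(gt["cluster"][i]),
                planted_slope=float(gt["planted_slope"][i]),
                gain=float(gt["gain"][i]), latency_s=float(gt["latency_s"][i]),
                ap=float(gt["ap"][i]), ml=float(gt["ml"][i]))
                for i in range(gt["roi_id"].shape[0])]
            truth = GroundTruth(glomeruli=gloms, lick_policy=policy,
                                config=config,
                                trial_intermittency=list(gt["trial_intermittency"][:]),
                                trial_perceived=list(gt["trial_perceived"][:]))
    return trials, truth


def load_config(path: str) -> GeneratorConfig:
    """Read a GeneratorConfig from a YAML key/value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "bleach_coeffs" in raw:
        raw["bleach_coeffs"] = tuple(raw["bleach_coeffs"])
    return GeneratorConfig(**raw)


def session_digest(trials: Sequence[TrialRecord]) -> str:
    """SHA-256 over every numeric array of the session, for byte-level
    determinism checks."""
    h = hashlib.sha256()
    for tr in trials:
        h.update(str(tr.trial_id).encode())
        h.update(tr.cs_label.encode())
        h.update(np.ascontiguousarray(tr.stimulus.values).tobytes())
        h.update(np.ascontiguousarray(tr.sniff.values).tobytes())
        h.update(np.ascontiguousarray(np.asarray(tr.lick_times)).tobytes())
        for roi_id in sorted(tr.fluorescence):
            h.update(np.ascontiguousarray(tr.fluorescence[roi_id].values).tobytes())
    return h.hexdigest()
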