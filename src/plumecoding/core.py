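"""Core containers shared across the pipeline.

Every signal in the package — odor concentration, sniff pressure, raw and
processed fluorescence — is carried as a :class:`Trace`: a uniformly
sampled scalar time series with a sampling rate and a start time.
Stimulus traces additionally carry the source concentration ``C0``, the
stimulus kind, the delivery gain and the nominal intermittency so that
threshold-based statistics can always refer to the gain-1 maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Default trial timeline (seconds): 2 s pre-odor, 6 s odor, 1 s post-odor.
ODOR_ONSET_S = 2.0
ODOR_DURATION_S = 6.0
POST_S = 1.0
TRIAL_DURATION_S = ODOR_ONSET_S + ODOR_DURATION_S + POST_S


@dataclass
class Trace:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values : ndarray
        Sample values.
    rate : float
        Sampling rate in Hz (> 0).
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be one-dimensional")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def window_indices(self, t_start: float, t_stop: float) -> slice:
        """Half-open sample slice covering ``t_start <= t < t_stop``."""
        if not t_stop > t_start:
            raise ValueError("empty window: t_stop must exceed t_start")
        i0 = int(np.ceil((t_start - self.t0) * self.rate - 1e-9))
        i1 = int(np.ceil((t_stop - self.t0) * self.rate - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.n)
        return slice(i0, i1)

    def window(self, t_start: float, t_stop: float) -> np.ndarray:
        return self.values[self.window_indices(t_start, t_stop)]

    def with_values(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class StimulusTrace(Trace):
    """Odor concentration trace with stimulus metadata.

    ``c0`` is the gain-1 source (maximum) concentration; threshold-based
    statistics (intermittency, whiff counting, binarization) always use
    ``0.1 * c0`` regardless of the delivered gain.
    """

    c0: float = 1.0
    kind: str = "naturalistic"  # naturalistic | binary | square
    gain: float = 1.0
    nominal_intermittency: float = float("nan")
    odor_onset: float = ODOR_ONSET_S
    odor_duration: float = ODOR_DURATION_S

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.c0 > 0:
            raise ValueError("c0 must be positive")
        if not 0 < self.gain <= 1:
            raise ValueError("gain must lie in (0, 1]")

    @property
    def odor_offset(self) -> float:
        return self.odor_onset + self.odor_duration

    def odor_window_indices(self) -> slice:
        return self.window_indices(self.odor_onset, self.odor_offset)


@dataclass
class GlomerulusInfo:
    """Imaging ROI identity and position on the dorsal bulb.

    Coordinates live in the 256x256 camera frame: ``ap`` runs
    anterior-to-posterior in pixels, ``ml`` is the pixel distance from
    the midline (non-negative).
    """

    roi_id: int
    ap: float
    ml: float

    def __post_init__(self) -> None:
        if not (0 <= self.ap <= 256):
            raise ValueError("AP coordinate outside the 256-pixel frame")
        if not (0 <= self.ml <= 256):
            raise ValueError("ML distance outside the 256-pixel frame")


@dataclass
class TrialRecord:
    """One 9 s trial: stimulus, sniffing, licks and per-glomerulus raw F."""

    trial_id: int
    stimulus: StimulusTrace
    sniff: Trace
    lick_times: np.ndarray
    cs_label: str  # CSplus | CSminus | excluded
    fluorescence: dict[int, Trace] = field(default_factory=dict)
    sniff_truth: Optional[tuple[np.ndarray, np.ndarray]] = None  # (onsets, peaks)
    meta: dict = field(default_factory=dict)

    @property
    def gain(self) -> float:
        return self.stimulus.gain

    @property
    def nominal_intermittency(self) -> float:
        return self.stimulus.nominal_intermittency
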