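"""Synthetic session generator with planted ground truth.

Every downstream stage of the pipeline is exercised against sessions built
here: fluctuating odor-concentration traces with controllable
intermittency, quasi-periodic sniff pressure waveforms, glomerular
fluorescence from two planted response phenotypes with opposite
GI-vs-intermittency slopes, and lick behavior driven by the perceived
intermittency of each trial.

Plume-like stimuli are a two-state renewal (telegraph) process: whiff and
blank durations are exponential with means chosen so the duty-weighted
whiff fraction hits the target intermittency; the realized value is
measured on the finished trace and the duration ratio rescaled until it is
within +/-0.02 of the target.

The planted encoding phenotypes control the *duration* of supra-threshold
activity, because glomerular intermittency (GI) is a time-above-threshold
fraction and amplitude scaling cannot plant a slope. A cluster-2 unit with
planted slope s responds for the first s-fraction of every whiff it
samples during an inhalation, so its expected GI is s * gamma; a
cluster-1 unit responds during blanks, giving GI = |s| * (1 - gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import stimulus as stim
from .core import (ODOR_DURATION_S, ODOR_ONSET_S, POST_S, StimulusTrace,
                   Trace, TrialRecord)

# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic sessions.

    Defaults mirror the recording setup being emulated: 9 s trials
    (2 s pre-odor + 6 s odor + 1 s post), stimulus channels at 1 kHz,
    imaging at 25 frames/s, a 150 ms GCaMP decay constant, and sniffing
    in the 2-8 Hz range.
    """

    pre_s: float = ODOR_ONSET_S
    odor_s: float = ODOR_DURATION_S
    post_s: float = POST_S
    stim_rate: float = 1000.0
    imaging_rate: float = 25.0
    sniff_freq: float = 4.0
    sniff_jitter: float = 0.10       # SD of cycle period, fraction of period
    tau_s: float = 0.150             # GCaMP kernel decay constant
    c0: float = 1.0                  # gain-1 source concentration, a.u.
    f0: float = 1000.0               # baseline fluorescence, a.u.
    response_dff: float = 0.15       # peak dF/F of a driven unit at gain 1
    noise_sd: float = 0.003          # white fluorescence noise, dF/F units
    bleach_coeffs: tuple = (0.0, -0.006, 0.0003)  # dF/F = c0 + c1*t + c2*t^2
    plume_cycle_s: float = 1.0       # mean whiff+blank renewal cycle
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pre_s", "odor_s", "post_s", "stim_rate",
                     "imaging_rate", "tau_s", "c0", "f0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 1 <= self.sniff_freq <= 12:
            raise ValueError("sniff_freq must lie in [1, 12] Hz")
        if self.stim_rate % self.imaging_rate:
            raise ValueError("stim_rate must be an integer multiple of imaging_rate")

    @property
    def duration_s(self) -> float:
        return self.pre_s + self.odor_s + self.post_s

    @property
    def odor_onset(self) -> float:
        return self.pre_s

    @property
    def odor_offset(self) -> float:
        return self.pre_s + self.odor_s


def subrng(seed: int, *keys: int) -> np.random.Generator:
    """Derive an independent RNG stream from ``seed`` and integer keys.

    Uses a SeedSequence over (seed, *keys), so adding a trial or a
    glomerulus never perturbs the draws of the others.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


@dataclass
class GroundTruthGlomerulus:
    """Planted phenotype of one synthetic glomerulus."""

    roi_id: int
    cluster: int                 # 1 (blank-activated) | 2 (whiff-activated)
    planted_slope: float         # expected d(GI)/d(gamma); sign follows cluster
    gain: float                  # peak dF/F of the driven response
    latency_s: float             # activation delay after epoch start
    ap: float                    # anterior->posterior pixel coordinate
    ml: float                    # pixel distance from midline

    def __post_init__(self) -> None:
        if self.cluster not in (1, 2):
            raise ValueError("cluster label must be 1 or 2")
        if not np.isfinite(self.planted_slope):
            raise ValueError("planted slope must be finite")


@dataclass
class LickPolicy:
    """Logistic lick policy on estimated perceived intermittency.

    The lick probability is sigmoid(slope * (perceived_gamma - threshold));
    the threshold sits in the gap between the CS- band (<= 0.15) and the
    CS+ band (>= 0.2). First-lick latency (from odor onset) decreases
    linearly with perceived intermittency, mimicking anticipatory licking.
    """

    threshold: float = 0.175
    slope: float = 50.0
    latency_intercept_s: float = 5.4
    latency_slope_s: float = -2.2
    latency_sd_s: float = 0.3

    def lick_probability(self, perceived_gamma: float) -> float:
        if not np.isfinite(perceived_gamma):
            return 0.0
        x = self.slope * (perceived_gamma - self.threshold)
        return float(1.0 / (1.0 + np.exp(-np.clip(x, -60, 60))))


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    glomeruli: list[GroundTruthGlomerulus]
    lick_policy: LickPolicy
    config: GeneratorConfig
    trial_intermittency: list[float] = field(default_factory=list)
    trial_perceived: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stimuli


def _full_trace(odor_values: np.ndarray, config: GeneratorConfig,
                kind: str, nominal: float, c0: float) -> StimulusTrace:
    n_pre = int(round(config.pre_s * config.stim_rate))
    n_post = int(round(config.post_s * config.stim_rate))
    values = np.concatenate((np.zeros(n_pre), odor_values, np.zeros(n_post)))
    return StimulusTrace(values=values, rate=config.stim_rate, t0=0.0,
                         c0=c0, kind=kind, gain=1.0,
                         nominal_intermittency=nominal,
                         odor_onset=config.pre_s,
                         odor_duration=config.odor_s)


def _telegraph(target: float, duration: float, rate: float, cycle_s: float,
               rng: np.random.Generator) -> np.ndarray:
    """Alternating exponential whiff/blank renewal, returned as 0/1."""
    mu_w = cycle_s * target
    mu_b = cycle_s * (1.0 - target)
    n = int(round(duration * rate))
    out = np.zeros(n)
    # start in a state drawn with the stationary occupancy
    on = rng.random() < target
    t = 0.0
    while t < duration:
        dur = rng.exponential(mu_w if on else mu_b)
        if on:
            i0 = int(np.ceil(t * rate - 1e-9))
            i1 = min(int(np.ceil((t + dur) * rate - 1e-9)), n)
            out[i0:i1] = 1.0
        t += dur
        on = not on
    return out


def gen_plume_trace(target_intermittency: float, config: GeneratorConfig,
                    kind: str = "naturalistic",
                    rng: Optional[np.random.Generator] = None,
                    tol: float = 0.02, max_iter: int = 50) -> StimulusTrace:
    """Fluctuating 6 s concentration trace with realized intermittency
    within ``tol`` of the target.

    ``kind='binary'`` yields a two-level telegraph at {0, C0};
    ``kind='naturalistic'`` adds per-whiff amplitude variation and
    low-pass smoothing before renormalizing the peak to C0. The whiff /
    blank mean durations are rescaled (up to ``max_iter`` times) until the
    realized intermittency — recomputed on the finished trace with the
    0.1*C0 threshold — lands inside the tolerance band.
    """
    if not 0 < target_intermittency < 1:
        raise ValueError("target intermittency must lie strictly in (0, 1)")
    if kind not in ("naturalistic", "binary"):
        raise ValueError(f"unknown plume kind {kind!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    aim = target_intermittency
    last = np.nan
    for _ in range(max_iter):
        aim = min(max(aim, 1e-4), 1 - 1e-4)
        gate = _telegraph(aim, config.odor_s, config.stim_rate,
                          config.plume_cycle_s, rng)
        odor = gate * config.c0
        if kind == "naturalistic":
            odor = _naturalize(gate, config, rng)
        trace = _full_trace(odor, config, kind, target_intermittency, config.c0)
        last = stim.compute_intermittency(trace)
        if abs(last - target_intermittency) <= tol:
            return trace
        # move the requested duty fraction by the observed error
        aim = aim + (target_intermittency - last)
    raise RuntimeError(
        f"plume generation failed to reach intermittency "
        f"{target_intermittency:.3f} in {max_iter} iterations "
        f"(last realized {last:.3f})")


def _naturalize(gate: np.ndarray, config: GeneratorConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Per-whiff amplitude variation + causal low-pass for plume texture."""
    padded = np.concatenate(([0], gate.astype(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    odor = np.zeros_like(gate)
    for a, b in zip(starts, stops):
        amp = 0.55 + 0.45 * rng.random()
        odor[a:b] = amp * config.c0
    # first-order smoothing, ~20 ms time constant
    alpha = float(np.exp(-1.0 / (0.020 * config.stim_rate)))
    sm = np.empty_like(odor)
    acc = 0.0
    coef = 1.0 - alpha
    for i, v in enumerate(odor):
        acc = alpha * acc + coef * v
        sm[i] = acc
    peak = sm.max()
    if peak > 0:
        sm = stim.normalize_trace(sm, config.c0)
    return sm


def gen_square_wave(n_pulses: int, duty: float,
                    config: GeneratorConfig) -> StimulusTrace:
    """``n_pulses`` equal pulses evenly spanning the 6 s odor window with
    on-fraction duty/100 and amplitude C0; intermittency equals duty/100
    up to sample quantization."""
    if not (1 <= int(n_pulses) <= 8) or n_pulses != int(n_pulses):
        raise ValueError("pulse count must be an integer in 1..8")
    if not 0 < duty < 100:
        raise ValueError("duty cycle must lie in (0, 100)")
    n = int(round(config.odor_s * config.stim_rate))
    # integer phase arithmetic: position in period = (i * n_pulses mod n) / n,
    # so the on-fraction is exactly duty/100 whenever n * duty / 100 is whole
    phase = (np.arange(n) * int(n_pulses)) % n
    odor = np.where(phase < n * duty / 100.0, config.c0, 0.0)
    return _full_trace(odor, config, "square", duty / 100.0, config.c0)


# ---------------------------------------------------------------------------
# sniffing


def gen_sniff_trace(sniff_freq: float, config: GeneratorConfig,
                    rng: Optional[np.random.Generator] = None,
                    jitter: Optional[float] = None,
                    noise_sd: float = 0.0):
    """Quasi-periodic biphasic pressure waveform over the whole trial.

    Each cycle is a positive half-sine inhalation lobe (30% of the cycle)
    followed by a negative exhalation lobe (35%), then an inter-breath
    pause. Returns ``(trace, true_onsets, true_peaks)``; onsets are the
    zero-crossings at the start of each inhalation lobe.
    """
    if not 1 <= sniff_freq <= 12:
        raise ValueError("sniff frequency must lie in [1, 12] Hz")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if jitter is None:
        jitter = config.sniff_jitter
    rate = config.stim_rate
    n = int(round(config.duration_s * rate))
    values = np.zeros(n)
    onsets, peaks = [], []
    t = 0.0
    base = 1.0 / sniff_freq
    while t < config.duration_s:
        period = base * float(np.clip(1.0 + jitter * rng.standard_normal(), 0.5, 1.5))
        inh = 0.30 * period
        exh = 0.35 * period
        i0 = int(np.ceil(t * rate - 1e-9))
        i1 = min(int(np.ceil((t + inh) * rate - 1e-9)), n)
        if i1 > i0:
            tt = np.arange(i0, i1) / rate - t
            values[i0:i1] = np.sin(np.pi * tt / inh)
        j0 = i1
        j1 = min(int(np.ceil((t + inh + exh) * rate - 1e-9)), n)
        if j1 > j0:
            tt = np.arange(j0, j1) / rate - (t + inh)
            values[j0:j1] = -0.6 * np.sin(np.pi * tt / exh)
        if t + inh / 2 < config.duration_s:
            onsets.append(t)
            peaks.append(t + inh / 2)
        t += period
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(n)
    return (Trace(values=values, rate=rate), np.asarray(onsets), np.asarray(peaks))


# ---------------------------------------------------------------------------
# glomeruli


#: Cluster-mean GI slopes used as generator presets (positive = GI rises
#: with intermittency; negative = blank-activated, GI falls).
CLUSTER1_SLOPE = -0.59
CLUSTER2_SLOPE = 0.89
#: Cluster sizes of the reference 228-glomerulus session preset.
PRESET_N_CLUSTER1 = 37
PRESET_N_CLUSTER2 = 191


def gen_glomerulus_population(n: int, frac_cluster1: float,
                              config: GeneratorConfig,
                              rng: Optional[np.random.Generator] = None,
                              slope_jitter: float = 0.04,
                              ) -> list[GroundTruthGlomerulus]:
    """Plant ``n`` glomeruli, a ``frac_cluster1`` share of them
    blank-activated (negative GI slope), the rest whiff-activated.

    Response gain and latency follow a posterior-lateral gradient so the
    spatiotemporal-map statistics have planted signal.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    if not 0 <= frac_cluster1 <= 1:
        raise ValueError("frac_cluster1 must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n1 = int(round(frac_cluster1 * n))
    gloms: list[GroundTruthGlomerulus] = []
    for i in range(n):
        cluster = 1 if i < n1 else 2
        base = CLUSTER1_SLOPE if cluster == 1 else CLUSTER2_SLOPE
        slope = base + slope_jitter * rng.standard_normal()
        slope = float(np.clip(slope, -0.98, 0.98))
        if cluster == 1 and slope >= -0.05:
            slope = -0.05
        if cluster == 2 and slope <= 0.05:
            slope = 0.05
        ap = float(rng.uniform(20, 236))
        ml = float(rng.uniform(5, 120))
        grad = 0.5 * (ap / 256.0 + ml / 128.0)       # 0 medial-anterior -> 1
        gain = config.response_dff * (0.6 + 0.6 * grad) \
            * float(np.clip(1 + 0.05 * rng.standard_normal(), 0.8, 1.2))
        latency = 0.04 + 0.10 * grad \
            + float(np.clip(0.005 * rng.standard_normal(), -0.015, 0.015))
        gloms.append(GroundTruthGlomerulus(
            roi_id=i, cluster=cluster, planted_slope=slope, gain=gain,
            latency_s=max(latency, 0.0), ap=ap, ml=ml))
    return gloms


def _active_intervals(glom: GroundTruthGlomerulus, stimulus: StimulusTrace,
                      inh_intervals: np.ndarray) -> list[tuple[float, float]]:
    """Activation epochs of the planted phenotype, in seconds.

    The unit samples an epoch (whiff for cluster 2, blank for cluster 1)
    if any inhalation interval overlaps it; it then responds for the
    first |slope|-fraction of that epoch's duration, delayed by its
    latency.
    """
    if glom.cluster == 2:
        epochs = stim.whiff_intervals(stimulus)
    else:
        epochs = stim.blank_intervals(stimulus)
    frac = abs(glom.planted_slope)
    active = []
    for a, b in epochs:
        if inh_intervals.size:
            overlap = np.minimum(inh_intervals[:, 1], b) \
                - np.maximum(inh_intervals[:, 0], a)
            if not np.any(overlap > 0):
                continue
        start = a + glom.latency_s
        active.append((start, start + frac * (b - a)))
    return active


def exp_kernel_convolve(rate_values: np.ndarray, tau_s: float,
                        sample_rate: float) -> np.ndarray:
    """Causal discrete exponential (AR(1)) kernel:
    c_t = a * c_{t-1} + (1 - a) * r_t with a = exp(-dt/tau).

    The filter starts at steady state (c_{-1} = r_0), so a constant rate
    maps to the same constant and the kernel inverts exactly."""
    from scipy.signal import lfilter
    a = float(np.exp(-1.0 / (tau_s * sample_rate)))
    x = np.asarray(rate_values, dtype=float)
    y, _ = lfilter([1.0 - a], [1.0, -a], x, zi=np.array([a * x[0]]))
    return y


def gen_rate(glom: GroundTruthGlomerulus, stimulus: StimulusTrace,
             inh_intervals: np.ndarray, config: GeneratorConfig,
             edge_smooth_s: float = 0.06) -> Trace:
    """Planted normalized firing-rate proxy at the imaging rate (0..1).

    Activation edges are smoothed with a ~``edge_smooth_s`` Gaussian so
    the planted rate is band-limited to the preprocessing passband
    (instantaneous steps would be unrecoverable through the 10 Hz
    low-pass); the epoch on-durations are preserved because the smoothing
    is symmetric.
    """
    n_hi = int(round(config.duration_s * config.stim_rate))
    gate = np.zeros(n_hi)
    for a, b in _active_intervals(glom, stimulus, inh_intervals):
        i0 = int(np.ceil(a * config.stim_rate - 1e-9))
        i1 = min(int(np.ceil(b * config.stim_rate - 1e-9)), n_hi)
        gate[max(i0, 0):i1] = 1.0
    if edge_smooth_s > 0:
        from scipy.ndimage import gaussian_filter1d
        gate = gaussian_filter1d(gate, edge_smooth_s * config.stim_rate / 2.0)
    factor = int(round(config.stim_rate / config.imaging_rate))
    rate = gate.reshape(-1, factor).mean(axis=1)
    return Trace(values=rate, rate=config.imaging_rate)


def gen_fluorescence(glom: GroundTruthGlomerulus, stimulus: StimulusTrace,
                     inh_intervals: np.ndarray, config: GeneratorConfig,
                     rng: Optional[np.random.Generator] = None,
                     noise_sd: Optional[float] = None) -> Trace:
    """Forward model: planted rate -> GCaMP kernel -> bleach + noise.

    The clean response deconvolves back to the planted rate exactly
    (shared AR(1) kernel); quadratic bleaching drift and white noise are
    added on the dF/F scale, and the output is raw fluorescence
    F = F0 * (1 + dff)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if noise_sd is None:
        noise_sd = config.noise_sd
    rate = gen_rate(glom, stimulus, inh_intervals, config)
    dff = glom.gain * stimulus.gain \
        * exp_kernel_convolve(rate.values, config.tau_s, config.imaging_rate)
    t = rate.times()
    c = config.bleach_coeffs
    bleach = c[0] + c[1] * t + c[2] * t ** 2
    dff = dff + bleach + noise_sd * rng.standard_normal(dff.size)
    return Trace(values=config.f0 * (1.0 + dff), rate=config.imaging_rate)


# ---------------------------------------------------------------------------
# sessions


DEFAULT_CS_PLUS_MENU = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
DEFAULT_CS_MINUS_MENU = (0.05, 0.10, 0.15)


def gen_session(config: GeneratorConfig,
                glomeruli: Optional[Sequence[GroundTruthGlomerulus]] = None,
                n_trials: int = 64,
                n_engagement: int = 8,
                cs_plus_menu: Sequence[float] = DEFAULT_CS_PLUS_MENU,
                cs_minus_menu: Optional[Sequence[float]] = DEFAULT_CS_MINUS_MENU,
                gains: Sequence[float] = (1.0, 0.5),
                lick_policy: Optional[LickPolicy] = None,
                kind: str = "binary",
                ) -> tuple[list[TrialRecord], GroundTruth]:
    """Generate a Go/No-Go session with planted ground truth.

    The default layout follows the task: 8 engagement trials of
    intermittency > 0.6 at gain 1, then a random interleaving of 28 CS+
    and 28 CS- trials with gains {1, 0.5} balanced. Licks are drawn from
    the logistic policy on the trial's true perceived intermittency
    (computed from the generator's own sniff ground truth).

    ``cs_minus_menu=None`` builds an encoding-style session whose main
    block draws every trial from ``cs_plus_menu`` (the passive /
    anesthetized protocol, where no CS- band is delivered).
    """
    if not cs_plus_menu or (cs_minus_menu is not None and not cs_minus_menu):
        raise ValueError("intermittency menus must be non-empty")
    if any(not 0 < g < 1
           for g in list(cs_plus_menu) + list(cs_minus_menu or [])):
        raise ValueError("menu intermittency values must lie in (0, 1)")
    if lick_policy is None:
        lick_policy = LickPolicy()
    if glomeruli is None:
        glomeruli = []
    rng = np.random.default_rng(config.seed)

    n_main = n_trials - n_engagement
    if n_main < 0:
        raise ValueError("n_trials smaller than the engagement prefix")
    if cs_minus_menu is None:
        n_plus, n_minus = n_main, 0
    else:
        n_plus = n_main // 2
        n_minus = n_main - n_plus

    def build_block(menu, count):
        block = []
        k = 0
        while len(block) < count:
            for g in menu:
                for gain in gains:
                    block.append((float(g), float(gain)))
            k += 1
            if k > count:
                break
        return block[:count]

    engage_menu = [g for g in cs_plus_menu if g > 0.6] or [max(cs_plus_menu)]
    plan = [(engage_menu[i % len(engage_menu)], 1.0)
            for i in range(n_engagement)]
    main = build_block(cs_plus_menu, n_plus)
    if n_minus:
        main += build_block(cs_minus_menu, n_minus)
    order = rng.permutation(len(main))
    plan += [main[i] for i in order]

    trials: list[TrialRecord] = []
    truth = GroundTruth(glomeruli=list(glomeruli), lick_policy=lick_policy,
                        config=config)
    from . import sniff as sniffmod
    for trial_id, (gamma, gain) in enumerate(plan):
        trng = subrng(config.seed, 1, trial_id)
        if kind == "square":
            duty = float(np.clip(round(gamma * 100), 1, 99))
            stimulus = gen_square_wave(5, duty, config)
        else:
            stimulus = gen_plume_trace(gamma, config, kind=kind, rng=trng)
        if gain != 1.0:
            stimulus = stim.apply_gain(stimulus, gain)
        sniff_trace, onsets, peaks = gen_sniff_trace(
            config.sniff_freq, config, rng=trng, noise_sd=0.01)
        inh = np.column_stack((onsets, peaks)) if onsets.size else np.empty((0, 2))
        fluorescence = {}
        for glom in glomeruli:
            grng = subrng(config.seed, 2, trial_id, glom.roi_id)
            fluorescence[glom.roi_id] = gen_fluorescence(
                glom, stimulus, inh, config, rng=grng)
        events = sniffmod.SniffEvents(onsets=onsets, peaks=peaks)
        perceived = sniffmod.perceived_intermittency(stimulus, events)
        lick_times = _draw_licks(perceived, lick_policy, config, trng)
        trials.append(TrialRecord(
            trial_id=trial_id, stimulus=stimulus, sniff=sniff_trace,
            lick_times=lick_times,
            cs_label=stim.label_cs(stimulus.nominal_intermittency),
            fluorescence=fluorescence, sniff_truth=(onsets, peaks),
            meta={"engagement": trial_id < n_engagement}))
        truth.trial_intermittency.append(stimulus.nominal_intermittency)
        truth.trial_perceived.append(perceived)
    return trials, truth


def _draw_licks(perceived: float, policy: LickPolicy,
                config: GeneratorConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Anticipatory + decision-window licks under the logistic policy."""
    p = policy.lick_probability(perceived)
    if rng.random() >= p:
        return np.asarray([])
    g = perceived if np.isfinite(perceived) else 0.0
    latency = policy.latency_intercept_s + policy.latency_slope_s * g \
        + policy.latency_sd_s * rng.standard_normal()
    latency = float(np.clip(latency, 0.3, config.odor_s - 0.1))
    first = config.odor_onset + latency
    decision_start = config.odor_offset + 0.5
    decision = decision_start + 0.1 + rng.exponential(0.15)
    decision = min(decision, decision_start + 1.4)
    licks = [first]
    t = first
    while t < decision_start - 0.3:
        t += rng.exponential(0.4)
        if t < decision_start - 0.3:
            licks.append(t)
    licks.append(decision)
    return np.asarray(sorted(licks))
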