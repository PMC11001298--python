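"""Sniff detection and the intermittency an animal actually samples.

Detects inhalations on a synthetic pressure trace and compares the
stimulus intermittency with the sniff-gated (perceived) estimate.
"""

import numpy as np

from plumecoding import GeneratorConfig, sniff, stimulus, synthetic

config = GeneratorConfig(seed=2)
square = synthetic.gen_square_wave(5, 80, config)

pressure, true_onsets, _ = synthetic.gen_sniff_trace(
    4.0, config, rng=np.random.default_rng(2), noise_sd=0.01)
events = sniff.detect_sniffs(pressure)
print(f"true inhalations: {len(true_onsets)}, detected: {events.n}")
print(f"mean sniff frequency over the odor window: "
      f"{sniff.mean_sniff_frequency(events, (2.0, 8.0)):.2f} Hz")

gamma = stimulus.compute_intermittency(square)
perceived = sniff.perceived_intermittency(square, events)
print(f"stimulus gamma = {gamma:.3f}, perceived gamma = {perceived:.3f}")
# perceived != stimulus in a single trial because inhalations sample the
# pulse train at a few phases; over many trials the two agree on average

grid = np.arange(2.5, 8.01, 0.5)
curve = sniff.cumulative_perceived_intermittency(square, events, grid)
print("cumulative perceived gamma across the trial:")
for t, v in zip(grid[::3], curve[::3]):
    print(f"  t = {t - 2.0:.1f} s after odor onset: {v:.3f}")
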