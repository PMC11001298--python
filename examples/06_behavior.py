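"""Go/No-Go session analytics on a simulated behaving animal.

Scores a full 64-trial session (8 engagement trials + 28 CS+ / 28 CS-),
computes hit rate / false alarms / performance, the first-lick latency
fit, and decodes trial identity from cumulative perceived intermittency.
"""

import numpy as np

from plumecoding import GeneratorConfig, behavior, synthetic

config = GeneratorConfig(seed=6)
trials, truth = synthetic.gen_session(config, [], n_trials=64)

outcomes = behavior.score_trials(trials)
m = behavior.session_metrics(outcomes)
print(f"HR = {m.hr:.3f}, FA = {m.fa:.3f}, performance = {m.performance:.3f}")
print(f"meets criterion (HR > 0.75 and FA < 0.25): {m.meets_criterion}")

times = np.array([o.first_lick_time for o in outcomes])
gammas = np.array([t.nominal_intermittency for t in trials])
fit = behavior.first_lick_by_intermittency(times, gammas)
print(f"first-lick latency vs gamma: slope = {fit.slope:.2f} s per unit "
      f"gamma (r2 = {fit.r2:.2f}, {fit.n_lickfree} lick-free trials)")
# animals lick earlier on high-intermittency trials -> negative slope

res = behavior.decode_from_perceived(trials, t_cutoffs=[3.0, 5.0, 8.0],
                                     seed=6)
print("decoding CS+/CS- from cumulative perceived gamma:")
for t, a, c in zip(res.t_cutoffs, res.accuracy, res.control):
    print(f"  cutoff {t - 2.0:.0f} s after odor onset: accuracy {a:.3f} "
          f"(shuffled control {c:.3f})")
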