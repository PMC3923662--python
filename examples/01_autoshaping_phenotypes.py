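"""Simulate autoshaping acquisition for the three phenotypes.

Three groups of 14 agents share every parameter except the integration
weight omega (feature-value system vs planner).  High omega produces
sign-trackers (lever engagement), low omega goal-trackers (magazine
engagement), intermediate omega a mixed group.
"""
import numpy as np

from autoshape import Schedule, default_groups, run_autoshaping

results = run_autoshaping(default_groups(), Schedule(), seed=1)
print("Probability of engaging each stimulus, per 50-trial block:")
for label, res in results.items():
    lev, lev_sem = res.engagement_curve("lever")
    mag, _ = res.engagement_curve("magazine")
    omega = res.agents[0].config.omega
    print(f"  {label} (omega={omega}): lever {np.round(lev, 2)}  "
          f"magazine {np.round(mag, 2)}  (final-block sem {lev_sem[-1]:.3f})")
print("\nSign-trackers end lever-dominant, goal-trackers magazine-dominant,")
print("the intermediate group sits between them on both measures.")
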