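"""Per-session reward-prediction errors at CS onset and food delivery.

The feature-value system's RPE is the model's analogue of phasic dopamine.
Sign-trackers show the classic shift of the response from the US to the CS;
goal-trackers keep responding at the US (their magazine value is depressed
between trials, so food delivery stays better than expected) while a CS
response grows alongside.
"""
import numpy as np

from autoshape import Schedule, default_groups, run_autoshaping

results = run_autoshaping(default_groups(), Schedule(), seed=1)
for label, res in results.items():
    cs, _ = res.rpe_curve("CS")
    us, _ = res.rpe_curve("US")
    print(f"{label}: CS delta per session {np.round(cs, 3)}")
    print(f"{' ' * len(label)}  US delta per session {np.round(us, 3)}")
print("\nST: US response decays toward zero while the CS response saturates.")
print("GT: US response persists every session; IG: both persist, CS overtakes.")
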