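"""Inter-trial-interval manipulation predictions for goal-trackers.

The parameter u is the fraction of the magazine value lost to unrewarded
checks between trials.  Removing the magazine during the ITI (u = 0) should
make the goal-tracker's food-delivery dopamine burst disappear; longer or
richer ITIs (larger u) should enlarge it and erode goal-tracking.
"""
from autoshape import run_iti_manipulation

sweep = run_iti_manipulation(u_values=(0.0, 0.1, 0.3, 0.5), seed=1)
print("   u   US RPE at convergence   P(goal-track)")
for u, m in sweep.items():
    print(f" {u:.1f}        {m['us_delta']:.3f}               {m['goal_tracking']:.2f}")
print("\nThe food-delivery RPE vanishes at u = 0 and grows steeply with u;")
print("comparing the extremes, goal-tracking is weaker at u = 0.5 than at u = 0.")
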