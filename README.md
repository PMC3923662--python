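# autoshape

A dual-system reinforcement-learning simulator of Pavlovian autoshaping:
why some rats come to engage a reward-predicting lever (sign-trackers, ST),
others the food magazine (goal-trackers, GT), why only sign-trackers show
the classic reward-prediction-error-like dopamine signature, and why a
dopamine antagonist blocks the acquisition of sign-tracking but only the
expression of goal-tracking.

The package is for computational-neuroscience researchers who want to
simulate these experiments, probe the model's predictions (inter-trial
interval manipulations, conditioned reinforcement, dose–response curves),
compare model variants, or fit the model's parameters to engagement curves.

## The model

The task is an eight-state episodic MDP: empty box → lever appears (CS) →
approach lever / approach magazine / explore → lever retracts, food drops
(US) → consume → end of trial. Two learners evaluate every action
simultaneously:

* a **model-based planner (MB)** that learns the transition and reward
  functions by exponential averaging,
  T(s,a,s′) ← T + α(𝟙[s′] − T), R(s,a) ← R + α(r − R),
  plans Q(s,a) = R + γ Σ T·max Q by value iteration, and outputs the
  advantage A(s,a) = Q(s,a) − max<sub>a′</sub> Q(s,a′) ≤ 0. It favours the
  shorter magazine path: goal-tracking.
* a **feature-model-free learner (FMF)** whose temporal-difference values
  attach to the *stimulus an action is directed at* (lever, magazine, food)
  rather than to states:
  δ = r + γ·max<sub>a′</sub> V(f(s′,a′)) − V(f(s,a)), V(f(s,a)) ← V + αδ.
  Because the magazine value is depressed by unrewarded checking between
  trials — V(Magazine) ← (1−u)·V(Magazine) once per episode — while the
  lever anchors directly on the discounted food value, this system favours
  the lever: sign-tracking. Its δ is the model's analogue of phasic
  dopamine.

Decisions use a softmax (temperature β) over the convex combination
P(s,a) = ω·V(f(s,a)) + (1−ω)·A(s,a). The single weight ω spans the
phenotype spectrum: ω high → ST, low → GT, intermediate → mixed.
Flupentixol is modelled as δ′ = sign(δ)·max(0, |δ| − η<sub>RPE</sub>)
applied to every RPE a model-free-type learner consumes (systemic and
intra-accumbens), plus β′ = β·(1 + η<sub>temp</sub>) under systemic
administration only. Four model variants (replacing either system with
classical state-level learners or Pavlovian-impetus bonuses) are included
for comparison, and an NSGA-II fitter recovers parameters from engagement
curves. See `docs/methods.md` for assumptions, parameter meanings, and the
calibration of the defaults.

## Worked example

```bash
python examples/01_autoshaping_phenotypes.py
```

```
Probability of engaging each stimulus, per 50-trial block:
  ST (omega=0.8): lever [0.83 1.   1.   1.  ]  magazine [0.11 0.   0.   0.  ]  (final-block sem 0.000)
  IG (omega=0.35): lever [0.66 0.79 0.79 0.8 ]  magazine [0.28 0.21 0.21 0.2 ]  (final-block sem 0.104)
  GT (omega=0.05): lever [0.21 0.15 0.15 0.16]  magazine [0.52 0.57 0.57 0.57]  (final-block sem 0.096)

Sign-trackers end lever-dominant, goal-trackers magazine-dominant,
the intermediate group sits between them on both measures.
```

Three groups of 14 simulated rats, 8 sessions of 25 trials, sharing every
parameter except ω. The numbers are mean probabilities (per 50-trial block)
that a trial contained at least one lever or magazine engagement: the ST
group converges on the lever, the GT group on the magazine, the
intermediate group in between. The other examples in `examples/` show the
dopamine-like RPE traces (`02`), the conditioned-reinforcement probe
(`03`), both flupentixol experiments (`04`, `05`), the ITI predictions
(`06`), and parameter recovery by NSGA-II (`07`). A thin CLI wraps the same
protocols (`autoshape autoshaping --seed 1`, `autoshape local-flu …`); it
writes tidy CSVs, a JSON summary, and the resolved configuration.

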