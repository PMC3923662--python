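# Methods

## Task model

One conditioning trial is one episode of a deterministic, acyclic,
eight-state MDP. From the empty pre-CS state the only action is to explore;
lever appearance (CS onset) opens the single choice point — approach the
lever, approach the magazine, or keep exploring — after which engagement
with the proximal stimulus is forced, food is delivered, the agent reaches
the magazine if it is not already there, eats (the only rewarded
transition, magnitude `r_food`), and the episode ends. The magazine path is
four actions long, the lever and exploration paths five, so any discounting
planner prefers the magazine path. Engagement is exclusive: a trial can
contain a lever CR or a magazine CR, never both.

Every legal (state, action) pair carries a *feature* — the stimulus the
action is directed at: approach/engage lever → Lever; approach/engage
magazine during the CS period → Magazine; eating → Food; exploring and
pre-CS behaviour → None. Post-delivery approach to the magazine is directed
at the delivered **food**, not the empty magazine. This last assignment is
load-bearing: it lets the lever (one step upstream of food on its path)
anchor near the full discounted food value. If that transition is instead
labelled Magazine, the lever's value is capped by γ·V(Magazine), sits
strictly below the magazine value at every parameter setting, and no weight
on the feature system can produce sign-tracking — contradicting the
behaviour the model exists to explain. The feature table, like the whole
topology, is data (explicit maps serialisable to a plain document), so
alternative readings are one configuration away.

The inter-trial interval is not represented as states. Its behavioural
residue — rats occasionally check the empty magazine between trials — is a
single per-episode revision applied before the first transition:
V(Magazine) ← (1 − u)·V(Magazine), u ∈ [0, 1]. The multiplicative form is
the aggregate of unrewarded TD revisions toward zero; u = 0 removes the
mechanism entirely (as if the magazine were absent during the ITI).

## Learning systems

**Model-based planner (MB).** Learns T and R by exponential averaging with
the shared learning rate α and replans after every observation; on the
acyclic task one successors-first sweep of value iteration is exact, so the
planner is always at the fixed point of its current model. Its read-out is
the advantage A(s,a) = Q(s,a) − max Q(s,·) ≤ 0 (using Q directly would be
equivalent for choice within a state). Unvisited pairs keep T ≡ 0 and
Q = R₀, so the early planner is ignorant rather than optimistic.

**Feature-model-free learner (FMF).** A TD(0) learner over the four
features with the bootstrap
δ = r + γ·max over next legal actions of V(feature) − V(current feature).
Only the focused feature is updated (one value per step); V(None) is pinned
at zero. The pin matters: if exploration could absorb value, the CS-onset
prediction error — computed on a None-focused transition — would vanish
with training, and the persistent CS response of trained sign-trackers
with it. Because features are shared across states, a revision made at food
delivery is the same number consulted at the CS choice point; that
generalisation is what keeps the goal-tracker's food-delivery error
permanently positive (the ITI keeps deflating V(Magazine) that food
delivery keeps reinflating).

**Integration and choice.** P(s,a) = ω·V(f(s,a)) + (1 − ω)·A(s,a),
softmax with temperature β (larger β = flatter; ties broken by fixed action
order, measure-zero with continuous values). ω is the only parameter that
differs between the canonical phenotypes.

**Variants.** v1 replaces the planner with a state-level advantage
(Q-)learner; v2/v3 combine a Q-learner with an ω-weighted Pavlovian-impetus
bonus (max Q of the state) on lever-directed actions (v2) or on both lever-
and magazine-directed actions (v3); v4 combines the two state-level
advantages. v4's two systems provably converge to the same values and both
favour the short path, so it cannot sign-track at any ω — the factored
representation, not duality alone, carries the phenomenon.

## Pharmacology

A dopamine antagonist has two dose-proportional effects. Learning:
δ′ = sign(δ)·max(0, |δ| − η) for every RPE consumed by a model-free-type
learner — the additive clamp can block learning but never reverse it (a
multiplicative shrink only slows learning, which is why it is not used);
negative errors are clamped symmetrically, so |δ′| ≤ |δ| always. The ITI
revision passes through the same clamp, being itself a summary of
dopamine-dependent negative updates; full blockade therefore freezes the
feature values exactly. Expression: β′ = β(1 + η_temp), systemic
administration only — intra-accumbens injections spare the selection
mechanism. The planner is untouched by both.

Dose maps to effect via two protocol constants (k_rpe, k_temp). The
systemic protocol uses a fully blocking dose (η ≥ max attainable |δ| =
(1 + γ)·r_food) with k_temp large enough that β′ ≈ 2 flattens choice to
near-uniform. The local protocol uses doses on the *monotone branch* of the
magazine-value equilibrium: while η < u·V(Magazine), the drug blocks the
small ITI decrement before it blocks the large food-delivery reload, so
V(Magazine) climbs monotonically with dose and competes with the lever.
Beyond that branch (η ≳ 0.23 at the defaults) the equilibrium turns over
and the dose–response would invert; the default grid (doses 0–4,
k_rpe = 0.05, η ≤ 0.2) stays on the branch. Expression effects emerge only
through relearning during the test sessions — an instant (first-trial)
drug effect is outside this model class. The dose–response metric is the
softmax probability of each approach at lever appearance (the same
value-based probe used elsewhere), which responds smoothly to the
drug-shifted values instead of quantising through trial sampling.

## Default parameters (shared calibration)

All groups share α = 0.1, γ = 0.98, β = 0.1, u = 0.3, r_food = 1,
V₀(Magazine) = 0.1, V₀(Food) = 0.5, R₀ = Q₀ = 0; phenotypes differ only in
ω: ST 0.8, IG 0.35, GT 0.05. These come from a regime analysis, not from a
fit:

* On the pure sign-tracking path the lever value fixes at
  V(Lever)\* = γ·r_food/(2 − γ) (the approach step's own bootstrap drags it
  below γ·r_food), leaving a residual food-delivery error
  γ(1 − γ)/(2 − γ)·r_food. For the trained sign-tracker's US response to
  count as extinguished (< 0.05) γ must exceed ≈ 0.95; γ = 0.98 leaves
  margin. The cost is a small planner advantage range (γ²(1 − γ) ≈ 0.019),
  which compresses the ω phenotype boundary toward zero — hence the small
  GT default.
* β = 0.1 balances two failure modes: much colder and early magazine value
  (V₀ and first updates) locks *every* agent into goal-tracking before the
  lever is sampled; much hotter and the goal-tracker's small decision gaps
  drown in exploration.
* u = 0.3 is large enough that the per-episode magazine deflation outpaces
  reinflation (the sign-tracking condition V(Lever) > V(Magazine) at choice
  time requires roughly u > 1 − γ plus slack); u = 0.1 already abolishes
  sign-tracking at these settings.
* V₀(Magazine) = 0.1 and V₀(Food) = 0.5 encode magazine pretraining: enough
  early bias to seed goal-tracking and bootstrap the first lever value,
  small enough not to trap high-ω agents.

The intermediate group sits deliberately near the phenotype boundary, so
its agents bifurcate (some lock to the lever, some to the magazine) and its
group curves carry the largest seed-to-seed variance; orderings between
group means are stable, exact values are not.

## ITI-manipulation metric

The sweep over u reports, per condition, the population goal-tracking
probability and the mean food-delivery RPE **on magazine-CR trials**. The
prediction being tested concerns the goal-tracker's US burst while engaging
the magazine; an all-trials mean would be floored by rare exploration-path
transitions, whose bootstrap runs through the permanently-zero None feature
and yields a large δ at any temperature, masking the u = 0 disappearance of
the burst.

## Feature-value contribution

The incentive-salience read-out ablates the ω·V term of the favoured
action only and reports 100·(P_full − P_ablated)/P_full: the share of the
favoured CR's choice probability owed to the motivational value of the
stimulus being engaged. Feature values are non-negative here, so the
contribution is non-negative by construction. (Ablating the term for *all*
actions instead also removes the lever bonus from the goal-tracker's
comparison set; since trained goal-trackers still carry a sizeable lever
value — they sample the lever on a fraction of trials throughout — that
variant can make the magazine CR look *anti*-driven by feature values,
which answers a different question.)

## Fitting

Two objectives — summed squared per-block differences of the lever and the
magazine engagement curves, kept separate because lever curves are
systematically easier to match — are minimised by NSGA-II (non-dominated
sorting, crowding distance, binary tournaments, SBX crossover η = 15 at
rate 0.5, polynomial mutation η = 20 at rate 0.1, box bounds per
parameter). Implementation details that matter for noisy objectives:

* Candidate evaluation simulates `reps` agents; all candidates within a
  generation share repetition seeds (common random numbers), and each
  genome re-accumulates `draws_per_generation` fresh evaluations per
  generation it survives, its fitness being the running mean. Survivors are
  therefore good under many noise draws, not one lucky one, and the whole
  fit is deterministic given its seed.
* The GA's internal fitness subtracts the finite-repetition variance
  estimate (sample variance of the per-agent curves / reps) from the
  squared error. The plain squared error of a small-sample mean contains
  Var(mean), which vanishes as curves saturate at 0 or 1 and otherwise
  pulls a noisy search toward saturated (extreme-ω) regimes; the corrected
  statistic is an unbiased estimate of the population-curve distance. The
  public `objectives` function keeps the plain non-negative least-squares
  definition.
* The Pareto representative is chosen automatically as the front member
  minimising the sum of min–max-normalised objectives (reproducible, in
  place of picking by eye).
* The engagement simulator used by the objectives is a compiled (numba)
  re-implementation of the same trial loop, specialised to the default
  topology; a statistical-equivalence test against the reference loop
  guards it, and the pure-Python path is used automatically when numba is
  absent or a non-default variant is fitted.

Identifiability: above the phenotype boundary the curves saturate, so ω is
only weakly identified there (for a target generated at ω = 0.8 the
likelihood basin spans roughly ±0.1 even with a low-noise target);
recovery experiments therefore use session-level (25-trial) blocks and a
large generating group (500 synthetic agents), and still inherit that
basin. With all eight parameters free, only ω is expected to recover — it
is the one parameter the phenotypes require.

## Synthetic targets

Model-generated targets (known ground truth, optional truncated Gaussian
block noise) stand in for behavioural engagement curves, which exist only
as published figures; logistic-shaped "smoke" targets exercise the fitting
pipeline without trusting the simulator under test. Passing recovery on
synthetic targets shows the estimation pipeline is sound under the model's
own noise structure — not that the model fits any real rat, and not that
parameters beyond ω would be identifiable from real curves of this length.

## Known limitations

Discrete time only: no CS duration, response latencies, or within-trial
repeated lever presses. One engagement per trial by construction. The
softmax forces probability freed from one action onto the others, which is
why blocking sign-tracking *increases* simulated goal-tracking where the
experimental data show invariance; this artefact is reproduced as-is.
Drug effects require relearning; instant post-injection expression changes
are out of scope. The ITI is a single scalar revision, so ITI-duration
predictions are qualitative. Group-level curves at n = 14 carry the
bifurcation variance described above; comparisons in the test suite are
therefore ordinal or carry an explicit Monte-Carlo allowance.
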