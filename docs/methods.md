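# Methods

## Overview

`hexnav` is a simulation-and-analysis pipeline for a question in the
computational neuroscience of spatial navigation: when an agent is free to
act in either a world-fixed (allocentric) or a body-centred (egocentric)
reference frame, which strategy does it adopt for a given task, and what
spatial representations emerge in its network to support that strategy?

The pipeline has five stages, each usable on its own:

1. **World.** A square arena whose movement graph is a hexagonal lattice
   (`arena`), with deterministic transition dynamics over three action
   spaces (`actions`), and two episodic tasks (`tasks`): *guidance* (fixed,
   unmarked goal; stable distal landmarks) and *aiming* (visibly cued goal
   relocated every 10 trials).
2. **Vision.** A procedural panoramic renderer (`rendering`) producing the
   agent's only input: 48x12 RGB images with a 240-degree field of view.
3. **Learner.** A convolutional dueling double-DQN with experience replay
   and epsilon-greedy exploration (`dqn`), written directly in numpy.
4. **Representation analysis.** Spatial activity maps of the 50-unit layer
   preceding the action outputs, classified into place / egocentric-vector /
   head-direction-modulated / view-selective / other cells, plus coverage
   entropy of the place-cell population (`analysis`).
5. **Perturbation.** Noise-injection lesions of single units or whole
   classes, measuring test-phase success (`lesion`).

`experiments` orchestrates full studies (full/constrained models,
generalization splits, environmental manipulations, dropout sweeps), and a
small CLI (`python -m hexnav`) exposes the verbs.

## Model

### World and actions

Nodes are the points of a hexagonal lattice (spacing 0.25 m by default, one
axis aligned with the arena's x-axis, anchored at the centre) that fall
strictly inside the square; nodes close to a wall are kept, since walls act
through the collision rule, not the geometry. Headings are the six lattice
directions, 60 degrees apart. The *allocentric* action space has 12 actions:
move one step in lattice direction d (0..5), or rotate in place to absolute
heading h (0..5). The rotation is absolute ("face direction h") rather than
relative, matching the allocentric reading of the action space. The
*egocentric* space has 3 actions: step forward along the current heading,
turn 60 degrees left, turn right. The *full* space concatenates the 12
allocentric actions with four copies of each egocentric action (24 total) so
that neither frame is favoured by action count; copies are distinct output
units with identical physical effect, and TD credit flows only to the copy
actually chosen. Moves into a missing neighbour (wall/corner) leave the
agent in place and are penalised like any step.

### Tasks and rewards

+1 on reaching the goal node, -1 for every other step (collisions included).
An episode ends on goal arrival or after `max_steps` (100 at full scale);
arrival exactly on the last step counts as success. The goal-reaching step
earns +1 alone (not -1+1); both rules are stated independently in the task
definition and this composition keeps "+1 upon successfully reaching the
goal" literal — it is config-overridable. A start drawn equal to the goal is
redrawn: a zero-length trial carries no learning signal. In guidance the
goal node is fixed per experiment (drawn reproducibly from the seed, by
default in the upper-right quadrant). In aiming the cued goal is redrawn
uniformly every 10 trials. Generalization experiments split the eligible
nodes 80/20 (start nodes for guidance, cue nodes for aiming), assigned
randomly per agent before training.

### Vision

Rather than a full 3D engine, vision is a deterministic column-raycast
renderer that preserves exactly the information the agent needs: distal colour landmarks, cue bearing and apparent size, and
lighting cues. Column c looks along azimuth `heading*60 - 120 +
240*(c+0.5)/48` degrees; the nearest surface hit by that ray (one of four
distinctly coloured walls, or the red cue cylinder of radius 0.10 m) sets
the column's colour, and its distance d sets the vertical extent of the
surface band around the horizon, half-height `(H/2)/(1+d/d0)` rows with
`d0 = side/4`. Two point lights above opposite corners multiply column
brightness with a Gaussian angular profile (sigma 25 degrees) and 1/distance
falloff. Wall colours are blue/green/yellow/magenta — pure red is reserved
for the cue. The spatial-information manipulations follow directly: *high* =
walls + point lights, *medium* = point lights only, *low* = a uniform
distant light (fixed sky/floor gradient) plus the cue if present. Because a
60-degree rotation shifts the column grid by exactly 12 columns (azimuths
are canonicalized mod 360 in degrees, where the half-degree grid is exact in
floating point), columns imaging the same world azimuth are bit-identical
across headings. Eye/head movements independent of the body are not
modelled.

### Learner

Three 5x5 convolutions (32/64/64 filters at full scale; stride 2 along the
48-pixel panorama axis, stride 1 vertically, with one row of vertical
padding on the third layer so the map shrinks 12x48 -> 2x3), then a fully
connected layer of 50 rectified units — the **analysis layer** — with
dropout (rate 0.35) during training, feeding a dueling head: V and A streams
are linear maps from the 50-unit layer itself, so the analysed layer
unambiguously precedes both streams. Q(s,a) = V(s) + A(s,a) - mean(A).
Training: epsilon-greedy behaviour (epsilon = 0.3, constant), FIFO replay of
3000 transitions, one Adam step (lr 0.001) per environment step on the
squared TD error of the chosen action, double-Q targets (gamma = 0.99) with
a target network synced every 100 steps, 4000 trials. Unstated details fixed
here: minibatch 32, He fan-in initialization, one gradient step per
environment step, Adam. Evaluation (generalization tests, lesion tests) runs
at epsilon = 0.05, the customary DQN test-phase exploration rate — a purely
greedy policy on a deterministic environment can trap the agent in a
rotation loop, which would measure policy brittleness rather than task
knowledge; lesion baselines and lesioned runs use identical seeds either way.

### Activity maps and classification

Maps sample the analysis layer's activations on a 25x25 grid of bin centres
over the arena (continuous positions, not snapped to lattice nodes), for
each of 6 headings, in evaluation mode, then smooth each heading slice with
a Gaussian filter (sigma = 2 bins, edge-replicated borders). *Position maps*
move the agent; *cue maps* fix the agent at the centre and move the cue.

A unit's field in one heading slice is the >=15%-of-peak region; the field
*centre* is defined as the activation-weighted centroid of the connected
component containing the peak; "active in < 50% of the environment" is
evaluated on the full
>=15% mask. The decision cascade (first match wins, making classes mutually
exclusive):

1. global peak below 1% of the layer-wide maximum -> **other** (rectifier
   nets have dead units);
2. active (per-heading peak >= 20% of the unit's global peak) in <= 2
   headings -> **view_selective**;
3. all active headings localized (mask < 50% of arena) with centres within
   5% of arena size of each other -> **place**;
4. otherwise rotate each heading's allocentric centroid offset into the body
   frame by -60h degrees; if the egocentric vectors agree within 5% of arena
   size in length and one 60-degree sector in angle -> **ego_vector**.
   For cue maps the offset is field-centre minus agent (the field marks
   where the *cue* is); for position maps the relation inverts (the field
   marks where the *agent* is relative to the goal): offset is reference
   minus field-centre, with the goal as reference;
5. all active headings localized -> **hd_modulated**;
6. otherwise -> **other**.

Per-heading field extraction (rather than heading-averaged) is what "field
centre did not change location with head direction" literally requires. The
view-selectivity threshold (20%) and heading count (<= 2, "a single head
direction or a subset") and the one-sector angular tolerance for ego vectors
are free parameters of the cascade, exposed in `ClassifierParams`.

**Coverage entropy**: direction-averaged maps of all place units are summed,
normalized to a probability distribution over the 625 bins, and summarized
by Shannon entropy in bits; uniform coverage gives log2(625) = 9.288 bits,
goal-clustered coverage less.

**Fixture generator** (`generate_fixture_maps`): synthetic per-heading maps
realizing each class's defining geometry — Gaussian bumps (sigma 1.75 bins)
that are position-stable (place), at a fixed body-frame vector (ego_vector),
heading-scattered (hd_modulated), present in <= 2 headings (view_selective),
or broad and unlocalized (other) — with uniform positive noise up to a
stated fraction of the bump amplitude. These provide known ground truth for
classifier validation; they do not emulate training noise correlations, so
classifier accuracy on fixtures bounds idealized, not in-vivo, performance.

### Lesions

A lesion adds zero-mean Gaussian noise to targeted analysis-layer units on
every forward pass, s.d. = `noise_scale` x the maximum activation in the
layer. "Maximum activation in the layer" is read per forward pass (the
self-contained reading); a dataset-wide constant is available via
`layer_max`. Noise is redrawn every pass, not frozen per trial. Performance
is the success fraction over 25 test trials; a zero-scale lesion reproduces
the baseline bit-for-bit under the same seeds.

## Scale presets and what the tests show

`full_scale_preset` keeps the full study conditions (2.75 m arena at 0.25 m
spacing — 379 nodes, 4000 trials, 32/64/64 filters); a single such training
takes hours on one CPU and is intended for deliberate full-scale runs.

`desk_preset` preserves the structure at desk scale: a 2.0 m arena at 0.5 m
spacing (17 nodes), 40-step episodes, 8/16/16 filters in front of the same
50-unit analysis layer, minibatch 16, replay 1500, a gradient step every
second environment step, and 300 (guidance) / 450 (aiming) trials —
aiming's moving cued goal needs more episodes to converge at this scale.

Two phenomena need specific desk conditions, provided as named configs:

* **Strategy preference** (`desk_preference_config`). In arenas with 2-4
  step paths, egocentric solutions are as good as allocentric ones and the
  full model settles on whichever strategy exploration consolidates first;
  the allocentric advantage in guidance (turn steps wasted by the
  egocentric strategy; one heading-invariant mapping versus six
  heading-specific ones) becomes decisive only with longer paths and
  well-fitted Q-values. The guidance preference study therefore uses a
  2.5 m arena (23 nodes), 700 trials, and full-strength learning (a
  gradient step per environment step, minibatch 32, replay 3000); under
  these conditions the allocentric preference emerges in every seed
  examined, with the same gradual consolidation the full-scale model shows.
  Aiming keeps the 17-node arena, where the egocentric preference is
  already decisive.
* **Generalization** (`desk_generalization_config`). Guidance trains both
  strategies in the 2.5 m arena with identical budgets (225 trials,
  full-strength learning); aiming trains under low spatial information
  (200 trials). The aiming contrast reproduces sharply (the egocentric
  agent steers by the visible cue regardless of landmarks; the allocentric
  agent cannot self-localize). The guidance contrast does **not** reproduce
  at this scale: both strategies reach held-out-start success near 1.0,
  because the agent traverses held-out nodes mid-episode during training
  and the convolutional net interpolates neighbouring views — the
  view-memorization penalty of the egocentric strategy appears only at
  near-full-scale state counts. The corresponding test asserts the
  full-scale claim and is expected to fail at desk scale; it is retained,
  unweakened, as a scale marker.

Similarly, heading-invariant *place fields* do not form at desk scale under
any variant we examined (dropout up to 0.5, up to 700 trials, doubled
filters): localized fields appear but their centres move with heading,
i.e. units remain view-driven. Cross-view integration into allocentric
fields is a slow product of full-scale training; the coverage-entropy test
asserts the full-scale property (some place units; 0 < H < 9.288 with
goal-clustered centres) and likewise fails at desk scale by design rather
than being weakened. The entropy machinery itself is verified exactly on
analytic fixtures (uniform = 9.288 bits, single-bin = 0, two-bin = 1).

Desk-scale studies use 5 seeds (the full-scale study used 10-15); exact
class proportions and success values are scale-dependent and never
asserted, only ordinal contrasts.

## Numerical choices

* Network arithmetic is float32 (float64 available via `NetworkSpec.dtype`;
  the gradient checks run in float64). Convolutions are lowered to one GEMM
  per layer via im2col.
* Epsilon-greedy ties are broken uniformly among exact maxima.
* The replay buffer is preallocated and strictly FIFO; sampling is uniform
  with replacement.
* Divergence (non-finite TD loss) aborts training with a diagnostic rather
  than continuing silently.
* Smoothing uses `scipy.ndimage.gaussian_filter` (sigma in bins, truncation
  4 sigma, `mode="nearest"` = edge replication), applied per heading slice;
  linearity makes slice order irrelevant.
* An all-zero heading map yields no field descriptor; a unit whose active
  headings contain such a slice cannot be localized and falls through to
  *other*.
* Entropy uses the 0 log 0 = 0 convention and normalizes its input.
* Every run is fully determined by (config, seed): one generator seeded from
  the run seed drives exploration, dropout, minibatch sampling, and episode
  resets; evaluation and lesion noise use separate generators derived from
  the evaluation seed.

## Known limitations

* The renderer is a geometric abstraction: no texture, shadows, or
  perspective distortion. Distinguishability of views (>= 99% of pose pairs
  differ) is a tested invariant, but absolute pixel statistics differ from a
  3D engine's, so learned filters are not comparable to the original
  network's at the weight level.
* Desk-scale class proportions are noisier than full-scale ones (17 nodes,
  5 seeds); only ordinal claims are meaningful at that scale.
* The ego-vector cascade needs at least three active headings (fewer is
  view-selective by definition), so a genuinely vectorial unit active in
  only two headings is labelled view-selective.
* Lesion curves use the per-pass layer maximum; extremely sparse activity
  patterns make the effective noise scale fluctuate across passes.
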