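# Methods

`copsense` finds small sets of pressure-sensor positions on a foot-shaped
grid that reproduce the center-of-pressure (COP) trajectory of full
plantar pressure recordings. This note documents the model, the
numerical and design choices, what the synthetic data does and does not
emulate, and the problem sizes used in the shipped experiments.

## The placement problem and reward

A plantar pressure video is a sequence of H x W grids of pressure
(kPa); the default working resolution is H = 20 cells along the foot's
long (anteroposterior) axis and W = 7 across, obtained from native
insole recordings by stance splitting, border cropping and
force-conserving downsampling (below). The COP of frame *n* is the
pressure-weighted centroid in continuous 0-based cell units,

    COP_n = ( sum(p * x) / sum(p),  sum(p * y) / sum(p) ).

A placement assigns `n_sensors` (default 8) sensors to grid cells,
duplicates allowed; only the coverage mask matters. Masking the video to
the covered cells yields a second COP trajectory, and the episode reward
compares the two:

    reward = ( 1 - mean_n d_n / maxdistance ) ^ 0.4 ,
    maxdistance = sqrt(W^2 + H^2),

with d_n the Euclidean COP distance on frame *n*. The exponent 0.4
expands resolution near small distances. The reward lies in [0, 1] and
equals 1 exactly when the masked COP coincides with the full-field COP
on every frame.

Degenerate frames need a convention. A frame whose *full-field* COP is
undefined (zero total pressure) is excluded from the mean — this keeps
the attainable maximum at exactly 1 for videos with empty lead/tail
frames. A frame where only the *masked* COP is undefined (the placement
captures no pressure) incurs the maximal distance `d_n = maxdistance`,
which makes the empty placement score exactly 0.

## The decision process and reward redistribution

An episode starts from an empty board with a video drawn uniformly from
the dataset; each step places one sensor (one of H*W = 140 discrete
actions, row-major); the episode ends after exactly `n_sensors` steps.
In the raw formulation the only non-zero reward arrives at termination.

Because the episode reward of any placement *prefix* is cheap to
compute, the delayed reward can be redistributed exactly: with
accumulative reward `A_t` = episode reward of the prefix after *t*
placements (`A_0 = 0` for the empty board, matching the empty-placement
convention), the per-step reward is `r_t = A_t - A_{t-1}`. The sum
telescopes to the terminal reward identically, a duplicate placement
earns exactly 0, and a step can earn a negative reward when newly
captured mass drags the masked COP away from the target. Redistribution
is the default training signal (`reward_mode="redistributed"`); the
terminal mode is retained for ablations.

The observation given to the networks is the raw sensor-count grid (an
H x W integer image, scaled by `1/n_sensors` at the network input); the
remaining-budget counter is derivable from it and is not fed separately.

## SAC-Discrete

The agent is soft actor–critic with discrete actions: a categorical
policy pi_phi and twin soft Q-functions Q_theta1, Q_theta2 with
Polyak-averaged target copies. Per batch of replayed transitions:

* targets `y = r + gamma (1 - done) V(s')` with
  `V(s') = pi(s')^T [ min_i Qbar_i(s') - alpha log pi(s') ]`
  (clipped double-Q on the *target* networks, current policy);
* one Adam step per Q-network on the squared error at the taken action;
* one Adam step on `E_s[ pi(s)^T ( alpha log pi(s) - min_i Q_i(s) ) ]`
  with Q frozen;
* target update `thetabar <- tau thetabar + (1 - tau) theta` — note the
  orientation: large tau means slow target drift.

Probabilities are clamped at 1e-8 inside logarithms so that
`0 * log 0 = 0` holds exactly and a deterministic policy has zero
entropy. The temperature alpha is held fixed between population-based
training events rather than autotuned by gradient.

**Networks.** Both heads are dense nets over the flattened board:
140 -> 64 -> 64 -> 140 (ReLU, linear output) plus a linear
input->output shortcut, implemented directly in numpy with explicit
backprop. At this input size a dense net sees the entire spatial
pattern at once and trains in about a millisecond per agent step on one
CPU core. The shortcut matters: the value of placing on a cell depends
strongly on whether that same cell is already covered (a duplicate is
worthless), and the per-cell linear term expresses this directly
instead of routing it through the hidden layers — it measurably speeds
up credit assignment on the board task. Layer widths and the shortcut
are config (`hidden_sizes`, `skip_connections`); the dataset
experiments in the test suite use a wider 128 x 128 head without the
shortcut, which fits the more varied marginal-reward structure of a
20-video dataset better. The final layer is initialized at 1e-2 scale
so the initial policy is near uniform and initial Q-values near zero.

**Defaults** (all overridable): gamma 0.99, tau 0.995, Adam lr 3e-4,
batch 64, replay capacity 1e5, one gradient update every 4 agent steps,
1 000 uniform-random warmup steps, seed-derived RNG streams for network
init, action sampling, batch sampling and episode video draws. Training
is single-threaded-deterministic: a run is a pure function of its
config.

## Population-based training

A population (default 15 members) trains in parallel; each member's
temperature is initialized log-uniformly in [1e-3, 1e-1]. Every
`ready_interval` agent steps (default 5e5) a member is ranked by the
mean of its last 10 episodic rewards; a member in the bottom 20% copies
the parameters and temperature of a uniformly drawn top-20% member and
then multiplies its temperature by 0.8 or 1.2 (members outside the
bottom set are untouched, and the perturbation is applied only after an
actual copy). Cutoffs use ceil(0.2 N); ties rank by member index.

Scheduling is synchronous round-robin in slices of `slice_steps` agent
steps, which makes whole-population runs bit-reproducible from one seed;
the cost is that exploitation uses evaluations up to one slice old,
which at the default slice size (1e4 steps = 1 250 episodes) is
immaterial. The training budget is counted **per member** — the ready
interval implies ~20 exploit/explore events per member over a 1e7-step
run, which is the regime in which temperature adaptation is visible.

## Synthetic data

No public plantar-pressure corpus exists at this resolution, so the
package generates its own inputs; they define the study conditions for
all shipped tests.

**Testing video** (diagnostic): a 20 x 7 clip, empty first and last
frames, and a single pressure point that visits 8 fixed midline support
cells in order across 10 active frames with a triangular
increase-then-decrease magnitude ramp. Design rationale: a frame whose
active cell is covered is reproduced exactly by the masked video, and a
frame whose cell is missed leaves the masked frame empty (maximal
distance), so the episode reward depends *only on which support cells
are covered*. The landscape is modular — every uncovered support cell
has a strictly positive marginal (>= 0.04 under the defaults) from any
prefix — and the maximum of exactly 1 is attained precisely by
placements covering all 8 cells. An earlier design with simultaneous
pressure on all support cells was abandoned: its reward landscape
contained prefix states from which *no* single placement improved the
score (an exhaustive immediate-marginal search stalls at 0.96), i.e. it
was not solvable by incremental placement at all, which contradicts the
intended role of the video as a sanity check whose optimum is
reachable.

**Gait videos** (dataset stand-in): a 2D Gaussian pressure blob
travelling heel to toe with the double-hump (loading / push-off)
total-force profile of running stance, 5% multiplicative noise, and
seeded anatomical jitter (blob widths, contact duration, heel/toe
endpoints) across a dataset. These emulate the *geometry* a placement
optimizer must exploit — a concentrated moving pressure centroid — but
not subject-specific anatomy, forefoot/heel pressure splitting, sensor
saturation or crosstalk; results on them certify the optimizer, not any
clinical claim.

**Oracle.** `brute_force_optimal` enumerates all C(H*W, k) duplicate-free
subsets (duplicates never change the mask, so this finds the true
optimum of the multiset space) and returns all tied optima; it is
feasible only on tiny grids and is used as the independent ground truth
in tests.

## Shipped experiment scales

The full-scale experiment (population 15, 1e7 steps per member) is
CPU-days; the package's own experiments are scaled to desk size:

* **Testing-video run** (`diagnostic_run_config`, also what
  `scripts/acceptance.py` executes): population 3, 70 000 agent steps
  per member (~2.1e5 total, ~8 750 episodes per member), ready interval
  2e4. Single agents with a well-chosen temperature reach the optimum in
  30-50k steps on this video; the population plus exploit/explore makes
  the greedy-rollout reward of the best member reach the environment
  maximum 1.0 reliably. Runtime ~6 min on one CPU core.
* **Tiny-grid oracle equivalence**: 4 x 4 grid, 2 sensors, 3-frame
  random video; 2e4 training steps; the greedy placement's reward
  equals the brute-force optimum.
* **Temperature sensitivity**: fixed alpha 1e-3 vs 4e-3, 3 seeds each,
  6e4 steps; compared by the final moving-average (window 1 000)
  episodic reward. Too-low temperature starves exploration — some seeds
  lock onto incomplete placements — and averages clearly lower; the
  ordering is stable when the budget is extended further.
* **Learned-vs-naive dominance**: a single agent (temperature 1e-2,
  128 x 128 heads) trained for 6e4 steps on 20 seeded gait videos; its
  greedy placement must score at least a hand-sketched two-column
  layout on the same videos.

## Known limitations

* The reward targets COP fidelity only; pressure magnitudes, contact
  timing and regional loading are invisible to it.
* Episode rewards across a dataset are averaged per-episode draws, so a
  placement's evaluation is itself stochastic unless the full video set
  is scored deterministically (`evaluate_placement` without sampling).
* The synchronous PBT scheduler trades the paper-style asynchronous
  wall-clock parallelism for exact reproducibility.
* Networks are dense; on much larger grids a convolutional head would
  be the natural replacement and can be slotted in behind the same
  config surface.
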