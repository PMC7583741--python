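# copsense

Sensor-placement optimization for foot plantar center-of-pressure (COP)
trajectories, without prior anatomical knowledge.

In-shoe pressure systems record full plantar pressure videos (here on a
20 x 7 cell grid), but wearable insoles carry only a handful of discrete
sensors. Where should eight sensors go so that the COP trajectory
computed from just those cells best matches the full-field trajectory?
The space of ordered 8-sensor placements on 140 cells holds 140^8 ≈
1.5 x 10^17 possibilities, far beyond exhaustive search; `copsense`
treats placement as a sequential decision problem and solves it with
deep reinforcement learning. It is aimed at wearable-sensing and gait
researchers who want data-driven sensor layouts (or a testbed for
delayed-reward RL on a small combinatorial task).

## Method

For a pressure video with frames indexed by *n*, the COP is the
pressure-weighted centroid per frame; a placement is scored by

    reward = ( 1 − mean_n d_n / maxdistance )^0.4 ,  maxdistance = √(W² + H²),

where `d_n` is the per-frame Euclidean distance between the full-field
COP and the COP of the video masked to the covered cells. The reward
lives in [0, 1] and equals 1 exactly when the masked trajectory matches
everywhere.

An episode places one sensor per step on an initially empty board for 8
steps. The raw problem pays only a terminal reward; because the episode
reward of any placement prefix is computable, the terminal reward is
redistributed exactly over the steps by differencing prefix scores
(duplicate placements earn 0; negative steps are possible; the sum
telescopes to the terminal reward). The agent is **SAC-Discrete** — a
categorical policy with twin soft Q-networks, clipped double-Q targets
and Polyak-averaged target copies — and the entropy temperature α is
tuned online by **population-based training**: bottom-20% members
periodically copy parameters and temperature from the top 20% and
perturb the temperature by ×0.8 or ×1.2. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

Train a small population on the built-in diagnostic video (a pressure
point visiting 8 support cells under a ramp-up/ramp-down magnitude
pattern, empty first and last frames — full coverage of the 8 cells is
the unique optimum, with reward exactly 1):

```python
from copsense.orchestration import run_experiment, diagnostic_run_config

config = diagnostic_run_config(seed=1, out_dir="runs/testing")
summary = run_experiment(config)
print(summary["greedy_reward"], summary["best_alpha"])
```

which prints (about five minutes later):

```
1.0 0.012485819099590179
```

The best member's greedy rollout places one sensor on each of the 8
support cells and achieves the environment maximum 1.0; the winning
temperature (~1.2e-2) was found by PBT from a log-uniform start in
[1e-3, 1e-1]. The run directory contains per-member episode logs
(JSONL), moving-average reward curves, the final placement as JSON, and
a rendering of the placement over the accumulated pressure image.

The same machinery runs on synthetic running-stance videos (heel and
forefoot pressure regions cross-fading under the classic double-hump
force profile) or on your own recordings:

```
copsense preprocess --in raw/ --out clips/ --groups 5 --target 20x7 --seed 0
copsense train --data clips/ --pop 15 --steps 1e7 --seed 0 --out runs/full
copsense evaluate --placement runs/full/placement.json --data clips/ --episodes 1000
```

`preprocess` splits recordings at zero-pressure frames into stance
clips, keeps one clip per temporal fifth, crops the never-loaded
border, and downsamples to 20 x 7 with force conservation (P = F/A).

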