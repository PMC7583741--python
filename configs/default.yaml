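# Full-scale defaults for a dataset training run.
# Every named value is a package default; override per run.
env:
  grid: [20, 7]          # anteroposterior x mediolateral cells
  n_sensors: 8
  reward_mode: redistributed
sac:
  gamma: 0.99
  tau: 0.995             # target <- tau*target + (1-tau)*local
  lr: 0.0003             # Adam step size
  batch_size: 64
  update_every: 4        # agent steps per gradient update
  buffer_capacity: 100000
  warmup_steps: 1000
  hidden_sizes: [64, 64]
  skip_connections: true
pbt:
  population_size: 15
  exploit_fraction: 0.2  # top/bottom 20%
  perturb_factors: [0.8, 1.2]
  ready_interval: 500000 # agent steps between exploit/explore events
  alpha_range: [0.001, 0.1]  # log-uniform temperature initialization
budget: 10000000         # agent steps per population member
video_source: "gait:150" # or "testing", or a directory of .ppv files
moving_average_window: 1000
final_window: 1000
out_dir: runs/default
seed: 0
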