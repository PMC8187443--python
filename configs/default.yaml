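# rerep-kit pipeline configuration (all fields optional; defaults shown).
# Probabilities apply per label window / per round, not per minute.

genome:
  n_bins: 1000          # bins per chromosome
  bin_width: 10000      # bp
  coupling: 1.0         # timing <-> euchromatin coupling in [0, 1]
  smooth_bins: 50.0     # Gaussian sigma of the timing field, in bins

origins:
  density_per_mb: 30.0  # licensed origins per Mb
  skew: 2.0             # kappa: early-licensing intensity exp(kappa*(1-t))
  dormant_fraction: 0.15

simulation:
  fork_speed_kb_per_min: 1.5
  stall_prob: 0.05            # per fork side per label window
  fire_prob_normal: 0.6       # per competent origin per S phase
  rerep_bias: 2.0             # beta: early preference of re-firing
  relicense_prob: 0.3         # per origin per re-round
  label_minutes_first: 20.0
  label_minutes_second: 20.0
  cells: 500
  depth: 500.0                # expected NS reads per always-firing origin
  s_phase_minutes: 480.0
  rerep_minutes: 60.0         # re-round fork-extension window
  fiber_noise_cv: 0.05
  stress_dormant_fire_prob: 0.7
  stress_speed_factor: 0.5

analysis:
  asymmetry_threshold: 0.30   # |L-R|/max(L,R) rule
  peak_small: [250, 400]      # small-peak read window
  peak_large_min: 400         # large peaks above this
  n_fractions: 10
  timing_scheme: six_range    # or four_equal
  pseudocount: 1.0
  dormant_low: 50.0
  dormant_high: 250.0
  background_quantile: 0.9    # domain segmentation threshold quantile
  min_gap_bp: 10000
  min_size_bp: 20000
  flank_bp: 50000             # anchor-profile flank
  depth_per_bin: 50.0
  n_fibers: 1000
  treated_stall_prob: 0.4

out_dir: rerep_out
seed: 0
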