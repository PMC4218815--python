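# Full-pipeline configuration for `xenodeconv run --config config.yaml`.
# Every value shown is the default; omitted keys fall back to these.
out_dir: xenodeconv_run
seed: 0
simulate: true          # set false and give input_dir to analyze an existing bundle
# input_dir: path/to/bundle

simulation:
  n_genes_per_species: 150
  probes_per_set: 11
  probe_length: 25
  transcript_length: 400
  n_lines: 2
  n_animals_per_line: 4
  frac_de_human: 0.15
  frac_de_mouse: 0.15
  de_log2fc_mean: 1.5
  de_log2fc_sd: 0.4
  frac_xhyb_probes: 0.08
  xhyb_match_min: 15
  xhyb_coupling: 0.5      # kappa: raw-scale leakage of foreign abundance
  mixing_fraction_b: 0.5  # human fraction of region-B tissue
  mixing_jitter_sd: 0.05
  noise_sd: 0.25
  seed: 0                 # overridden by the top-level seed when simulating

# probe masking
l_min: 15                 # contiguous-match threshold, nt
i_min: 0.75               # seed-anchored ungapped identity threshold
min_probes_per_set: 3

# normalization / summarization
normalization: reference  # reference | scale | quantile
summarization_method: median  # median | medianpolish

# differential expression / consensus
alpha: 0.05
require_same_direction: true
use_adjusted_p: false

# enrichment
theta: 0.30               # minimum overlap coefficient between reported terms
p_max: 0.05
overlap_metric: min       # min (overlap coefficient) | jaccard

# concordance (count platform)
n_panel_genes: 30
count_dispersion: 0.05
count_depth: 50000.0
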