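"""Generate a synthetic xenograft experiment with planted ground truth.

Emulates the laser-microdissection design: 2 tumor lines x 4 animals x 3
regions (A tumor core, B area of invasion, C distal brain), with region B
being a human/mouse mixture hybridized on both array types.
"""

from xenodeconv import SimulationConfig, generate_bundle

cfg = SimulationConfig(seed=0)
bundle = generate_bundle(cfg)

sheet = bundle.sample_sheet
print(f"array samples: {len(sheet)} "
      f"({(sheet.array_species == 'human').sum()} human, "
      f"{(sheet.array_species == 'mouse').sum()} mouse)")
print(f"genes per species: {cfg.n_genes_per_species}, "
      f"probes per probeset: {cfg.probes_per_set}")

truth = bundle.truth
print(f"planted human DE genes (B vs A): {len(truth.de_genes('human'))}")
print(f"planted mouse DE genes (B vs C): {len(truth.de_genes('mouse'))}")
print(f"planted cross-hybridizing probes: {len(truth.xhyb)} "
      f"(exact implants of {truth.xhyb.match_length.min()}-"
      f"{truth.xhyb.match_length.max()} nt in the foreign transcriptome)")
print(f"region-B human fraction: "
      f"{truth.mixing.human_fraction.min():.2f}-"
      f"{truth.mixing.human_fraction.max():.2f}")

# The counts above are the ground truth every later stage is checked
# against: DE recovery, mask recovery and crosstalk bridging all refer to
# these planted quantities.
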