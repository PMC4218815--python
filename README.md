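# xenodeconv

Cross-species expression deconvolution for xenograft studies of tumor
invasion.

## The problem

In an orthotopic glioma xenograft, the invasion front is a physical mixture
of human tumor cells and mouse host cells. Laser microdissection yields
three regions per animal — tumor core (A), area of invasion (B), and distal
"normal" brain (C) — and region-B RNA is hybridized on **both** a human and
a mouse expression array. Short-oligo probes cross-hybridize across species,
so the raw region-B signal confounds the two compartments. `xenodeconv`
separates them computationally:

1. **Probe masking** — every probe is scored against the foreign-species
   transcriptome with an exact seed-and-extend matcher (both strands). A
   probe is excluded when its longest contiguous match reaches `L_min`
   (default 15 nt) or its seed-anchored ungapped identity reaches `I_min`
   (default 0.75); probesets left with fewer than 3 surviving probes are
   dropped. The reported longest match is provably exact at every length
   (equivalence with a dynamic-programming longest-common-substring oracle
   is part of the test suite).
2. **Normalization + summarization** — median-of-log-ratios normalization
   against a pseudo-reference profile (removes per-sample shifts, including
   the compartment-fraction shift of mixed samples, without the rank
   artifacts of distribution matching), then per-probeset median (or Tukey
   median polish) on the surviving probes.
3. **Differential expression** — per tumor line, a two-sided Welch *t* per
   gene on the region contrast (human compartment: B vs A; mouse
   compartment: B vs C), BH-adjusted within the contrast; the **consensus**
   keeps genes significant with the same direction in both lines. A
   hierarchical-clustering diagnostic (average linkage, 1 − Pearson)
   checks that consensus genes segregate the arrays by region (adjusted
   Rand index).
4. **Gene-set enrichment with overlap clustering** — hypergeometric upper
   tail P(X ≥ k) for up- and down-regulated consensus genes; significant
   terms are reported only when they share ≥ θ = 30% of their members
   (overlap coefficient |A∩B|/min(|A|,|B|)) with another significant term,
   and clusters are connected components of that overlap graph.
5. **Crosstalk inference** — consensus human genes × consensus mouse genes
   are bridged through a binding-pair reference after one-to-one orthology
   normalization, nominating tumor–host protein interactions (e.g. a human
   receptor meeting the mouse ortholog of its ligand).
6. **Cross-platform concordance** — a species-specific count platform
   (negative-binomial, housekeeping-normalized) re-measures a panel of
   consensus genes; concordance is sign agreement, Spearman correlation of
   log2 fold changes, and the validated proportion.

Because the real deposited arrays are not desk-reproducible, the package
ships a first-class **synthetic-data generator** that emulates the full
2-line × 4-animal × 3-region design with planted truth: known DE genes,
known cross-hybridizing probes (exact sequence implants into foreign
transcripts), and known mixing fractions. Every stage is validated against
that truth.

## Worked example

```bash
python examples/05_full_pipeline.py
```

prints (seed 0, default configuration):

```
probes flagged: human 132, mouse 132
consensus DEGs: human 22, mouse 22
clustering ARI (A vs B, human arrays): 1.0
reported GO-style terms: human 4, mouse 4
crosstalk candidates: 8
count-platform validated proportion: human 0.9545, mouse 0.9545
```

Reading these numbers: the mask recovered exactly the 132 planted
cross-hybridizing probes per species (no false flags — see
`examples/02_mask_probes.py`); the cross-line consensus recovered all 22
planted DE genes per species with no false positives; consensus genes
split the human arrays perfectly into tumor core vs invasion front
(ARI 1.0); the planted direction-specific gene sets surface as overlap
clusters; 8 tumor×host binding pairs bridge the two consensus lists; and
95% of the re-measured panel validates on the leakage-free count platform.

The other scripts in `examples/` walk through each capability separately,
and `xenodeconv --help` exposes the same stages as a CLI
(`simulate`, `mask`, `run`, `validate`; see `examples/config.yaml`).

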