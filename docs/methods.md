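# Methods

## Study design being modeled

The pipeline targets the laser-microdissection xenograft layout: two glioma
stem-cell lines, four injected animals per line, three dissected regions
per animal. Region A (tumor core, essentially pure human tissue) is
profiled on human arrays, region C (brain distal to the tumor, pure mouse)
on mouse arrays, and region B (the area of invasion, a human/mouse
mixture) on both array types — 32 array samples in all. The human
compartment contrast is B vs A (invading vs core tumor cells); the mouse
compartment contrast is B vs C (reactive vs normal microenvironment).

## Synthetic data model

The generator is the testbed for every stage, so its guarantees are spelled
out here.

**Sequences and design.** Each species gets `n_genes_per_species` (default
150) random transcripts of 400 nt. Probes (11 per probeset, 25 nt) tile
non-overlapping segments at the transcript head, leaving a ~100 nt
probe-free tail. One probeset per gene.

**Signal.** Probe log2 intensity is
`log2( φ_own · 2^(μ_g + Δ_g·[region B] + a_p) + κ · φ_foreign · 2^(μ'_{g'} + Δ'_{g'}·[B]) ) + ε`,
with gene baselines μ ~ N(7, 1), probe affinities a ~ N(0, 0.5) shared
across samples, noise ε ~ N(0, σ=0.25) i.i.d. on the log2 scale, and
compartment fractions φ: region A/C are pure (φ_own = 1); in region B the
human fraction f is 0.5 ± 0.05 per animal (a free parameter — the true
mixing proportion at the invasion front is not identifiable from the
design, so it is configurable and recorded in truth). The leakage term
applies only to implanted probes (below) and only where foreign tissue is
present, so regions A and C carry none by construction.

**Planted differential expression.** 15% of genes per species receive a
region effect Δ shared by both lines, sign ± at random, magnitude
|N(1.5, 0.4)|. The 15% rate and ~1.5 log2-unit effects are typical of
strong regional contrasts in microdissected tissue at panel scale; they are
deliberately large enough that n = 4 animals per group gives near-complete
power, so recovery failures indict the pipeline, not the sample size.

**Planted cross-hybridization.** 8% of probes receive an exact implant: a
window of the probe (length uniform in [15, 25] nt, either strand) is
written into the probe-free tail of a random foreign transcript. Implants
cluster within probesets — per affected probeset, 55–72% of its probes are
implanted — because real cross-hybridization is homology-driven and hits
most probes of an affected set; the clustering is what makes unmasked
median summaries genuinely biased while leaving ≥ 3 clean probes so the
probeset survives masking and the before/after comparison is like-for-like.

**Background decontamination.** At desk scale, chance alone puts ~2
shared 15-mers and ~160 shared 12-mers between 1650 random 25-mers and a
60 kb foreign reference, which would blur the planted truth. After design
construction the generator therefore mutates single bases (in probes, and
after implanting in foreign sequence outside implants and probe footprints)
until no probe shares any 12-mer — the matcher's seed scale — with the
foreign transcriptome or with another probe of its species, in either
orientation. The implants are then provably the only cross-species matches
of seed length or longer, which is what makes planted-mask recovery exact
rather than merely probable.

**Fixture bundle.** Everything is written as plain text (FASTA, TSV, GMT)
and round-trips bit-identically; identical seeds give byte-identical
bundles. The bundle also carries direction-specific enriched gene sets
(80% of members drawn from planted up- or down-regulated genes), a
one-to-one orthology map covering 90% of genes, and an interaction
reference seeded with human-DE × mouse-DE bridging pairs plus background
pairs, so enrichment and crosstalk have recoverable signal.

**What the generator does not emulate** — and hence what passing tests do
not show about real arrays: partial-homology hybridization thermodynamics
(implants are exact by design, since they are the truth the mask is scored
against), probe GC/Tm effects, spatial array artifacts, batch structure,
line-specific expression differences, and raw CEL-level preprocessing.
Real probe designs also target many genes with multiple probesets.

## Masking

The scorer is exact seed-and-extend: 12-mer seeds at every probe offset
against an indexed reference, maximal bidirectional extension, both
strands. Any common substring of length ≥ 12 contains a full probe 12-mer,
so extension recovers the true longest match; shorter matches are found by
per-length k-mer set membership, making `max_contiguous_match` exact at
every length (tested against an O(n·m) dynamic-programming oracle).
Identity is the fraction of matching bases in a full-length ungapped
alignment anchored at a seed diagonal; with no seed-length match it is 0,
which is the intended semantics: a probe with no 12-mer in common cannot
reach 75% identity through a detectable alignment. `N` never matches.
Thresholds `L_min = 15`, `I_min = 0.75` and `min_probes_per_set = 3` are
standard short-oligo cross-hybridization heuristics; the true filtering
rule used for the deposited data is not published, so these are declared
substitutes exposed as parameters, not reconstructions.

## Normalization and summarization

Default normalization is **median-of-log-ratios against a pseudo-reference**
(the row-median profile): each sample is shifted by the median, over
probes, of its log2 ratio to the reference. This removes global per-sample
factors — including the `log2(compartment fraction)` shift of every mixed
region-B sample — while staying robust to a sizable truly-differential
fraction, because the null probes' ratios concentrate tightly around the
offset. Two alternatives are selectable and instructive:

* `quantile` forces identical column distributions. With 15% of genes
  truly differential at desk scale, rank interpolation drags null genes by
  0.2–0.6 log2 units *identically in both lines*, producing correlated
  false consensus calls (precision ~0.7 in our experiments). The operation
  is retained with its full contract (identical sorted multisets, tie
  handling by mean of tied ranks) for data where differential mass is
  small.
* `scale` (plain column-median centering) removes global shifts but the
  column median itself drifts when the differential signs are imbalanced,
  leaving a shared ~0.1 log2 bias at these settings.

Summarization is the per-sample median over a probeset's surviving probes
(robust to residual contamination); Tukey median polish (overall + sample
effects) is available. Background correction is intentionally absent — the
generator adds none — and the provenance records this.

## Differential expression and consensus

Welch's unequal-variance t per gene, two-sided, on log2 expression;
undefined statistics (zero variance, equal means) are reported as p = 1.
BH adjustment is computed within each contrast. The consensus rule is raw
p < 0.05 in both lines with the same direction — matching the published
prioritization phrasing — with BH-q selectable. Welch rather than a
moderated/empirical-Bayes test because the generator's noise is Gaussian
with homogeneous variance and n = 4 per group keeps Welch's size near
nominal (measured 0.041 at α = 0.05; slightly conservative, as expected
from the Welch–Satterthwaite approximation at small n); a moderated variant
could be added behind the same contract for variance-heterogeneous data.

The clustering diagnostic uses average linkage on (1 − Pearson) distance
across samples restricted to consensus genes, cut into two clusters, and
reports the adjusted Rand index against region labels. Constant rows are
dropped with a warning since correlation is undefined for them.

## Enrichment and term clustering

Hypergeometric upper tail `P(X ≥ k)` with universe = genes measurable on
the masked array (terms and lists restricted to it first; unmeasured genes
cannot be drawn). Terms with k = 0 are never reported. The reporting
filter keeps significant terms (raw p ≤ 0.05, BH-q reported alongside)
that share at least θ = 0.30 of their members with another significant
term. The overlap denominator is min(|A|,|B|) — the overlap coefficient —
because "30% overlap with another category" reads as containment-style
sharing; this choice is not documented in the source analysis, so Jaccard
is available behind a flag. Clusters are connected components of the
θ-graph; raising θ only refines them.

## Crosstalk

Mouse consensus symbols are mapped into the human namespace through a
strictly one-to-one orthology table (one-to-many rows are an error, not a
guess; unmapped symbols are carried but cannot match). A candidate is any
(human consensus gene, mouse consensus gene) whose pair exists in the
unordered, de-duplicated reference. Direction of regulation is annotated
but never filtered — receptor/ligand biology runs in both directions —
and homotypic pairs (a gene binding its own ortholog) are tagged rather
than removed. Output is sorted and deterministic, and equals an exhaustive
triple-loop enumeration by construction and by test.

## Concordance

The count platform models a species-specific probe panel: negative-binomial
counts (variance m + 0.05·m²; Poisson below dispersion 1e-8) with mean
proportional to the planted raw-scale expression and a per-sample
log-normal lane factor — species-pure even in region B, since its probes
carry no cross-species binding. Normalization divides by the geometric
mean of housekeeping counts (genes with zero planted fold change), making
fold changes exactly invariant to per-sample scaling. Count DE uses the
same Welch contrast on log2(normalized + 1) for symmetry with the array
stage. "Validated" means significant on the count platform (p < α) with
the array's sign; the threshold and direction requirement are parameters
because the original validation criterion is not printed.

## Numerical and engineering choices

* All randomness flows from one integer seed per entry point;
  sub-generators derive from (seed, stream) pairs so stages are
  independently reproducible. Identical seeds ⇒ byte-identical outputs.
* Quantile-normalization ties get the mean of the reference values at the
  tied ranks (exact, not interpolated).
* Degenerate inputs fail loudly: empty references, non-ACGTN probes,
  groups with < 2 samples, genes missing from the universe, one-to-many
  orthology, unknown probe ids in a matrix.
* Problem sizes in the tests and the acceptance script (150 genes ×
  11 probes per species; 20 seeds for the bias comparison; 500 × 1000 for
  calibration) were chosen so the whole validation runs in about a minute
  on one CPU while keeping every Monte-Carlo margin far from its
  threshold.

## Known limitations

* The masking thresholds and the consensus/validation rules stand in for
  unpublished originals; they are exposed as parameters and their defaults
  are design decisions, not reconstructions.
* Exact-match scoring cannot flag probes that cross-hybridize through
  high-identity gapped alignments with no 12-mer seed; for 25-mers this is
  a negligible corner, and the identity criterion is explicitly
  seed-anchored.
* The generator's crisp truth (exact implants, decontaminated background)
  is what makes recovery testable as an equality; on real data
  cross-hybridization is graded and mask recovery would be a trade-off
  curve, not a point.
* One probeset per gene; multi-probeset genes and probeset-to-gene
  many-to-one summarization are out of scope.
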