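"""Synthetic mixed-species xenograft experiment with planted ground truth.

The generator emulates the laser-microdissection xenograft design the
pipeline is built for: two glioma stem-cell lines, four animals per line,
three regions per animal. Region A (tumor core) is profiled on human
arrays, region C (distal brain) on mouse arrays, and region B (area of
invasion) — a human/mouse mixture — on BOTH array types.

Everything downstream needs crisp truth, so the generator plants:

* per-species differentially expressed genes with known log2 fold changes
  (human: region B vs A; mouse: region B vs C), shared across lines;
* cross-hybridizing probes, realised as exact sequence implants of known
  length written into foreign transcripts; implants cluster within
  probesets, the way homology-driven cross-hybridization clusters in real
  designs, and land in a probe-free zone of the target transcript so that
  every probe remains an exact substring of its own transcript and truth
  stays crisp;
* per-sample human/mouse mixing fractions for region-B tissue.

Probe log2 intensity follows a standard additive microarray error model:
gene baseline + planted region effect + per-probe affinity offset, with the
species' compartment fraction entering multiplicatively on the raw scale
and i.i.d. Gaussian noise on the log2 scale. Implanted probes additionally
receive kappa times the foreign transcript's raw-scale abundance whenever
foreign tissue is present (region B only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import SimulationConfig
from .masking import DEFAULT_SEED_LENGTH, ProbeDesign, reverse_complement

HUMAN = "human"
MOUSE = "mouse"
_BASES = np.array(list("ACGT"))

# probes tile segments of probe_length + _PROBE_JITTER at the transcript
# head; the remainder of the transcript is a probe-free zone that can
# receive cross-hybridization implants without touching probe sequence
_PROBE_JITTER = 2

# range of the fraction of an affected probeset's probes that receive
# implants; homology hits many probes of a probeset, not isolated ones, but
# rarely all of them — the remainder is what summarization can still use
_XHYB_PROBESET_FRACTION = (0.55, 0.72)


def probe_zone_length(cfg: SimulationConfig) -> int:
    return cfg.probes_per_set * (cfg.probe_length + _PROBE_JITTER)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated experiment."""

    de_human: pd.Series  # gene -> planted log2FC (B vs A); 0 for non-DE
    de_mouse: pd.Series  # gene -> planted log2FC (B vs C); 0 for non-DE
    xhyb: pd.DataFrame   # probe_id, species, foreign_transcript, match_length, strand
    mixing: pd.DataFrame  # line, animal, human_fraction
    baselines: dict[str, pd.Series] = field(default_factory=dict)
    affinities: dict[str, pd.Series] = field(default_factory=dict)
    bridging_pairs: pd.DataFrame | None = None  # planted DE x DE interaction pairs

    def de_series(self, species: str) -> pd.Series:
        return self.de_human if species == HUMAN else self.de_mouse

    def de_genes(self, species: str, min_abs_lfc: float = 0.0) -> list[str]:
        s = self.de_series(species)
        return sorted(s.index[(s != 0) & (s.abs() >= min_abs_lfc)])


@dataclass
class References:
    """Simulated transcriptomes and probe designs for both species."""

    transcriptome_human: dict[str, str]
    transcriptome_mouse: dict[str, str]
    design_human: ProbeDesign
    design_mouse: ProbeDesign

    def transcriptome(self, species: str) -> dict[str, str]:
        return self.transcriptome_human if species == HUMAN else self.transcriptome_mouse

    def design(self, species: str) -> ProbeDesign:
        return self.design_human if species == HUMAN else self.design_mouse


@dataclass
class FixtureBundle:
    """Complete simulated experiment: references, measurements and truth."""

    config: SimulationConfig
    references: References
    intensities_human: pd.DataFrame  # human-array probes x samples, log2
    intensities_mouse: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: SyntheticTruth
    gene_sets: dict[str, dict[str, list[str]]]  # species -> term -> members
    interactions: pd.DataFrame
    orthology: pd.DataFrame

    def intensities(self, species: str) -> pd.DataFrame:
        return self.intensities_human if species == HUMAN else self.intensities_mouse


def _gene_ids(species: str, n: int) -> list[str]:
    prefix = "HGENE" if species == HUMAN else "MGENE"
    return [f"{prefix}{i:04d}" for i in range(n)]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class _SpeciesState:
    """Mutable generator state for one species' design."""

    transcriptome: dict[str, str]
    design: ProbeDesign
    # probe -> (transcript name, start offset); probes never overlap
    location: dict[str, tuple[str, int]]

    def mutate_probe(self, rng: np.random.Generator, pid: str,
                     offset: int) -> None:
        """Substitute one probe base, keeping probe and transcript in sync."""
        tx_name, start = self.location[pid]
        seq = self.design.sequences[pid]
        old = seq[offset]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        self.design.sequences[pid] = seq[:offset] + new + seq[offset + 1:]
        tx = self.transcriptome[tx_name]
        pos = start + offset
        self.transcriptome[tx_name] = tx[:pos] + new + tx[pos + 1:]


def _make_species_design(rng: np.random.Generator, species: str,
                         cfg: SimulationConfig) -> _SpeciesState:
    genes = _gene_ids(species, cfg.n_genes_per_species)
    transcriptome = {f"{g}_tx": _random_seq(rng, cfg.transcript_length)
                     for g in genes}
    seg = cfg.probe_length + _PROBE_JITTER
    rows, seqs, loc = [], {}, {}
    for g in genes:
        tx_name = f"{g}_tx"
        tx = transcriptome[tx_name]
        probeset = f"{g}_at"
        for j in range(cfg.probes_per_set):
            # non-overlapping probes: implanted windows stay unique to their probe
            start = j * seg + int(rng.integers(0, _PROBE_JITTER + 1))
            pid = f"{g}_p{j:02d}"
            rows.append((pid, probeset, g, species))
            seqs[pid] = tx[start:start + cfg.probe_length]
            loc[pid] = (tx_name, start)
    ann = pd.DataFrame(rows, columns=["probe_id", "probeset_id", "gene_id", "species"])
    return _SpeciesState(transcriptome, ProbeDesign(ann, seqs).validate(), loc)


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _probe_kmers(design: ProbeDesign, k: int):
    """Yield (probe_id, offset, canonical k-mer) over all probe windows."""
    for pid in design.probe_ids:
        seq = design.sequences[pid]
        for i in range(len(seq) - k + 1):
            yield pid, i, _canonical(seq[i:i + k])


def _dedupe_within_species(rng: np.random.Generator, st: _SpeciesState,
                           k: int) -> int:
    """Mutate probes until no two probes of one species share a k-mer
    (either orientation). Returns the number of mutations applied."""
    owner: dict[str, str] = {}
    hits: list[tuple[str, int]] = []
    for pid, i, c in _probe_kmers(st.design, k):
        prev = owner.setdefault(c, pid)
        if prev != pid:
            hits.append((pid, i))
    done = set()
    for pid, i in hits:
        if pid not in done:  # one mutation per probe per round
            st.mutate_probe(rng, pid, min(i + k // 2,
                                          len(st.design.sequences[pid]) - 1))
            done.add(pid)
    return len(done)


def _foreign_kmer_map(transcriptome: dict[str, str], k: int
                      ) -> dict[str, tuple[str, int]]:
    out: dict[str, tuple[str, int]] = {}
    for name in sorted(transcriptome):
        seq = transcriptome[name]
        for j in range(len(seq) - k + 1):
            out.setdefault(_canonical(seq[j:j + k]), (name, j))
    return out


def _clean_probe_vs_foreign(rng: np.random.Generator, st: _SpeciesState,
                            foreign: dict[str, str], k: int) -> int:
    """Mutate probes of ``st`` until they share no k-mer with the foreign
    transcriptome. Returns the number of mutations applied."""
    fmap = _foreign_kmer_map(foreign, k)
    done = set()
    for pid, i, c in _probe_kmers(st.design, k):
        if c in fmap and pid not in done:
            st.mutate_probe(rng, pid, min(i + k // 2,
                                          len(st.design.sequences[pid]) - 1))
            done.add(pid)
    return len(done)


def _decontaminate(rng: np.random.Generator, states: dict[str, _SpeciesState],
                   k: int, max_rounds: int = 60) -> None:
    """Remove every chance probe/foreign and probe/probe k-mer collision.

    At desk scale, random transcriptomes share plenty of short words with
    the probes by chance alone; planted truth is only crisp if those
    background agreements stay below the matcher's seed scale. Mutations
    always act on a probe (and its own transcript), so foreign sequence is
    never touched here.
    """
    pairs = ((HUMAN, MOUSE), (MOUSE, HUMAN))
    for _ in range(max_rounds):
        changed = 0
        for sp, other in pairs:
            changed += _dedupe_within_species(rng, states[sp], k)
            changed += _clean_probe_vs_foreign(
                rng, states[sp], states[other].transcriptome, k)
        if changed == 0:
            return
    raise RuntimeError("decontamination did not converge; "
                       "reference space too small for the probe count")


def _place_window(rng: np.random.Generator, foreign: dict[str, str],
                  target: str, insert: str, zone_start: int,
                  occupied: list[tuple[int, int]]) -> int | None:
    """Overwrite ``insert`` into the probe-free zone of ``foreign[target]``,
    avoiding previous implants (1 nt gap so implants never merge).
    Returns the implant position, or None if no free slot was found."""
    tx = foreign[target]
    L = len(insert)
    if len(tx) - zone_start < L:
        return None
    for _ in range(30):
        pos = int(rng.integers(zone_start, len(tx) - L + 1))
        if not any(pos < hi + 1 and lo - 1 < pos + L for lo, hi in occupied):
            foreign[target] = tx[:pos] + insert + tx[pos + L:]
            occupied.append((pos, pos + L))
            return pos
    return None


def _implant_xhyb(rng: np.random.Generator, cfg: SimulationConfig,
                  design: ProbeDesign, foreign: dict[str, str],
                  species: str) -> list[tuple]:
    """Write windows of selected probes into foreign transcripts.

    Mutates ``foreign`` in place and returns truth rows
    (probe_id, species, foreign_transcript, match_length, strand).
    """
    n_probes = len(design.probe_ids)
    n_implants = round(cfg.frac_xhyb_probes * n_probes)
    if n_implants == 0:
        return []
    zone_start = probe_zone_length(cfg)
    lo, hi = _XHYB_PROBESET_FRACTION
    probesets = sorted(design.probesets().items())
    order = rng.permutation(len(probesets))
    occupied: dict[str, list[tuple[int, int]]] = {}
    foreign_names = sorted(foreign)
    rows: list[tuple] = []
    remaining = n_implants
    for idx in order:
        if remaining <= 0:
            break
        _, members = probesets[idx]
        per_set = max(1, round(rng.uniform(lo, hi) * len(members)))
        k = min(per_set, remaining, len(members))
        chosen = sorted(rng.choice(members, size=k, replace=False))
        for pid in chosen:
            L = int(rng.integers(cfg.xhyb_match_min, cfg.probe_length + 1))
            p_start = int(rng.integers(0, cfg.probe_length - L + 1))
            window = design.sequences[pid][p_start:p_start + L]
            strand = "+" if rng.random() < 0.5 else "-"
            insert = window if strand == "+" else reverse_complement(window)
            placed = False
            for _ in range(20):  # try targets until one has room
                target = foreign_names[int(rng.integers(0, len(foreign_names)))]
                pos = _place_window(rng, foreign, target, insert, zone_start,
                                    occupied.setdefault(target, []))
                if pos is not None:
                    rows.append((pid, species, target, L, strand, pos, p_start))
                    placed = True
                    break
            if placed:
                remaining -= 1
    if remaining > 0:
        raise RuntimeError(
            f"could not place {remaining} cross-hybridization implants; "
            "increase transcript_length or lower frac_xhyb_probes")
    return rows


def _clean_junctions(rng: np.random.Generator,
                     states: dict[str, "_SpeciesState"],
                     xhyb: pd.DataFrame, k: int,
                     max_rounds: int = 40) -> None:
    """Destroy chance k-mer matches created after implanting.

    An implant stitched into a foreign transcript creates chimeric words at
    its ends, and fixing one conflict can by chance create another; these
    are removed by mutating a matched foreign base that lies outside every
    implant interval and outside every implanted probe's source window.
    When the base falls inside a (non-implanted) foreign probe's footprint
    the probe sequence is updated in sync, so the exact-substring invariant
    holds throughout and planted implants are never touched.
    """
    # implants written INTO each transcript: (owner probe, lo, hi)
    implants: dict[str, list[tuple[str, int, int]]] = {}
    for r in xhyb.itertuples():
        implants.setdefault(r.foreign_transcript, []).append(
            (r.probe_id, r.foreign_pos, r.foreign_pos + r.match_length))
    # implanted probes' source windows, in their own transcript coordinates
    source_probe: dict[str, tuple[int, int]] = {}
    source_tx: dict[str, list[tuple[int, int]]] = {}
    for r in xhyb.itertuples():
        sp = r.species
        tx_name, start = states[sp].location[r.probe_id]
        lo = start + r.probe_offset
        source_probe[r.probe_id] = (r.probe_offset,
                                    r.probe_offset + r.match_length)
        source_tx.setdefault(tx_name, []).append((lo, lo + r.match_length))

    def mutate_foreign(other_st: _SpeciesState, name: str, pos: int) -> None:
        tx = other_st.transcriptome[name]
        new = str(rng.choice([b for b in "ACGT" if b != tx[pos]]))
        other_st.transcriptome[name] = tx[:pos] + new + tx[pos + 1:]
        for pid2, (tx2, start2) in other_st.location.items():
            seq2 = other_st.design.sequences[pid2]
            if tx2 == name and start2 <= pos < start2 + len(seq2):
                off = pos - start2
                other_st.design.sequences[pid2] = (
                    seq2[:off] + new + seq2[off + 1:])
                break

    pairs = ((HUMAN, MOUSE), (MOUSE, HUMAN))
    for _ in range(max_rounds):
        changed = 0
        for sp, other in pairs:
            st, other_st = states[sp], states[other]
            foreign = other_st.transcriptome
            fmap: dict[str, list[tuple[str, int]]] = {}
            for name in sorted(foreign):
                seq = foreign[name]
                for j in range(len(seq) - k + 1):
                    fmap.setdefault(_canonical(seq[j:j + k]), []).append((name, j))
            for pid, i, c in _probe_kmers(st.design, k):
                for name, j in fmap.get(c, ()):
                    intervals = implants.get(name, [])
                    if any(p == pid and lo <= j and j + k <= hi
                           for p, lo, hi in intervals):
                        continue  # the probe matching its own implant
                    mutable = [
                        pos for pos in range(j, j + k)
                        if not any(lo <= pos < hi
                                   for _, lo, hi in intervals)
                        and not any(lo <= pos < hi
                                    for lo, hi in source_tx.get(name, ()))]
                    if mutable:
                        mutate_foreign(other_st, name, mutable[len(mutable) // 2])
                    else:
                        # fall back to the probe side, outside its own
                        # implant source window
                        s_lo, s_hi = source_probe.get(pid, (-1, -1))
                        free = [t for t in range(i, i + k)
                                if not s_lo <= t < s_hi]
                        if not free:
                            raise RuntimeError(
                                "junction cleanup found no mutable base")
                        st.mutate_probe(rng, pid, free[len(free) // 2])
                    changed += 1
        if changed == 0:
            return
    raise RuntimeError("junction cleanup did not converge")


def generate_references(
    config: SimulationConfig,
) -> tuple[References, pd.DataFrame]:
    """Simulate transcriptomes and probe designs for both species.

    Returns the references and the partial truth: the table of implanted
    cross-hybridizing probes (empty when ``frac_xhyb_probes`` is 0). After
    decontamination and implanting, the ONLY probe/foreign contiguous
    matches of seed scale (>= 12 nt) or longer are the planted implants,
    which is what makes planted-mask recovery exact.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    states = {sp: _make_species_design(rng, sp, cfg) for sp in (HUMAN, MOUSE)}
    _decontaminate(rng, states, DEFAULT_SEED_LENGTH)
    rows = _implant_xhyb(rng, cfg, states[HUMAN].design,
                         states[MOUSE].transcriptome, HUMAN)
    rows += _implant_xhyb(rng, cfg, states[MOUSE].design,
                          states[HUMAN].transcriptome, MOUSE)
    xhyb = pd.DataFrame(
        rows, columns=["probe_id", "species", "foreign_transcript",
                       "match_length", "strand", "foreign_pos",
                       "probe_offset"])
    if len(xhyb):
        _clean_junctions(rng, states, xhyb, DEFAULT_SEED_LENGTH)
    refs = References(states[HUMAN].transcriptome, states[MOUSE].transcriptome,
                      states[HUMAN].design, states[MOUSE].design)
    return refs, xhyb


def _sample_sheet(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for line in range(1, cfg.n_lines + 1):
        for animal in range(1, cfg.n_animals_per_line + 1):
            base = f"L{line}_M{animal}"
            rows.append((f"{base}_A_hs", f"L{line}", str(animal), "A", HUMAN))
            rows.append((f"{base}_B_hs", f"L{line}", str(animal), "B", HUMAN))
            rows.append((f"{base}_B_mm", f"L{line}", str(animal), "B", MOUSE))
            rows.append((f"{base}_C_mm", f"L{line}", str(animal), "C", MOUSE))
    return pd.DataFrame(
        rows, columns=["sample_id", "line", "animal", "region", "array_species"])


def _planted_lfc(rng: np.random.Generator, genes: list[str], frac: float,
                 mean: float, sd: float) -> pd.Series:
    lfc = pd.Series(0.0, index=pd.Index(genes, name="gene_id"), name="log2fc")
    n_de = round(frac * len(genes))
    de_genes = sorted(rng.choice(genes, size=n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    mags = np.abs(rng.normal(mean, sd, size=n_de))
    lfc[de_genes] = signs * mags
    return lfc


def simulate_experiment(
    config: SimulationConfig,
    references: References,
    xhyb: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate probe-level log2 intensities for the full array design.

    Returns (human-array intensities, mouse-array intensities, sample
    sheet, truth). Region-B samples appear once per array species; their
    same-species signal is scaled by the compartment fraction, and
    implanted probes leak kappa x foreign abundance (raw scale).
    """
    cfg = config.validate()
    # independent stream, offset so reference and experiment draws never overlap
    rng = np.random.default_rng((cfg.seed, 1))
    sheet = _sample_sheet(cfg)

    genes = {sp: _gene_ids(sp, cfg.n_genes_per_species) for sp in (HUMAN, MOUSE)}
    baselines = {sp: pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes_per_species),
        index=genes[sp]) for sp in (HUMAN, MOUSE)}
    lfc = {
        HUMAN: _planted_lfc(rng, genes[HUMAN], cfg.frac_de_human,
                            cfg.de_log2fc_mean, cfg.de_log2fc_sd),
        MOUSE: _planted_lfc(rng, genes[MOUSE], cfg.frac_de_mouse,
                            cfg.de_log2fc_mean, cfg.de_log2fc_sd),
    }
    affinities = {}
    for sp in (HUMAN, MOUSE):
        pids = references.design(sp).probe_ids
        affinities[sp] = pd.Series(rng.normal(0.0, cfg.affinity_sd, len(pids)),
                                   index=pids)

    # per-tissue mixing fraction for region B (human fraction)
    tissues = sheet[["line", "animal"]].drop_duplicates().reset_index(drop=True)
    fr = np.clip(cfg.mixing_fraction_b
                 + rng.normal(0.0, cfg.mixing_jitter_sd, len(tissues)),
                 0.02, 1.0)
    mixing = tissues.assign(human_fraction=fr)
    mix_lookup = {(r.line, r.animal): r.human_fraction
                  for r in mixing.itertuples()}

    # foreign-gene lookup for implanted probes: probe -> foreign gene id
    implant_target = {}
    for r in xhyb.itertuples():
        implant_target[r.probe_id] = r.foreign_transcript.removesuffix("_tx")

    matrices = {}
    for sp, other in ((HUMAN, MOUSE), (MOUSE, HUMAN)):
        design = references.design(sp)
        ann = design.annotation
        pids = ann["probe_id"].to_numpy()
        gene_of = ann["gene_id"].to_numpy()
        cols = sheet[sheet["array_species"] == sp]
        mu = baselines[sp][gene_of].to_numpy()
        eff = lfc[sp][gene_of].to_numpy()
        aff = affinities[sp][pids].to_numpy()
        # foreign abundance per probe (baseline + foreign region effect in B)
        is_implanted = np.array([p in implant_target for p in pids])
        f_gene = [implant_target.get(p) for p in pids]
        f_mu = np.array([baselines[other][g] if g else 0.0 for g in f_gene])
        f_eff = np.array([lfc[other][g] if g else 0.0 for g in f_gene])
        data = {}
        for row in cols.itertuples():
            in_b = row.region == "B"
            f_h = mix_lookup[(row.line, row.animal)]
            own_frac = 1.0 if not in_b else (f_h if sp == HUMAN else 1.0 - f_h)
            foreign_frac = 0.0 if not in_b else (1.0 - f_h if sp == HUMAN else f_h)
            own = own_frac * np.exp2(mu + eff * in_b + aff)
            leak = (cfg.xhyb_coupling * foreign_frac
                    * np.exp2(f_mu + f_eff * in_b) * is_implanted)
            noise = rng.normal(0.0, cfg.noise_sd, len(pids))
            # tiny raw-scale background keeps log2 finite when a
            # compartment fraction reaches 0 (pure-tissue limit)
            data[row.sample_id] = np.log2(own + leak + 1e-6) + noise
        matrices[sp] = pd.DataFrame(data, index=pids)

    truth = SyntheticTruth(
        de_human=lfc[HUMAN], de_mouse=lfc[MOUSE], xhyb=xhyb,
        mixing=mixing, baselines=baselines, affinities=affinities)
    return matrices[HUMAN], matrices[MOUSE], sheet, truth


def _make_gene_sets(rng: np.random.Generator, genes: list[str],
                    lfc: pd.Series, n_random_terms: int = 8,
                    n_planted_per_direction: int = 2) -> dict[str, list[str]]:
    """Gene-set collection with planted direction-specific enriched terms.

    Planted terms draw 80% of their members from the up- (or down-)
    regulated planted DE genes, the rest at random; the remaining terms are
    uniform draws, so only planted terms should surface in enrichment.
    """
    sets: dict[str, list[str]] = {}
    non_de = sorted(lfc.index[lfc == 0])
    for direction, pool in (("UP", sorted(lfc.index[lfc > 0])),
                            ("DN", sorted(lfc.index[lfc < 0]))):
        for t in range(n_planted_per_direction):
            size = int(rng.integers(10, 16))
            n_from_de = min(round(0.8 * size), len(pool))
            members = list(rng.choice(pool, size=n_from_de, replace=False))
            members += list(rng.choice(non_de, size=size - n_from_de,
                                       replace=False))
            sets[f"TERM_{direction}_{t}"] = sorted(set(members))
    for t in range(n_random_terms):
        size = int(rng.integers(10, 26))
        sets[f"TERM_RAND_{t}"] = sorted(set(
            rng.choice(genes, size=size, replace=False)))
    return sets


def _make_interactions(rng: np.random.Generator, truth: SyntheticTruth,
                       n_bridging: int = 6, n_random: int = 20
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Orthology map, interaction reference, and planted bridging pairs.

    Orthologs pair HGENEi with MGENEi for 90% of indices. The reference is
    written in the human symbol namespace; bridging pairs connect a planted
    human DE gene with the ortholog of a planted mouse DE gene, so the
    crosstalk stage has recoverable signal.
    """
    h_genes = sorted(truth.de_human.index)
    m_genes = sorted(truth.de_mouse.index)
    n = min(len(h_genes), len(m_genes))
    mapped_idx = sorted(rng.choice(n, size=round(0.9 * n), replace=False))
    orthology = pd.DataFrame({
        "human_symbol": [h_genes[i] for i in mapped_idx],
        "mouse_symbol": [m_genes[i] for i in mapped_idx],
    })
    m2h = dict(zip(orthology["mouse_symbol"], orthology["human_symbol"]))

    h_de = truth.de_genes(HUMAN)
    m_de = [g for g in truth.de_genes(MOUSE) if g in m2h]
    pairs: list[tuple[str, str, str]] = []
    bridge_rows = []
    seen = set()
    k = min(n_bridging, len(h_de), len(m_de))
    if k > 0:
        hs = rng.choice(h_de, size=k, replace=False)
        ms = rng.choice(m_de, size=k, replace=False)
        for h, m in zip(hs, ms):
            key = frozenset((h, m2h[m]))
            if key in seen or h == m2h[m]:
                continue
            seen.add(key)
            pairs.append((h, m2h[m], "planted_bridge"))
            bridge_rows.append((h, m))
    for _ in range(n_random * 3):
        if sum(1 for p in pairs if p[2] == "background") >= n_random:
            break
        a, b = rng.choice(h_genes, size=2, replace=False)
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((a, b, "background"))
    interactions = pd.DataFrame(
        pairs, columns=["gene_sym_1", "gene_sym_2", "evidence_tag"])
    bridging = pd.DataFrame(bridge_rows, columns=["human_gene", "mouse_gene"])
    return orthology, interactions, bridging


def generate_bundle(config: SimulationConfig) -> FixtureBundle:
    """Run the full generator: references, experiment, gene sets, reference
    interactions. One call, one seed, fully deterministic."""
    cfg = config.validate()
    refs, xhyb = generate_references(cfg)
    ih, im, sheet, truth = simulate_experiment(cfg, refs, xhyb)
    rng = np.random.default_rng((cfg.seed, 2))
    gene_sets = {
        HUMAN: _make_gene_sets(rng, sorted(truth.de_human.index), truth.de_human),
        MOUSE: _make_gene_sets(rng, sorted(truth.de_mouse.index), truth.de_mouse),
    }
    orthology, interactions, bridging = _make_interactions(rng, truth)
    truth.bridging_pairs = bridging
    return FixtureBundle(
        config=cfg, references=refs, intensities_human=ih,
        intensities_mouse=im, sample_sheet=sheet, truth=truth,
        gene_sets=gene_sets, interactions=interactions, orthology=orthology)


def write_fixture_bundle(bundle: FixtureBundle, directory) -> dict[str, Path]:
    """Write every fixture artifact as plain text; returns the manifest.

    Files round-trip bit-identically through :func:`read_fixture_bundle`.
    """
    import json

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def _p(name: str) -> Path:
        manifest[name] = d / name
        return d / name

    io.write_fasta(bundle.references.transcriptome_human,
                   _p("transcriptome_human.fasta"))
    io.write_fasta(bundle.references.transcriptome_mouse,
                   _p("transcriptome_mouse.fasta"))
    ann = pd.concat([bundle.references.design_human.annotation,
                     bundle.references.design_mouse.annotation],
                    ignore_index=True)
    io.write_table(ann, _p("probe_annotation.tsv"))
    seqs = {**bundle.references.design_human.sequences,
            **bundle.references.design_mouse.sequences}
    io.write_fasta(seqs, _p("probes.fasta"))
    io.write_matrix(bundle.intensities_human, _p("intensities_human.tsv"))
    io.write_matrix(bundle.intensities_mouse, _p("intensities_mouse.tsv"))
    io.write_table(bundle.sample_sheet, _p("sample_sheet.tsv"))
    io.write_table(bundle.truth.de_human.rename("log2fc").rename_axis("gene_id")
                   .reset_index(), _p("truth_de_human.tsv"))
    io.write_table(bundle.truth.de_mouse.rename("log2fc").rename_axis("gene_id")
                   .reset_index(), _p("truth_de_mouse.tsv"))
    io.write_table(bundle.truth.xhyb, _p("truth_xhyb.tsv"))
    io.write_table(bundle.truth.mixing, _p("truth_mixing.tsv"))
    if bundle.truth.bridging_pairs is not None:
        io.write_table(bundle.truth.bridging_pairs, _p("truth_bridging.tsv"))
    io.write_gmt(bundle.gene_sets[HUMAN], _p("gene_sets_human.gmt"))
    io.write_gmt(bundle.gene_sets[MOUSE], _p("gene_sets_mouse.gmt"))
    io.write_table(bundle.interactions, _p("interactions.tsv"))
    io.write_table(bundle.orthology, _p("orthology.tsv"))
    with open(_p("simulation_config.json"), "w") as fh:
        json.dump(bundle.config.to_dict(), fh, indent=2, sort_keys=True)
    return manifest


def read_fixture_bundle(directory) -> FixtureBundle:
    """Load a fixture bundle previously written by :func:`write_fixture_bundle`."""
    import json

    d = Path(directory)
    with open(d / "simulation_config.json") as fh:
        cfg = SimulationConfig.from_dict(json.load(fh))
    ann = io.read_probe_annotation(d / "probe_annotation.tsv")
    seqs = io.read_fasta(d / "probes.fasta")
    designs = {}
    for sp in (HUMAN, MOUSE):
        sub = ann[ann["species"] == sp].reset_index(drop=True)
        designs[sp] = ProbeDesign(sub, {p: seqs[p] for p in sub["probe_id"]})
    refs = References(
        transcriptome_human=io.read_fasta(d / "transcriptome_human.fasta"),
        transcriptome_mouse=io.read_fasta(d / "transcriptome_mouse.fasta"),
        design_human=designs[HUMAN], design_mouse=designs[MOUSE])
    de_h = io.read_table(d / "truth_de_human.tsv").set_index("gene_id")["log2fc"]
    de_m = io.read_table(d / "truth_de_mouse.tsv").set_index("gene_id")["log2fc"]
    bridging_path = d / "truth_bridging.tsv"
    truth = SyntheticTruth(
        de_human=de_h, de_mouse=de_m,
        xhyb=io.read_table(d / "truth_xhyb.tsv"),
        mixing=io.read_table(d / "truth_mixing.tsv",
                             dtype={"line": str, "animal": str}),
        bridging_pairs=io.read_table(bridging_path)
        if bridging_path.exists() else None)
    return FixtureBundle(
        config=cfg, references=refs,
        intensities_human=io.read_matrix(d / "intensities_human.tsv"),
        intensities_mouse=io.read_matrix(d / "intensities_mouse.tsv"),
        sample_sheet=io.read_sample_sheet(d / "sample_sheet.tsv"),
        truth=truth,
        gene_sets={HUMAN: io.read_gmt(d / "gene_sets_human.gmt"),
                   MOUSE: io.read_gmt(d / "gene_sets_mouse.gmt")},
        interactions=io.read_table(d / "interactions.tsv"),
        orthology=io.read_table(d / "orthology.tsv"))
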