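"""Probe-level cross-hybridization scoring and masking.

In a xenograft, region-B (area of invasion) tissue is a mixture of human
tumor cells and mouse host cells, so a human array probe can pick up signal
from homologous mouse transcripts and vice versa. This module scores every
probe against the foreign-species transcriptome, flags probes whose longest
contiguous exact match or best ungapped identity crosses configurable
thresholds, and removes them (dropping probesets left with too few
survivors) so that downstream expression is species-specific.

The matcher is seed-and-extend: exact k-mer seeds (default k=12) anchored at
every probe offset, extended maximally in both directions. Any common
substring of length >= k contains a full probe k-mer, so extension from seed
hits recovers the true longest match for lengths >= k; shorter matches are
found by an exhaustive substring scan, making the reported
``max_contiguous_match`` exact at every length (this equivalence with a
dynamic-programming longest-common-substring oracle is enforced by tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_L_MIN = 15
DEFAULT_I_MIN = 0.75
DEFAULT_MIN_PROBES_PER_SET = 3
DEFAULT_SEED_LENGTH = 12

_RC = str.maketrans("ACGTN", "TGCAN")
_SEP = "#"  # transcript separator; never matches a probe base


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class ProbeDesign:
    """Probe-level array definition: annotation table plus sequences.

    ``annotation`` columns: probe_id, probeset_id, gene_id, species.
    ``sequences`` maps probe_id to its nucleotide sequence.
    """

    annotation: pd.DataFrame
    sequences: dict[str, str]

    def validate(self) -> "ProbeDesign":
        ids = self.annotation["probe_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate probe_ids: {dup[:5]}")
        missing = [p for p in ids if p not in self.sequences]
        if missing:
            raise ValueError(f"probes without sequence: {missing[:5]}")
        for pid in ids:
            seq = self.sequences[pid].upper()
            if set(seq) - set("ACGTN"):
                raise ValueError(
                    f"probe {pid} contains non-ACGTN characters: {seq}")
        if (self.annotation.groupby("probeset_id")["probe_id"].count() < 1).any():
            raise ValueError("every probeset must have >= 1 probe")
        return self

    @property
    def probe_ids(self) -> list[str]:
        return self.annotation["probe_id"].tolist()

    def probesets(self) -> dict[str, list[str]]:
        return {ps: g["probe_id"].tolist()
                for ps, g in self.annotation.groupby("probeset_id", sort=True)}

    def subset(self, species: str) -> "ProbeDesign":
        ann = self.annotation[self.annotation["species"] == species]
        seqs = {p: self.sequences[p] for p in ann["probe_id"]}
        return ProbeDesign(ann.reset_index(drop=True), seqs)


@dataclass
class CrossHybReport:
    """Per-probe cross-hybridization scores and flags.

    ``table`` columns: probe_id, max_contiguous_match (nt), best_identity
    (fraction of identical bases over a full-length ungapped alignment at
    the best seed anchor; 0 when no seed-length exact match exists),
    flagged.
    """

    table: pd.DataFrame
    l_min: int
    i_min: float


@dataclass
class ProbeMask:
    """Exclusion set produced from a :class:`CrossHybReport`."""

    excluded_probes: set[str]
    dropped_probesets: set[str]
    l_min: int
    i_min: float
    min_probes_per_set: int
    # all rows to remove = flagged probes plus every member of dropped sets
    removed_probe_ids: set[str] = field(default_factory=set)
    known_probe_ids: set[str] = field(default_factory=set)


class _ReferenceIndex:
    """k-mer position index over a concatenated transcriptome."""

    def __init__(self, transcriptome: dict[str, str], k: int):
        self.k = k
        self.concat = _SEP.join(s.upper() for s in transcriptome.values())
        index: dict[str, list[int]] = {}
        concat = self.concat
        for j in range(len(concat) - k + 1):
            kmer = concat[j:j + k]
            if _SEP in kmer or "N" in kmer:
                continue
            index.setdefault(kmer, []).append(j)
        self.index = index
        self._mer_sets: dict[int, frozenset[str]] = {}

    def mer_set(self, m: int) -> frozenset[str]:
        """All clean m-mers of the reference (for sub-seed match lengths)."""
        if m not in self._mer_sets:
            concat = self.concat
            mers = {concat[j:j + m] for j in range(len(concat) - m + 1)}
            self._mer_sets[m] = frozenset(
                s for s in mers if _SEP not in s and "N" not in s)
        return self._mer_sets[m]


def _extend(probe: str, concat: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximally extend an exact match seeded at probe[i:i+k] == concat[j:j+k].

    Returns (length, probe_start, ref_start) of the maximal match.
    """
    lo_i, lo_j = i, j
    while lo_i > 0 and lo_j > 0:
        a, b = probe[lo_i - 1], concat[lo_j - 1]
        if a != b or a not in "ACGT":
            break
        lo_i -= 1
        lo_j -= 1
    hi_i, hi_j = i + k, j + k
    n, m = len(probe), len(concat)
    while hi_i < n and hi_j < m:
        a, b = probe[hi_i], concat[hi_j]
        if a != b or a not in "ACGT":
            break
        hi_i += 1
        hi_j += 1
    return hi_i - lo_i, lo_i, lo_j


def _identity_at(probe: str, concat: str, i: int, j: int) -> float:
    """Ungapped full-length identity anchoring probe position i at ref j."""
    start = j - i
    n = len(probe)
    matches = 0
    m = len(concat)
    for t in range(n):
        r = start + t
        if 0 <= r < m:
            a, b = probe[t], concat[r]
            if a == b and a in "ACGT":
                matches += 1
    return matches / n


def _score_one(probe: str, ref: _ReferenceIndex) -> tuple[int, float]:
    """Longest contiguous exact match and best anchored identity, one strand."""
    k = ref.k
    concat = ref.concat
    n = len(probe)
    best_len = 0
    best_ident = 0.0
    ident_diags: set[int] = set()
    runs_by_diag: dict[int, list[tuple[int, int]]] = {}
    for i in range(max(n - k + 1, 0)):
        kmer = probe[i:i + k]
        for j in ref.index.get(kmer, ()):
            diag = j - i
            # full-length ungapped identity depends only on the diagonal
            if diag not in ident_diags:
                ident_diags.add(diag)
                best_ident = max(best_ident, _identity_at(probe, concat, i, j))
            runs = runs_by_diag.setdefault(diag, [])
            if any(lo <= j and j + k <= hi for lo, hi in runs):
                continue  # seed lies inside an already-extended run
            length, _, lo_j = _extend(probe, concat, i, j, k)
            runs.append((lo_j, lo_j + length))
            best_len = max(best_len, length)
    if best_len < k:
        # exhaustive short-match scan keeps max_contiguous_match exact below
        # the seed size; identity stays seed-anchored by definition
        for length in range(min(k - 1, n), 0, -1):
            mers = ref.mer_set(length)
            if any("N" not in (sub := probe[i:i + length]) and sub in mers
                   for i in range(n - length + 1)):
                best_len = length
                break
    return best_len, best_ident


def score_cross_hybridization(
    design: ProbeDesign,
    foreign_transcriptome: dict[str, str],
    l_min: int = DEFAULT_L_MIN,
    i_min: float = DEFAULT_I_MIN,
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> CrossHybReport:
    """Score every probe of ``design`` against the foreign transcriptome.

    Both the probe and its reverse complement are searched, since the
    orientation of cross-species targets is unknown. A probe is flagged when
    ``max_contiguous_match >= l_min`` or ``best_identity >= i_min``.
    """
    if not foreign_transcriptome:
        raise ValueError("foreign transcriptome is empty")
    design.validate()
    if seed_length > l_min:
        raise ValueError(f"seed_length={seed_length} must be <= l_min={l_min}")
    ref = _ReferenceIndex(foreign_transcriptome, seed_length)
    rows = []
    for pid in design.probe_ids:
        seq = design.sequences[pid].upper()
        fwd_len, fwd_id = _score_one(seq, ref)
        rev_len, rev_id = _score_one(reverse_complement(seq), ref)
        max_match = max(fwd_len, rev_len)
        identity = max(fwd_id, rev_id)
        rows.append((pid, max_match, identity,
                     max_match >= l_min or identity >= i_min))
    table = pd.DataFrame(
        rows, columns=["probe_id", "max_contiguous_match", "best_identity",
                       "flagged"])
    return CrossHybReport(table=table, l_min=l_min, i_min=i_min)


def build_mask(
    report: CrossHybReport,
    design: ProbeDesign,
    min_probes_per_set: int = DEFAULT_MIN_PROBES_PER_SET,
) -> ProbeMask:
    """Turn a scoring report into an exclusion set.

    Flagged probes are excluded; probesets left with fewer than
    ``min_probes_per_set`` surviving probes are dropped entirely.
    """
    scored = set(report.table["probe_id"])
    missing = [p for p in design.probe_ids if p not in scored]
    if missing:
        raise ValueError(f"report does not cover probes: {missing[:5]}")
    flagged = set(report.table.loc[report.table["flagged"], "probe_id"])
    dropped: set[str] = set()
    removed = set(flagged)
    for ps, members in design.probesets().items():
        survivors = [p for p in members if p not in flagged]
        if len(survivors) < min_probes_per_set:
            dropped.add(ps)
            removed.update(members)
    return ProbeMask(
        excluded_probes=flagged,
        dropped_probesets=dropped,
        l_min=report.l_min,
        i_min=report.i_min,
        min_probes_per_set=min_probes_per_set,
        removed_probe_ids=removed,
        known_probe_ids=set(design.probe_ids),
    )


def apply_mask(intensities: pd.DataFrame, mask: ProbeMask) -> pd.DataFrame:
    """Remove rows for excluded probes and members of dropped probesets.

    Sample columns are untouched; the operation is idempotent.
    """
    unknown = [p for p in intensities.index if p not in mask.known_probe_ids]
    if unknown:
        raise ValueError(f"unknown probe ids in matrix: {unknown[:10]}")
    keep = [p for p in intensities.index if p not in mask.removed_probe_ids]
    return intensities.loc[keep]
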