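"""Inter-compartment protein–protein crosstalk inference.

The human consensus genes describe the invading tumor cells and the mouse
consensus genes the host microenvironment at the invasion front. A
crosstalk candidate is a pair (human gene, mouse gene) whose protein
products form a known binding pair once the mouse symbol is normalized
into the human namespace through a one-to-one orthology map. Direction of
regulation is annotated, never filtered: receptors up in tumor cells can
meet ligands enriched — or depleted — in the host compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


def _check_bijection(orthology: pd.DataFrame) -> None:
    for col in ("human_symbol", "mouse_symbol"):
        dup = orthology[col][orthology[col].duplicated()]
        if len(dup):
            raise ValueError(
                f"orthology map is not one-to-one: duplicated {col} "
                f"{sorted(set(dup))[:5]}; resolve the map before use")


def normalize_symbols(genes, orthology: pd.DataFrame,
                      source: str = "mouse") -> pd.DataFrame:
    """Map gene symbols across species through the orthology table.

    Returns a frame with columns gene, normalized, mapped. Symbols absent
    from the map are carried through with ``mapped=False`` and are never
    silently matched.
    """
    _check_bijection(orthology)
    if source == "mouse":
        lookup = dict(zip(orthology["mouse_symbol"], orthology["human_symbol"]))
    elif source == "human":
        lookup = dict(zip(orthology["human_symbol"], orthology["mouse_symbol"]))
    else:
        raise ValueError(f"source must be 'human' or 'mouse', got {source!r}")
    rows = [(g, lookup.get(g, g), g in lookup) for g in genes]
    out = pd.DataFrame(rows, columns=["gene", "normalized", "mapped"])
    return out.astype({"mapped": bool})


@dataclass
class CrosstalkCandidates:
    """Nominated tumor–host binding pairs with their DE annotations."""

    table: pd.DataFrame  # human_gene, mouse_gene, evidence_tag, homotypic, directions
    n_human: int
    n_mouse: int


def infer_crosstalk(
    human_genes,
    mouse_genes,
    interactions: pd.DataFrame,
    orthology: pd.DataFrame,
    human_directions: dict | None = None,
    mouse_directions: dict | None = None,
) -> CrosstalkCandidates:
    """All (human gene, mouse gene) pairs backed by a reference interaction.

    A candidate requires the human gene in the human consensus list, the
    mouse gene in the mouse consensus list, and the unordered pair
    {human gene, ortholog(mouse gene)} present in ``interactions`` (columns
    gene_sym_1, gene_sym_2, evidence_tag, human namespace). Mouse genes
    without an ortholog cannot match. Output is deterministic and sorted;
    homotypic pairs (gene binding its own ortholog) are tagged, not removed.
    """
    human_set = set(human_genes)
    norm = normalize_symbols(sorted(set(mouse_genes)), orthology, source="mouse")
    mapped = norm[norm["mapped"]]
    by_human_ns: dict[str, str] = dict(zip(mapped["normalized"], mapped["gene"]))

    # de-duplicate unordered reference pairs, keeping the first evidence tag
    seen: dict[frozenset, str] = {}
    for r in interactions.itertuples():
        key = frozenset((r.gene_sym_1, r.gene_sym_2))
        seen.setdefault(key, r.evidence_tag)

    rows = []
    for key, tag in seen.items():
        pair = sorted(key)
        a, b = (pair[0], pair[-1])
        for h, partner in ((a, b), (b, a)):
            if h in human_set and partner in by_human_ns:
                m = by_human_ns[partner]
                rows.append((h, m, tag, h == partner,
                             (human_directions or {}).get(h, "na"),
                             (mouse_directions or {}).get(m, "na")))
            if a == b:  # homotypic reference pair: single orientation
                break
    table = (pd.DataFrame(
        rows, columns=["human_gene", "mouse_gene", "evidence_tag",
                       "homotypic", "direction_human", "direction_mouse"])
        .drop_duplicates(subset=["human_gene", "mouse_gene"])
        .sort_values(["human_gene", "mouse_gene"])
        .reset_index(drop=True))
    return CrosstalkCandidates(table=table, n_human=len(human_set),
                               n_mouse=len(set(mouse_genes)))
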