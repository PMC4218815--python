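"""Gene-set over-representation with membership-overlap term clustering.

Over-representation is the upper-tail hypergeometric test: for a list of n
genes drawn from a universe of N, a term with K members and k of them in
the list gets p = P(X >= k). Enriched terms are then linked whenever their
membership overlap coefficient |A∩B| / min(|A|,|B|) reaches a threshold
theta; only terms with at least one such partner are reported (singletons
are kept in a side table) and clusters are the connected components of the
overlap graph. This reproduces the common reporting style where a term
must share at least 30% of its genes with another reported category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Term -> member genes, with the gene universe they are tested against."""

    sets: dict[str, set]
    universe: set

    @classmethod
    def from_gmt(cls, gene_sets: dict[str, list[str]],
                 universe) -> "GeneSetCollection":
        uni = set(universe)
        restricted = {t: set(g) & uni for t, g in gene_sets.items()}
        return cls(sets={t: s for t, s in restricted.items() if s},
                   universe=uni)


def enrich(gene_list, collection: GeneSetCollection,
           direction: str = "na") -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in every term.

    Returns one record per term with k >= 1 overlap: term, direction, k,
    K, n, N, p (upper tail), BH q over the returned records, and the
    overlapping gene ids. Genes absent from the universe are an error,
    never silently dropped.
    """
    genes = set(gene_list)
    missing = sorted(genes - collection.universe)
    if missing:
        raise ValueError(f"genes not in universe: {missing[:10]}")
    N, n = len(collection.universe), len(genes)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term]
        K = len(members)
        overlap = sorted(members & genes)
        k = len(overlap)
        if k == 0:
            continue
        p = min(float(hypergeom.sf(k - 1, N, K, n)), 1.0)
        rows.append((term, direction, k, K, n, N, p, ",".join(overlap)))
    df = pd.DataFrame(rows, columns=["term", "direction", "k", "K", "n", "N",
                                     "p", "overlap_genes"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df.sort_values(["p", "term"]).reset_index(drop=True)


def overlap_coefficient(a, b, metric: str = "min") -> float:
    """Membership overlap between two gene sets.

    ``metric="min"`` gives |A∩B| / min(|A|,|B|) (the overlap coefficient);
    ``metric="jaccard"`` gives |A∩B| / |A∪B|.
    """
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap coefficient of an empty set is undefined")
    inter = len(a & b)
    if metric == "min":
        return inter / min(len(a), len(b))
    if metric == "jaccard":
        return inter / len(a | b)
    raise ValueError(f"unknown overlap metric {metric!r}")


@dataclass
class TermClusters:
    """Reported terms (>= 1 overlap partner) and their clusters."""

    report: pd.DataFrame     # enriched records + cluster_id
    singletons: pd.DataFrame  # significant but unpartnered terms
    theta: float
    p_max: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def cluster_and_filter(
    records: pd.DataFrame,
    collection: GeneSetCollection,
    theta: float = 0.30,
    p_max: float = 0.05,
    metric: str = "min",
) -> TermClusters:
    """Cluster significant terms by membership overlap and filter singletons.

    Keeps records with p <= p_max, draws an edge between two terms when
    their overlap coefficient >= theta, reports only terms with degree >= 1
    and labels connected components with a cluster_id. Raising theta can
    only refine clusters, never grow them.
    """
    sig = records[records["p"] <= p_max].copy()
    terms = sig["term"].tolist()
    g = nx.Graph()
    g.add_nodes_from(terms)
    pair_rows = []
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1:]:
            ov = overlap_coefficient(collection.sets[t1], collection.sets[t2],
                                     metric=metric)
            pair_rows.append((t1, t2, ov))
            if ov >= theta:
                g.add_edge(t1, t2)
    reported_terms = {t for t in terms if g.degree[t] >= 1}
    cluster_id = {}
    for cid, comp in enumerate(
            sorted(nx.connected_components(g.subgraph(reported_terms)),
                   key=lambda c: sorted(c)[0])):
        for t in comp:
            cluster_id[t] = cid
    report = sig[sig["term"].isin(reported_terms)].copy()
    report["cluster_id"] = report["term"].map(cluster_id)
    singletons = sig[~sig["term"].isin(reported_terms)].copy()
    return TermClusters(
        report=report.reset_index(drop=True),
        singletons=singletons.reset_index(drop=True),
        theta=theta, p_max=p_max,
        pairwise=pd.DataFrame(pair_rows,
                              columns=["term_a", "term_b", "overlap"]))
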