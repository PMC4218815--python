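"""Region-contrast differential expression, cross-line consensus and the
sample-clustering diagnostic.

Each species' compartment has one contrast: invading tumor cells are
region B vs A on human arrays, the host microenvironment is region B vs C
on mouse arrays. The per-gene test is a two-sided Welch t on log2
expression with Benjamini–Hochberg adjustment within the contrast. The
consensus list keeps genes significant — by default at raw p < alpha, with
the same direction — in both tumor lines, mirroring how replicate
xenograft lines are combined into a single differentially-expressed-gene
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

CONTRASTS = {"B-vs-A": ("B", "A"), "B-vs-C": ("B", "C")}


@dataclass
class DEResult:
    """Per-gene statistics for one line's region contrast."""

    table: pd.DataFrame  # index gene; log2fc, t, p, q, direction
    line: str
    species: str
    contrast: str


@dataclass
class ConsensusDEGs:
    """Genes significant in both lines under the selection rule."""

    table: pd.DataFrame  # index gene; per-line log2fc/p/q + direction
    species: str
    contrast: str
    alpha: float
    require_same_direction: bool
    use_adjusted_p: bool

    @property
    def genes(self) -> list[str]:
        return self.table.index.tolist()


def _direction(lfc: np.ndarray) -> np.ndarray:
    return np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))


def contrast(
    expression: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    contrast_spec: str,
    species: str,
    line: str,
) -> DEResult:
    """Welch two-sample t per gene for one line's region contrast.

    log2FC = mean(region B) − mean(reference region). Genes with zero
    variance in both groups and equal means get p = 1 (an undefined t is
    treated as no evidence against the null).
    """
    if contrast_spec not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast_spec!r}; "
                         f"expected one of {sorted(CONTRASTS)}")
    test_region, ref_region = CONTRASTS[contrast_spec]
    sel = sample_sheet[(sample_sheet["array_species"] == species)
                       & (sample_sheet["line"] == line)]
    groups = {}
    for region in (test_region, ref_region):
        ids = sel.loc[sel["region"] == region, "sample_id"].tolist()
        ids = [s for s in ids if s in expression.columns]
        if len(ids) < 2:
            raise ValueError(
                f"group line={line} region={region} species={species} has "
                f"{len(ids)} samples; need >= 2")
        groups[region] = expression[ids].to_numpy(dtype=float)
    a, b = groups[test_region], groups[ref_region]
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # constant genes yield nan t/p (handled below); silence the
        # catastrophic-cancellation warning they trigger
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2fc": lfc, "t": t, "p": p, "q": q, "direction": _direction(lfc)},
        index=expression.index)
    table.index.name = "gene"
    return DEResult(table=table, line=line, species=species,
                    contrast=contrast_spec)


def intersect_lines(
    de1: DEResult,
    de2: DEResult,
    alpha: float = 0.05,
    require_same_direction: bool = True,
    use_adjusted_p: bool = False,
) -> ConsensusDEGs:
    """Cross-line intersection: genes significant in BOTH lines.

    Uses raw p by default (``use_adjusted_p`` switches to BH q) and, if
    requested, the same fold-change direction in both lines.
    """
    if de1.species != de2.species or de1.contrast != de2.contrast:
        raise ValueError(
            f"cannot intersect {de1.species}/{de1.contrast} with "
            f"{de2.species}/{de2.contrast}: metadata mismatch")
    col = "q" if use_adjusted_p else "p"
    shared = de1.table.index.intersection(de2.table.index)
    t1, t2 = de1.table.loc[shared], de2.table.loc[shared]
    keep = (t1[col] < alpha) & (t2[col] < alpha)
    if require_same_direction:
        keep &= (t1["direction"] == t2["direction"]) & (t1["direction"] != "none")
    table = pd.DataFrame({
        f"log2fc_{de1.line}": t1["log2fc"], f"p_{de1.line}": t1["p"],
        f"q_{de1.line}": t1["q"],
        f"log2fc_{de2.line}": t2["log2fc"], f"p_{de2.line}": t2["p"],
        f"q_{de2.line}": t2["q"],
        "direction": t1["direction"],
    })[keep.to_numpy()]
    table["mean_log2fc"] = (table[f"log2fc_{de1.line}"]
                            + table[f"log2fc_{de2.line}"]) / 2
    return ConsensusDEGs(
        table=table.sort_index(), species=de1.species, contrast=de1.contrast,
        alpha=alpha, require_same_direction=require_same_direction,
        use_adjusted_p=use_adjusted_p)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


@dataclass
class ClusteringDiagnostic:
    """Two-group cut of an average-linkage (1 − Pearson) dendrogram."""

    newick: str
    cluster_labels: pd.Series  # sample -> 1/2
    ari: float  # adjusted Rand index vs. the true region labels
    perfect_separation: bool


def cluster_samples(
    expression: pd.DataFrame,
    region_labels: pd.Series,
    linkage: str = "average",
) -> ClusteringDiagnostic:
    """Hierarchical clustering of samples on (1 − Pearson) distance.

    Mirrors the standard array QC: with expression restricted to the
    consensus genes, samples should segregate by region when the contrast
    is real. Constant-expression rows are dropped with a warning
    (correlation is undefined for them).
    """
    if expression.shape[1] < 2 or expression.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 genes for clustering")
    const = expression.std(axis=1) == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant-expression rows")
        expression = expression[~const]
        if expression.shape[0] < 2:
            raise ValueError("fewer than 2 variable genes remain")
    dist = pdist(expression.to_numpy().T, metric="correlation")
    Z = hierarchy.linkage(dist, method=linkage)
    flat = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    labels = region_labels.loc[expression.columns]
    ari = adjusted_rand_score(labels.to_numpy(), flat)
    return ClusteringDiagnostic(
        newick=_linkage_to_newick(Z, list(expression.columns)),
        cluster_labels=pd.Series(flat, index=expression.columns),
        ari=float(ari),
        perfect_separation=bool(np.isclose(ari, 1.0)))
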