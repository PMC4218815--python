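"""Cross-platform validation against a count-based (NanoString-like) assay.

The count platform measures a selected gene panel with species-specific
probes, so region-B counts carry no cross-species leakage by design.
Counts are simulated as negative binomial with mean proportional to the
planted raw-scale expression, normalized by the geometric mean of
housekeeping genes, and tested with the same Welch t on
log2(normalized + 1) as the array stage so fold changes are comparable.
Concordance is summarized as sign agreement, Spearman correlation of the
log2 fold changes, and the validated proportion (significant on the count
platform with matching sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEResult, contrast
from .simulate import HUMAN, SyntheticTruth


def simulate_count_platform(
    truth: SyntheticTruth,
    genes,
    species: str,
    sample_sheet: pd.DataFrame,
    housekeeping_genes=(),
    dispersion: float = 0.05,
    depth: float = 5e4,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial counts for a gene panel, species-pure in region B.

    Mean count is ``size_factor x 2^(baseline + planted log2FC in B)``
    scaled to ``depth`` reads per sample; ``dispersion`` is the NB
    overdispersion (variance = m + dispersion·m²), with the Poisson limit
    taken below 1e-8. Housekeeping genes carry no planted fold change and
    anchor the normalization.
    """
    genes = list(genes)
    panel = genes + [g for g in housekeeping_genes if g not in genes]
    lfc = truth.de_series(species)
    baselines = truth.baselines.get(species)
    unknown = [g for g in panel if g not in lfc.index]
    if unknown:
        raise ValueError(f"panel genes not in truth: {unknown[:10]}")
    if baselines is None:
        baselines = pd.Series(8.0, index=lfc.index)
    regions = ("A", "B") if species == HUMAN else ("B", "C")
    sel = sample_sheet[(sample_sheet["array_species"] == species)
                       & (sample_sheet["region"].isin(regions))]
    rng = np.random.default_rng(seed)
    base = np.exp2(baselines[panel].to_numpy())
    eff = np.exp2(lfc[panel].to_numpy())
    # fixed scale: counts track absolute transcript abundance (times a
    # per-sample lane factor), so planted fold changes survive in raw counts
    scale = depth / base.sum()
    data = {}
    for row in sel.itertuples():
        mu = base * (eff if row.region == "B" else 1.0)
        size_factor = float(rng.lognormal(mean=0.0, sigma=0.3))
        mu = mu * scale * size_factor
        if dispersion < 1e-8:
            counts = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        data[row.sample_id] = counts
    out = pd.DataFrame(data, index=panel)
    out.index.name = "gene"
    return out


def housekeeping_normalize(counts: pd.DataFrame,
                           housekeeping_genes) -> pd.DataFrame:
    """Scale samples by the geometric mean of their housekeeping counts.

    Invariant to multiplying all counts of one sample by a constant.
    """
    hk = [g for g in housekeeping_genes if g in counts.index]
    if not hk:
        raise ValueError("no housekeeping genes present in the count table")
    # floor at 1 keeps the geometric mean defined at zero counts while the
    # normalization stays exactly scale-equivariant for counts >= 1
    gm = np.exp(np.log(np.maximum(counts.loc[hk].to_numpy(), 1.0)).mean(axis=0))
    factors = gm / np.exp(np.mean(np.log(gm)))
    return counts / factors


def count_contrast(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    species: str,
    line: str,
    housekeeping_genes,
) -> DEResult:
    """Welch t on log2(housekeeping-normalized counts + 1) for one line."""
    norm = housekeeping_normalize(counts, housekeeping_genes)
    expr = np.log2(norm + 1.0)
    spec = "B-vs-A" if species == HUMAN else "B-vs-C"
    res = contrast(expr, sample_sheet, spec, species, line)
    res.table = res.table.drop(index=[g for g in housekeeping_genes
                                      if g in res.table.index])
    return res


@dataclass
class ConcordanceReport:
    """Gene-level fold-change agreement between two platforms."""

    table: pd.DataFrame  # gene, log2fc_1, log2fc_2, p_2, sign_agree, validated
    sign_agreement: float
    spearman: float
    validated_proportion: float
    alpha: float


def compare_platforms(
    de_platform1: pd.DataFrame,
    de_platform2: pd.DataFrame,
    alpha: float = 0.05,
) -> ConcordanceReport:
    """Concordance of per-gene log2 fold changes across two platforms.

    ``de_platform*`` are gene-indexed frames with at least ``log2fc``;
    platform 2 additionally needs ``p`` for the validated proportion
    (fraction of genes significant on platform 2 with the same sign).
    """
    shared = de_platform1.index.intersection(de_platform2.index)
    if len(shared) == 0:
        raise ValueError("platforms share no genes")
    lfc1 = de_platform1.loc[shared, "log2fc"].to_numpy(dtype=float)
    lfc2 = de_platform2.loc[shared, "log2fc"].to_numpy(dtype=float)
    p2 = (de_platform2.loc[shared, "p"].to_numpy(dtype=float)
          if "p" in de_platform2.columns else np.zeros(len(shared)))
    sign_agree = np.sign(lfc1) == np.sign(lfc2)
    validated = sign_agree & (p2 < alpha)
    rho = float(stats.spearmanr(lfc1, lfc2).statistic) if len(shared) > 1 else 1.0
    table = pd.DataFrame({
        "log2fc_platform1": lfc1, "log2fc_platform2": lfc2, "p_platform2": p2,
        "sign_agree": sign_agree, "validated": validated}, index=shared)
    return ConcordanceReport(
        table=table,
        sign_agreement=float(sign_agree.mean()),
        spearman=rho,
        validated_proportion=float(validated.mean()),
        alpha=alpha)
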