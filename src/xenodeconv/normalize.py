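"""Normalization and probeset summarization of masked probe intensities.

Quantile normalization forces every sample column onto the identical value
multiset — this is also what removes the global log2 shift that the
region-B compartment fraction imposes on every probe of a mixed sample.
Summarization collapses the surviving probes of each probeset to one
expression value per sample: the probe-wise median by default, or the
sample effects fitted by Tukey median polish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .masking import ProbeDesign


@dataclass
class ExpressionMatrix:
    """Probeset/gene-level log2 expression with provenance."""

    data: pd.DataFrame  # probesets (or genes) x samples
    provenance: dict[str, Any] = field(default_factory=dict)


def quantile_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one distribution.

    Ties within a column receive the mean of the reference values at the
    tied ranks. Requires at least two samples and strictly positive
    (log2-scale microarray) intensities.
    """
    if intensities.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    if not np.isfinite(intensities.to_numpy()).all():
        raise ValueError("intensities contain non-finite values")
    if (intensities.to_numpy() <= 0).any():
        raise ValueError("intensities must be positive")
    X = intensities.to_numpy(dtype=float)
    n, _ = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for c in range(X.shape[1]):
        col = X[:, c]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # exact tie handling: average assigned reference values over ties
        s = pd.Series(assigned)
        out[:, c] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=intensities.index,
                        columns=intensities.columns)


def scale_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Global median scaling: center every column median on the grand median.

    A rank-free alternative to quantile normalization: it removes global
    per-sample shifts (labeling, loading, and the compartment-fraction
    shift of mixed samples) without matching full distributions, so genes
    with real regional fold changes cannot drag null genes' mapped values
    with them. Preferred when a substantial fraction of features is truly
    differential.
    """
    if intensities.shape[1] < 2:
        raise ValueError("normalization requires >= 2 samples")
    med = intensities.median(axis=0)
    return intensities - med + med.mean()


def reference_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Median-of-log-ratios normalization against a pseudo-reference.

    Each sample's offset is the median, over probes, of its log2 ratio to
    the row-median pseudo-reference profile; subtracting it removes global
    per-sample shifts, including the compartment-fraction shift of mixed
    samples. Because the ratios of non-differential probes concentrate
    tightly around the offset, the estimate tolerates a sizable fraction of
    truly differential probes without the median drift that plain column
    centering suffers — the same robustness argument behind
    median-of-ratios size factors for count data.
    """
    if intensities.shape[1] < 2:
        raise ValueError("normalization requires >= 2 samples")
    ref = intensities.median(axis=1)
    offsets = intensities.sub(ref, axis=0).median(axis=0)
    return intensities - offsets


def median_polish(table: np.ndarray, max_iter: int = 20,
                  tol: float = 1e-8) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D table.

    Returns (overall, row_effects, col_effects, residuals) with the usual
    alternating row/column median sweeps.
    """
    resid = np.asarray(table, dtype=float).copy()
    nr, nc = resid.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        cmed_r = np.median(row)
        row -= cmed_r
        overall += cmed_r
        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        rmed_c = np.median(col)
        col -= rmed_c
        overall += rmed_c
        if abs(rmed).max(initial=0) < tol and abs(cmed).max(initial=0) < tol:
            break
    return overall, row, col, resid


def summarize_probesets(
    normalized: pd.DataFrame,
    design: ProbeDesign,
    method: str = "median",
) -> ExpressionMatrix:
    """Collapse probe rows to one row per probeset.

    ``method``: "median" (per-sample median over member probes) or
    "medianpolish" (overall + fitted sample effects). Probe-row order has
    no influence on either summary.
    """
    ann = design.annotation.set_index("probe_id")
    unknown = [p for p in normalized.index if p not in ann.index]
    if unknown:
        raise ValueError(f"matrix rows not in design: {unknown[:10]}")
    probeset_of = ann.loc[normalized.index, "probeset_id"]
    if method == "median":
        data = normalized.groupby(probeset_of, sort=True).median()
        data.index.name = "probeset_id"
    elif method == "medianpolish":
        rows = {}
        for ps, grp in normalized.groupby(probeset_of, sort=True):
            overall, _, col_eff, _ = median_polish(grp.to_numpy())
            rows[ps] = overall + col_eff
        data = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=normalized.columns)
        data.index.name = "probeset_id"
    else:
        raise ValueError(f"unknown summarization method: {method!r}")
    return ExpressionMatrix(
        data=data,
        provenance={"summarization": method, "background_correction": "none"})


def to_gene_level(expr: ExpressionMatrix, design: ProbeDesign) -> ExpressionMatrix:
    """Re-index probeset rows by their gene (one probeset per gene here)."""
    mapping = (design.annotation[["probeset_id", "gene_id"]]
               .drop_duplicates().set_index("probeset_id")["gene_id"])
    counts = mapping.groupby(mapping).size()
    if (counts > 1).any():
        raise ValueError("gene-level re-indexing requires one probeset per gene")
    data = expr.data.rename(index=mapping.to_dict())
    data.index.name = "gene_id"
    return ExpressionMatrix(data=data, provenance=dict(expr.provenance))
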