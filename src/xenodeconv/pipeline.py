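"""End-to-end orchestration: simulate → mask → summarize → DE → consensus →
enrichment → crosstalk → concordance, from one declarative configuration.

Every stage writes its outputs as plain text under the run directory and
records counts, parameters and wall time in a machine-readable run report.
Reruns with the same configuration and seed reproduce identical outputs
(timestamps excepted).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io
from .concordance import (compare_platforms, count_contrast,
                          simulate_count_platform)
from .config import RunConfig, SimulationConfig
from .crosstalk import infer_crosstalk
from .de import cluster_samples, contrast, intersect_lines
from .enrichment import GeneSetCollection, cluster_and_filter, enrich
from .masking import apply_mask, build_mask, score_cross_hybridization
from .normalize import (quantile_normalize, reference_normalize,
                        scale_normalize, summarize_probesets, to_gene_level)
from .simulate import (HUMAN, MOUSE, FixtureBundle, generate_bundle,
                       read_fixture_bundle, write_fixture_bundle)

log = logging.getLogger("xenodeconv")


@dataclass
class RunReport:
    """Per-stage record of outputs, parameters and counts for one run."""

    config: dict[str, Any]
    seed: int
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def add(self, name: str, started: float, **payload: Any) -> None:
        self.stages[name] = {"wall_time_s": round(time.perf_counter() - started, 3),
                             **payload}

    def payload(self, include_timings: bool = True) -> dict[str, Any]:
        stages = {k: dict(v) for k, v in self.stages.items()}
        if not include_timings:
            for v in stages.values():
                v.pop("wall_time_s", None)
        return {"config": self.config, "seed": self.seed, "stages": stages}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.payload(), fh, indent=2, sort_keys=True)


def validate_config(cfg: RunConfig) -> list[str]:
    """Check every cross-field constraint; returns ALL violations."""
    errs: list[str] = []
    try:
        cfg.simulation.validate()
    except Exception as e:  # ConfigurationError carries the full list
        errs.extend(getattr(e, "violations", [str(e)]))
    if not cfg.simulate:
        if cfg.input_dir is None:
            errs.append("input_dir is required when simulate is false")
        elif not Path(cfg.input_dir).is_dir():
            errs.append(f"input_dir {cfg.input_dir!r} does not exist")
    if not (0 < cfg.l_min <= cfg.simulation.probe_length):
        errs.append(f"l_min={cfg.l_min} must lie in (0, probe_length]")
    if not 0.0 <= cfg.i_min <= 1.0:
        errs.append(f"i_min={cfg.i_min} must lie in [0, 1]")
    if cfg.min_probes_per_set < 1:
        errs.append("min_probes_per_set must be >= 1")
    if not 0.0 < cfg.alpha < 1.0:
        errs.append(f"alpha={cfg.alpha} must lie in (0, 1)")
    if not 0.0 <= cfg.theta <= 1.0:
        errs.append(f"theta={cfg.theta} must lie in [0, 1]")
    if not 0.0 < cfg.p_max <= 1.0:
        errs.append(f"p_max={cfg.p_max} must lie in (0, 1]")
    if cfg.summarization_method not in ("median", "medianpolish"):
        errs.append(f"unknown summarization_method {cfg.summarization_method!r}")
    if cfg.normalization not in ("reference", "scale", "quantile"):
        errs.append(f"unknown normalization {cfg.normalization!r}")
    if cfg.overlap_metric not in ("min", "jaccard"):
        errs.append(f"unknown overlap_metric {cfg.overlap_metric!r}")
    if cfg.n_panel_genes < 2:
        errs.append("n_panel_genes must be >= 2")
    if cfg.count_dispersion < 0:
        errs.append("count_dispersion must be >= 0")
    return errs


def _lines(sheet: pd.DataFrame) -> list[str]:
    return sorted(sheet["line"].unique())


def mask_species(bundle: FixtureBundle, species: str, l_min: int,
                 i_min: float, min_probes_per_set: int):
    """Score one species' probes against the other species' transcriptome."""
    foreign = MOUSE if species == HUMAN else HUMAN
    design = bundle.references.design(species)
    report = score_cross_hybridization(
        design, bundle.references.transcriptome(foreign),
        l_min=l_min, i_min=i_min)
    mask = build_mask(report, design, min_probes_per_set=min_probes_per_set)
    return report, mask


_NORMALIZERS = {"reference": reference_normalize, "scale": scale_normalize,
                "quantile": quantile_normalize}


def expression_for_species(bundle: FixtureBundle, species: str, mask=None,
                           method: str = "median",
                           normalization: str = "reference") -> pd.DataFrame:
    """Masked (optional), normalized, gene-level log2 expression."""
    intens = bundle.intensities(species)
    design = bundle.references.design(species)
    if mask is not None:
        intens = apply_mask(intens, mask)
    try:
        norm = _NORMALIZERS[normalization](intens)
    except KeyError:
        raise ValueError(f"unknown normalization {normalization!r}") from None
    expr = summarize_probesets(norm, design, method=method)
    expr.provenance["normalization"] = normalization
    return to_gene_level(expr, design).data


def run_pipeline(cfg: RunConfig, out_dir=None) -> RunReport:
    """Execute the full two-compartment analysis; returns the run report."""
    errs = validate_config(cfg)
    if errs:
        raise ValueError("invalid configuration: " + "; ".join(errs))
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg.to_dict(), seed=cfg.seed)

    # --- fixture -----------------------------------------------------------
    t0 = time.perf_counter()
    if cfg.simulate:
        sim_cfg = SimulationConfig.from_dict(
            {**cfg.simulation.to_dict(), "seed": cfg.seed})
        bundle = generate_bundle(sim_cfg)
        manifest = write_fixture_bundle(bundle, out / "bundle")
        report.add("simulate", t0, n_samples=len(bundle.sample_sheet),
                   n_genes_per_species=sim_cfg.n_genes_per_species,
                   outputs=sorted(str(p.relative_to(out))
                                  for p in manifest.values()))
        log.info("simulated bundle with %d array samples",
                 len(bundle.sample_sheet))
    else:
        bundle = read_fixture_bundle(cfg.input_dir)
        report.add("load", t0, input_dir=str(cfg.input_dir),
                   n_samples=len(bundle.sample_sheet))

    consensus = {}
    de_tables = {}
    expr_gene = {}
    lines = _lines(bundle.sample_sheet)
    for species in (HUMAN, MOUSE):
        # --- masking -------------------------------------------------------
        t0 = time.perf_counter()
        xreport, mask = mask_species(bundle, species, cfg.l_min, cfg.i_min,
                                     cfg.min_probes_per_set)
        mask_dir = out / "mask"
        mask_dir.mkdir(exist_ok=True)
        io.write_table(xreport.table, mask_dir / f"crosshyb_{species}.tsv")
        io.write_table(
            pd.DataFrame({"probeset_id": sorted(mask.dropped_probesets)}),
            mask_dir / f"dropped_probesets_{species}.tsv")
        report.add(f"mask_{species}", t0,
                   probes_flagged=len(mask.excluded_probes),
                   probesets_dropped=len(mask.dropped_probesets),
                   l_min=cfg.l_min, i_min=cfg.i_min)
        log.info("%s: %d probes flagged, %d probesets dropped", species,
                 len(mask.excluded_probes), len(mask.dropped_probesets))

        # --- normalize + summarize ----------------------------------------
        t0 = time.perf_counter()
        expr = expression_for_species(bundle, species, mask,
                                      cfg.summarization_method,
                                      cfg.normalization)
        expr_gene[species] = expr
        expr_dir = out / "expression"
        expr_dir.mkdir(exist_ok=True)
        io.write_matrix(expr, expr_dir / f"expression_{species}.tsv")
        report.add(f"summarize_{species}", t0, n_genes=expr.shape[0],
                   method=cfg.summarization_method)

        # --- differential expression + consensus --------------------------
        t0 = time.perf_counter()
        spec = "B-vs-A" if species == HUMAN else "B-vs-C"
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        per_line = []
        for line in lines:
            res = contrast(expr, bundle.sample_sheet, spec, species, line)
            per_line.append(res)
            io.write_table(res.table.reset_index(),
                           de_dir / f"de_{species}_{line}.tsv")
        cons = intersect_lines(per_line[0], per_line[1], alpha=cfg.alpha,
                               require_same_direction=cfg.require_same_direction,
                               use_adjusted_p=cfg.use_adjusted_p)
        consensus[species] = cons
        de_tables[species] = per_line
        io.write_table(cons.table.reset_index(names="gene"),
                       de_dir / f"consensus_{species}.tsv")
        report.add(f"de_{species}", t0, contrast=spec,
                   degs_per_line={r.line: int((r.table["p"] < cfg.alpha).sum())
                                  for r in per_line},
                   consensus_size=len(cons.table))
        log.info("%s consensus: %d genes", species, len(cons.table))

    # --- clustering diagnostic (human arrays, consensus genes) -------------
    t0 = time.perf_counter()
    diag_payload = {}
    for species in (HUMAN, MOUSE):
        genes = [g for g in consensus[species].genes
                 if g in expr_gene[species].index]
        if len(genes) >= 2:
            sheet = bundle.sample_sheet
            cols = sheet.loc[sheet["array_species"] == species, "sample_id"]
            sub = expr_gene[species][list(cols)]
            labels = sheet.set_index("sample_id").loc[sub.columns, "region"]
            diag = cluster_samples(sub.loc[genes], labels)
            (out / "clustering").mkdir(exist_ok=True)
            with open(out / "clustering" / f"dendrogram_{species}.nwk", "w") as fh:
                fh.write(diag.newick + "\n")
            diag_payload[species] = {"ari": diag.ari,
                                     "perfect": diag.perfect_separation}
    report.add("clustering", t0, **diag_payload)

    # --- enrichment ---------------------------------------------------------
    t0 = time.perf_counter()
    enr_counts = {}
    for species in (HUMAN, MOUSE):
        universe = list(expr_gene[species].index)
        coll = GeneSetCollection.from_gmt(bundle.gene_sets[species], universe)
        cons = consensus[species]
        frames = []
        for direction in ("up", "down"):
            genes = [g for g in cons.genes
                     if cons.table.loc[g, "direction"] == direction
                     and g in coll.universe]
            if genes:
                frames.append(enrich(genes, coll, direction=direction))
        records = (pd.concat(frames, ignore_index=True) if frames
                   else pd.DataFrame(columns=["term", "direction", "k", "K",
                                              "n", "N", "p", "overlap_genes",
                                              "q"]))
        clusters = cluster_and_filter(records, coll, theta=cfg.theta,
                                      p_max=cfg.p_max, metric=cfg.overlap_metric)
        enr_dir = out / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        io.write_table(clusters.report, enr_dir / f"terms_{species}.tsv")
        io.write_table(clusters.singletons,
                       enr_dir / f"singletons_{species}.tsv")
        enr_counts[species] = {"reported_terms": len(clusters.report),
                               "singletons": len(clusters.singletons)}
    report.add("enrichment", t0, **enr_counts)

    # --- crosstalk ----------------------------------------------------------
    t0 = time.perf_counter()
    h_cons, m_cons = consensus[HUMAN], consensus[MOUSE]
    candidates = infer_crosstalk(
        h_cons.genes, m_cons.genes, bundle.interactions, bundle.orthology,
        human_directions=dict(h_cons.table["direction"]),
        mouse_directions=dict(m_cons.table["direction"]))
    (out / "crosstalk").mkdir(exist_ok=True)
    io.write_table(candidates.table, out / "crosstalk" / "candidates.tsv")
    report.add("crosstalk", t0, n_candidates=len(candidates.table))
    log.info("crosstalk: %d candidate pairs", len(candidates.table))

    # --- concordance --------------------------------------------------------
    t0 = time.perf_counter()
    conc_payload = {}
    rng = np.random.default_rng((cfg.seed, 3))
    for species in (HUMAN, MOUSE):
        cons = consensus[species]
        ranked = cons.table["mean_log2fc"].abs().sort_values(ascending=False)
        panel = list(ranked.index[:cfg.n_panel_genes])
        if len(panel) < 2:
            conc_payload[species] = {"skipped": "consensus too small"}
            continue
        lfc = bundle.truth.de_series(species)
        hk = [g for g in lfc.index if lfc[g] == 0 and g not in panel][:5]
        counts = simulate_count_platform(
            bundle.truth, panel, species, bundle.sample_sheet,
            housekeeping_genes=hk, dispersion=cfg.count_dispersion,
            depth=cfg.count_depth, seed=int(rng.integers(2**31)))
        (out / "concordance").mkdir(exist_ok=True)
        io.write_matrix(counts, out / "concordance" / f"counts_{species}.tsv")
        validated = []
        for i, line in enumerate(lines):
            count_de = count_contrast(counts, bundle.sample_sheet, species,
                                      line, hk)
            array_de = de_tables[species][i].table.loc[panel]
            rep = compare_platforms(array_de, count_de.table, alpha=cfg.alpha)
            validated.append(rep)
            io.write_table(
                rep.table.reset_index(names="gene"),
                out / "concordance" / f"concordance_{species}_{line}.tsv")
        conc_payload[species] = {
            "panel_size": len(panel),
            "sign_agreement": round(float(np.mean(
                [r.sign_agreement for r in validated])), 4),
            "validated_proportion": round(float(np.mean(
                [r.validated_proportion for r in validated])), 4),
        }
    report.add("concordance", t0, **conc_payload)

    report.write(out / "run_report.json")
    return report
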