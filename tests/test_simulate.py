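"""Generator invariants: design counts, planted truth, determinism, leakage."""

import numpy as np
import pandas as pd
import pytest

from xenodeconv import (ConfigurationError, SimulationConfig,
                        generate_bundle, generate_references,
                        read_fixture_bundle, simulate_experiment,
                        write_fixture_bundle)
from xenodeconv.simulate import HUMAN, MOUSE

from .oracles import substring_match_count


def test_probes_are_substrings_of_own_transcript(small_bundle):
    for sp in (HUMAN, MOUSE):
        design = small_bundle.references.design(sp)
        tx = small_bundle.references.transcriptome(sp)
        for r in design.annotation.itertuples():
            assert design.sequences[r.probe_id] in tx[f"{r.gene_id}_tx"]


def test_no_implants_requested_means_empty_truth():
    cfg = SimulationConfig(n_genes_per_species=20, probes_per_set=4,
                           transcript_length=160, frac_xhyb_probes=0.0, seed=3)
    _, xhyb = generate_references(cfg)
    assert len(xhyb) == 0


def test_implant_count_matches_brute_force_substring_oracle(small_config):
    """round(frac * n_probes) implants per species, each verified by
    exhaustive substring search against the foreign reference."""
    refs, xhyb = generate_references(small_config)
    n_probes = small_config.n_genes_per_species * small_config.probes_per_set
    expected = round(small_config.frac_xhyb_probes * n_probes)
    for sp, foreign_sp in ((HUMAN, MOUSE), (MOUSE, HUMAN)):
        planted = set(xhyb.loc[xhyb["species"] == sp, "probe_id"])
        assert len(planted) == expected
        reference = "#".join(refs.transcriptome(foreign_sp).values())
        found = substring_match_count(refs.design(sp).sequences, reference,
                                      small_config.xhyb_match_min)
        assert found == planted


def test_generator_is_deterministic(tmp_path, small_config):
    b1 = generate_bundle(small_config)
    b2 = generate_bundle(small_config)
    write_fixture_bundle(b1, tmp_path / "a")
    write_fixture_bundle(b2, tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


def test_sample_sheet_matches_design(default_bundle):
    """2 lines x 4 animals x (A + C + dual-hybridized B) = 32 array samples."""
    sheet = default_bundle.sample_sheet
    assert len(sheet) == 32
    counts = sheet.groupby(["region", "array_species"]).size()
    assert counts[("A", "human")] == 8
    assert counts[("B", "human")] == 8
    assert counts[("B", "mouse")] == 8
    assert counts[("C", "mouse")] == 8
    assert ("A", "mouse") not in counts and ("C", "human") not in counts
    # every region-B tissue appears on both arrays
    b = sheet[sheet["region"] == "B"]
    per_tissue = b.groupby(["line", "animal"])["array_species"].nunique()
    assert (per_tissue == 2).all()


def test_noiseless_pure_limit_recovers_planted_log2fc():
    cfg = SimulationConfig(n_genes_per_species=30, probes_per_set=4,
                           transcript_length=160, noise_sd=1e-9,
                           mixing_fraction_b=1.0, mixing_jitter_sd=0.0,
                           xhyb_coupling=0.0, seed=5)
    refs, xhyb = generate_references(cfg)
    ih, _, sheet, truth = simulate_experiment(cfg, refs, xhyb)
    b = sheet.query("array_species=='human' and region=='B'").sample_id
    a = sheet.query("array_species=='human' and region=='A'").sample_id
    gene_of = refs.design_human.annotation.set_index("probe_id")["gene_id"]
    est = (ih[list(b)].mean(1) - ih[list(a)].mean(1)).groupby(gene_of).mean()
    assert np.allclose(est, truth.de_human[est.index], atol=1e-6)


def test_zero_coupling_removes_leakage():
    """With kappa=0, implanted probes' region-B residuals are
    indistinguishable from clean probes' (paired on planted truth)."""
    cfg = SimulationConfig(seed=7, xhyb_coupling=0.0)
    bundle = generate_bundle(cfg)
    resid = _region_b_residuals(bundle, MOUSE)
    implanted = set(bundle.truth.xhyb.query("species=='mouse'").probe_id)
    r_imp = resid[resid.index.isin(implanted)]
    r_clean = resid[~resid.index.isin(implanted)]
    # equal means within Monte-Carlo error of the planted noise model
    se = np.sqrt(r_imp.var() / len(r_imp) + r_clean.var() / len(r_clean))
    assert abs(r_imp.mean() - r_clean.mean()) < 4 * se


def test_leakage_is_local_to_implanted_probes(default_bundle):
    """With kappa>0, only probes in the planted cross-hyb table carry
    region-B signal above their own-compartment prediction."""
    resid = _region_b_residuals(default_bundle, MOUSE)
    implanted = set(default_bundle.truth.xhyb.query("species=='mouse'").probe_id)
    r_imp = resid[resid.index.isin(implanted)]
    r_clean = resid[~resid.index.isin(implanted)]
    assert r_imp.mean() > 0.2  # leakage lifts implanted probes
    assert abs(r_clean.mean()) < 0.05  # clean probes stay on-model


def _region_b_residuals(bundle, species):
    """Observed region-B log2 intensity minus the own-compartment
    prediction from planted truth, averaged over region-B samples."""
    truth, cfg = bundle.truth, bundle.config
    design = bundle.references.design(species)
    ann = design.annotation
    sheet = bundle.sample_sheet
    b = sheet[(sheet["array_species"] == species) & (sheet["region"] == "B")]
    mix = {(r.line, r.animal): r.human_fraction
           for r in truth.mixing.itertuples()}
    lfc = truth.de_series(species)
    mu = truth.baselines[species][ann["gene_id"]].to_numpy()
    eff = lfc[ann["gene_id"]].to_numpy()
    aff = truth.affinities[species][ann["probe_id"]].to_numpy()
    intens = bundle.intensities(species)
    out = np.zeros(len(ann))
    for row in b.itertuples():
        f_h = mix[(row.line, row.animal)]
        own = (f_h if species == HUMAN else 1 - f_h)
        pred = np.log2(own) + mu + eff + aff
        out += intens[row.sample_id].to_numpy() - pred
    return pd.Series(out / len(b), index=ann["probe_id"].to_numpy())


def test_fixture_bundle_round_trips(tmp_path, small_bundle):
    write_fixture_bundle(small_bundle, tmp_path)
    back = read_fixture_bundle(tmp_path)
    pd.testing.assert_frame_equal(back.intensities_human,
                                  small_bundle.intensities_human)
    pd.testing.assert_frame_equal(back.sample_sheet, small_bundle.sample_sheet)
    assert back.references.transcriptome_human == \
        small_bundle.references.transcriptome_human
    assert back.gene_sets == small_bundle.gene_sets
    pd.testing.assert_series_equal(back.truth.de_mouse,
                                   small_bundle.truth.de_mouse)


def test_gene_sets_respect_referential_integrity(small_bundle):
    for sp in (HUMAN, MOUSE):
        universe = set(small_bundle.truth.de_series(sp).index)
        for term, members in small_bundle.gene_sets[sp].items():
            assert set(members) <= universe, term


def test_interactions_contain_planted_bridging_pair(small_bundle):
    bridging = small_bundle.truth.bridging_pairs
    assert bridging is not None and len(bridging) >= 1
    m2h = dict(zip(small_bundle.orthology["mouse_symbol"],
                   small_bundle.orthology["human_symbol"]))
    pairs = {frozenset((r.gene_sym_1, r.gene_sym_2))
             for r in small_bundle.interactions.itertuples()}
    for r in bridging.itertuples():
        assert frozenset((r.human_gene, m2h[r.mouse_gene])) in pairs


def test_invalid_configuration_reports_all_violations():
    with pytest.raises(ConfigurationError) as exc:
        SimulationConfig(frac_de_human=1.5, noise_sd=-1.0,
                         probe_length=30, transcript_length=20).validate()
    msg = str(exc.value)
    assert "frac_de_human" in msg and "noise_sd" in msg
    assert "transcript_length" in msg or "probe_length" in msg
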