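"""Cross-hybridization scoring against brute-force oracles, mask semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenodeconv import (ProbeDesign, apply_mask, build_mask,
                        score_cross_hybridization)

from .oracles import lcs_both_strands, revcomp

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def make_design(seqs: dict[str, str], probeset="ps1", gene="g1") -> ProbeDesign:
    ann = pd.DataFrame({
        "probe_id": list(seqs), "probeset_id": probeset, "gene_id": gene,
        "species": "human"})
    return ProbeDesign(ann, dict(seqs))


def test_verbatim_probe_is_flagged_at_full_length():
    rng = np.random.default_rng(0)
    ref = random_seq(rng, 2000)
    probe = ref[500:525]
    design = make_design({"p1": probe})
    rep = score_cross_hybridization(design, {"tx1": ref}, l_min=15)
    row = rep.table.iloc[0]
    assert row["max_contiguous_match"] == 25
    assert row["best_identity"] == 1.0
    assert bool(row["flagged"])


def test_reverse_complement_match_is_found():
    rng = np.random.default_rng(1)
    ref = random_seq(rng, 1000)
    probe = revcomp(ref[100:125])
    rep = score_cross_hybridization(make_design({"p1": probe}), {"tx": ref},
                                    l_min=15)
    assert rep.table.iloc[0]["max_contiguous_match"] == 25


def test_unrelated_probe_is_not_flagged():
    # homopolymer probe vs a reference with no run of >= 8 identical bases
    ref = "ACGT" * 500
    probe = "A" * 25
    rep = score_cross_hybridization(make_design({"p1": probe}), {"tx": ref},
                                    l_min=15, i_min=0.75)
    row = rep.table.iloc[0]
    assert row["max_contiguous_match"] < 8
    assert not row["flagged"]


def test_scorer_matches_dp_oracle_on_random_probes():
    """Seed-and-extend max_contiguous_match equals the O(n*m) dynamic
    programming longest-common-substring oracle, probe by probe."""
    rng = np.random.default_rng(42)
    ref = random_seq(rng, 20000)
    seqs = {}
    for i in range(60):
        if i % 3 == 0:  # plant exact windows of varying length
            L = int(rng.integers(8, 26))
            pos = int(rng.integers(0, len(ref) - L))
            s = ref[pos:pos + L] + random_seq(rng, 25 - L)
            seqs[f"p{i:03d}"] = s[:25]
        else:
            seqs[f"p{i:03d}"] = random_seq(rng, 25)
    rep = score_cross_hybridization(make_design(seqs), {"tx": ref}, l_min=15)
    for r in rep.table.itertuples():
        assert r.max_contiguous_match == \
            lcs_both_strands(seqs[r.probe_id], ref), r.probe_id


def test_n_bases_never_match():
    ref = "ACGTACGTNNNNNNNNNNNNNNNNNNNNACGTACGT"
    probe = "N" * 25
    rep = score_cross_hybridization(make_design({"p1": probe}), {"tx": ref},
                                    l_min=15)
    assert rep.table.iloc[0]["max_contiguous_match"] == 0


def test_non_acgtn_probe_raises():
    with pytest.raises(ValueError, match="non-ACGTN"):
        score_cross_hybridization(make_design({"p1": "ACGTX" * 5}),
                                  {"tx": "ACGT" * 100})


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=12, max_value=25))
def test_lowering_lmin_never_unflags(l_min):
    """Flag sets are monotone: the exclusion at threshold L contains the
    exclusion at every threshold above L."""
    rng = np.random.default_rng(99)
    ref = random_seq(rng, 5000)
    seqs = {}
    for i in range(30):
        L = int(rng.integers(5, 26))
        pos = int(rng.integers(0, len(ref) - L))
        seqs[f"p{i}"] = (ref[pos:pos + L] + random_seq(rng, 25))[:25]
    design = make_design(seqs)
    rep_lo = score_cross_hybridization(design, {"tx": ref}, l_min=l_min,
                                       i_min=2.0)
    rep_hi = score_cross_hybridization(design, {"tx": ref},
                                       l_min=min(l_min + 3, 25), i_min=2.0)
    lo = set(rep_lo.table.loc[rep_lo.table["flagged"], "probe_id"])
    hi = set(rep_hi.table.loc[rep_hi.table["flagged"], "probe_id"])
    assert hi <= lo


def test_build_mask_drops_probesets_below_minimum():
    rng = np.random.default_rng(3)
    ref = random_seq(rng, 3000)
    seqs, ann_rows = {}, []
    for j in range(11):  # 10 of 11 probes are verbatim foreign substrings
        if j < 10:
            pos = int(rng.integers(0, len(ref) - 25))
            seqs[f"p{j:02d}"] = ref[pos:pos + 25]
        else:
            seqs[f"p{j:02d}"] = random_seq(rng, 25)
    design = make_design(seqs)
    rep = score_cross_hybridization(design, {"tx": ref}, l_min=15)
    mask = build_mask(rep, design, min_probes_per_set=3)
    assert mask.dropped_probesets == {"ps1"}
    assert len(mask.excluded_probes) == 10
    assert mask.removed_probe_ids == set(seqs)  # whole set removed


def test_empty_mask_keeps_matrix_and_no_drops(small_bundle):
    design = small_bundle.references.design("human")
    rep = score_cross_hybridization(
        design, {"tx": "ACGT" * 50}, l_min=15)
    mask = build_mask(rep, design)
    assert not mask.excluded_probes and not mask.dropped_probesets
    out = apply_mask(small_bundle.intensities_human, mask)
    pd.testing.assert_frame_equal(out, small_bundle.intensities_human)


def test_apply_mask_cardinality_and_idempotence(default_bundle, default_masks):
    mask = default_masks["mouse"]
    intens = default_bundle.intensities_mouse
    out = apply_mask(intens, mask)
    dropped_members = {
        p for p in mask.removed_probe_ids} - mask.excluded_probes
    assert len(out) == len(intens) - len(mask.excluded_probes) \
        - len([p for p in dropped_members if p in intens.index])
    pd.testing.assert_frame_equal(apply_mask(out, mask), out)
    assert list(out.columns) == list(intens.columns)


def test_apply_mask_rejects_unknown_probes(default_masks):
    bad = pd.DataFrame(np.ones((2, 3)), index=["nope1", "nope2"],
                       columns=list("abc"))
    with pytest.raises(ValueError, match="nope1"):
        apply_mask(bad, default_masks["human"])


def test_planted_mask_recovery_is_exact(default_bundle, default_masks):
    """With l_min equal to the generator's implant floor, the exclusion set
    equals the planted cross-hybridizing probes: sensitivity and
    specificity both 1."""
    for sp in ("human", "mouse"):
        planted = set(default_bundle.truth.xhyb
                      .query("species == @sp").probe_id)
        assert default_masks[sp].excluded_probes == planted
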