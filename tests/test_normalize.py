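"""Normalization and probeset summarization contracts."""

import numpy as np
import pandas as pd
import pytest

from xenodeconv import (ProbeDesign, median_polish, quantile_normalize,
                        reference_normalize, scale_normalize,
                        summarize_probesets, to_gene_level)
from xenodeconv.pipeline import expression_for_species


def _design(n_sets=2, probes_per_set=3):
    rows, seqs = [], {}
    for s in range(n_sets):
        for j in range(probes_per_set):
            pid = f"g{s}_p{j}"
            rows.append((pid, f"g{s}_at", f"g{s}", "human"))
            seqs[pid] = "ACGT" * 6 + "A"
    return ProbeDesign(pd.DataFrame(
        rows, columns=["probe_id", "probeset_id", "gene_id", "species"]), seqs)


class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_hand_computed_rank_means(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        expected = pd.DataFrame({"a": [2.5, 3.5, 4.5], "b": [2.5, 3.5, 4.5]})
        pd.testing.assert_frame_equal(out, expected)

    def test_ties_get_mean_of_tied_rank_values(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 8.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.5, 7.0]
        assert out["a"].iloc[0] == out["a"].iloc[1] == ref[:2].mean()
        assert out["a"].iloc[2] == ref[2]

    def test_all_column_means_equal_afterwards(self, rng):
        df = pd.DataFrame(rng.lognormal(2, 0.5, size=(50, 6)))
        out = quantile_normalize(df)
        assert np.allclose(out.mean(axis=0), out.mean(axis=0).iloc[0])
        # columns share one sorted value multiset
        ref = np.sort(out.to_numpy()[:, 0])
        for c in range(out.shape[1]):
            assert np.allclose(np.sort(out.to_numpy()[:, c]), ref)

    def test_rejects_nonpositive_and_single_column(self):
        with pytest.raises(ValueError, match="positive"):
            quantile_normalize(pd.DataFrame({"a": [1.0, -2.0], "b": [1.0, 2.0]}))
        with pytest.raises(ValueError, match=">= 2 samples"):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestGlobalNormalizers:
    def test_scale_normalize_equalizes_column_medians(self, rng):
        df = pd.DataFrame(rng.normal(7, 1, size=(101, 4))) + [0, 1, -2, 5]
        out = scale_normalize(df)
        assert np.allclose(out.median(axis=0), out.median(axis=0).iloc[0])

    def test_reference_normalize_removes_global_shifts(self, rng):
        base = rng.normal(7, 1, size=(200, 1))
        shifts = np.array([0.0, -1.0, 0.5, 2.0])
        df = pd.DataFrame(base + shifts + rng.normal(0, 0.05, (200, 4)))
        out = reference_normalize(df)
        col_offsets = out.sub(out.median(axis=1), axis=0).median(axis=0)
        # one-pass estimate: residual offsets far below the planted shifts
        assert np.abs(col_offsets).max() < 0.02

    def test_reference_normalize_tolerates_differential_rows(self, rng):
        """A 15% block of strongly shifted rows in half the samples must
        not drag the null rows' offsets the way plain median centering
        does (worst case: every shifted row moves the same direction)."""
        n = 400
        df = pd.DataFrame(rng.normal(7, 1, size=(n, 1))
                          + np.zeros((n, 8)) + rng.normal(0, 0.2, (n, 8)))
        de = rng.choice(n, size=60, replace=False)
        df.iloc[de, 4:] += 1.5  # all up, worst-case sign imbalance

        def null_shift(normalized):
            null = [i for i in range(n) if i not in set(de)]
            return (normalized.iloc[null, 4:].mean().mean()
                    - normalized.iloc[null, :4].mean().mean())

        ref_bias = abs(null_shift(reference_normalize(df)))
        scale_bias = abs(null_shift(scale_normalize(df)))
        assert ref_bias < 0.1
        assert ref_bias < scale_bias / 2


class TestSummarize:
    def test_single_probe_probeset_passes_through(self):
        design = _design(n_sets=1, probes_per_set=1)
        df = pd.DataFrame({"s1": [3.5], "s2": [4.5]}, index=["g0_p0"])
        out = summarize_probesets(df, design)
        assert out.data.loc["g0_at"].tolist() == [3.5, 4.5]

    def test_median_of_three(self):
        design = _design(n_sets=1, probes_per_set=3)
        df = pd.DataFrame({"s1": [1.0, 2.0, 9.0]},
                          index=["g0_p0", "g0_p1", "g0_p2"])
        assert summarize_probesets(df, design).data.loc["g0_at", "s1"] == 2.0

    def test_invariant_to_probe_row_order(self, rng):
        design = _design(n_sets=2, probes_per_set=3)
        idx = [f"g{s}_p{j}" for s in range(2) for j in range(3)]
        df = pd.DataFrame(rng.normal(size=(6, 4)), index=idx,
                          columns=list("abcd"))
        shuffled = df.sample(frac=1, random_state=7)
        for method in ("median", "medianpolish"):
            a = summarize_probesets(df, design, method=method).data
            b = summarize_probesets(shuffled, design, method=method).data
            pd.testing.assert_frame_equal(a, b)

    def test_median_polish_recovers_additive_sample_effects(self):
        """On a noiseless additive probes x samples table the fitted
        summary differs from the true sample effects by one constant."""
        probe_eff = np.array([0.0, 1.0, -0.5])
        sample_eff = np.array([2.0, 5.0, 3.0])
        table = 7.0 + probe_eff[:, None] + sample_eff[None, :]
        overall, row, col, resid = median_polish(table)
        fitted = overall + col
        assert np.allclose(fitted - fitted[0], sample_eff - sample_eff[0])
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_unknown_rows_rejected(self):
        design = _design()
        df = pd.DataFrame({"s": [1.0]}, index=["mystery_probe"])
        with pytest.raises(ValueError, match="mystery_probe"):
            summarize_probesets(df, design)

    def test_gene_level_reindex(self):
        design = _design(n_sets=2, probes_per_set=1)
        df = pd.DataFrame({"s": [1.0, 2.0]}, index=["g0_p0", "g1_p0"])
        out = to_gene_level(summarize_probesets(df, design), design)
        assert list(out.data.index) == ["g0", "g1"]


def test_noiseless_contrast_equals_planted_effects_end_to_end():
    """sigma -> 0, no leakage: summarized region contrasts reproduce the
    planted log2 fold changes to near machine precision."""
    from xenodeconv import SimulationConfig, generate_bundle
    cfg = SimulationConfig(n_genes_per_species=30, probes_per_set=4,
                           transcript_length=160, noise_sd=1e-9,
                           xhyb_coupling=0.0, frac_xhyb_probes=0.0,
                           mixing_jitter_sd=0.0, seed=21)
    bundle = generate_bundle(cfg)
    expr = expression_for_species(bundle, "human", None)
    sheet = bundle.sample_sheet
    b = sheet.query("array_species=='human' and region=='B'").sample_id
    a = sheet.query("array_species=='human' and region=='A'").sample_id
    est = expr[list(b)].mean(1) - expr[list(a)].mean(1)
    assert np.allclose(est, bundle.truth.de_human[est.index], atol=1e-6)
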