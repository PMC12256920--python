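"""LD estimation: filters, masks, correlation policies, store assembly."""

import numpy as np
import pandas as pd
import pytest

from prskit.ld_estimate import (GenotypePanel, blocks_to_index_intervals,
                                build_mask, compute_ld, pairwise_correlation,
                                read_ld_blocks, variant_filters)
from prskit.ld_store import QuantizationSpec
from prskit import simulate


def panel_from(dosages, cm=None, chrom=None, alleles=None):
    dosages = np.asarray(dosages, dtype=np.float64)
    M = dosages.shape[1]
    if alleles is None:
        alleles = [("A", "G")] * M
    variants = pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(M)],
        "chr": chrom if chrom is not None else np.ones(M, dtype=int),
        "pos": np.arange(1, M + 1) * 100,
        "cm": cm if cm is not None else np.arange(M, dtype=float),
        "a1": [a for a, _ in alleles],
        "a2": [b for _, b in alleles],
    })
    return GenotypePanel(dosages=dosages, variants=variants)


class TestVariantFilters:
    def test_mac_threshold(self):
        # variant 0: 10 minor copies out of 2*100 -> excluded at mac_min=20
        rng = np.random.default_rng(0)
        d = np.zeros((100, 2))
        d[:5, 0] = 2.0                      # MAC 10
        d[:, 1] = rng.integers(0, 3, 100)   # common variant
        panel = panel_from(d)
        kept = variant_filters(panel, mac_min=20)
        assert 0 not in kept and 1 in kept

    def test_ambiguous_strand_dropped(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (50, 2)).astype(float)
        panel = panel_from(d, alleles=[("A", "T"), ("C", "A")])
        kept = variant_filters(panel, mac_min=0, drop_ambiguous=True)
        assert list(kept) == [1]

    def test_hand_counted_toy(self):
        # 5 variants x 10 samples with known minor allele counts
        d = np.zeros((10, 5))
        d[:3, 0] = 1.0   # MAC 3
        d[:5, 1] = 2.0   # MAC 10
        d[:, 2] = 1.0    # MAC 10 (freq 0.5)
        d[0, 3] = 1.0    # MAC 1
        d[:, 4] = 2.0    # monomorphic: MAC 0
        panel = panel_from(d)
        kept = set(variant_filters(panel, mac_min=3))
        assert kept == {0, 1, 2}


class TestBuildMask:
    def test_windowed_pairs(self):
        panel = panel_from(np.zeros((4, 3)), cm=[0.0, 1.0, 5.0])
        mask = build_mask(panel, "windowed", window_cm=3.0)
        # distances: (0,1)=1 in, (0,2)=5 out, (1,2)=4 out
        assert list(mask.run_counts()) == [1, 0, 0]

    def test_window_saturation(self):
        panel = panel_from(np.zeros((4, 3)), cm=[0.0, 1.0, 2.0])
        mask = build_mask(panel, "windowed", window_cm=100.0)
        assert list(mask.run_counts()) == [2, 1, 0]

    def test_unsorted_cm_rejected(self):
        panel = panel_from(np.zeros((4, 3)), cm=[0.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="non-decreasing"):
            build_mask(panel, "windowed", window_cm=1.0)

    def test_window_does_not_cross_chromosomes(self):
        panel = panel_from(np.zeros((4, 4)), cm=[0.0, 0.5, 0.0, 0.5],
                           chrom=[1, 1, 2, 2])
        mask = build_mask(panel, "windowed", window_cm=10.0)
        assert list(mask.run_counts()) == [1, 0, 1, 0]

    def test_block_enumeration(self):
        panel = panel_from(np.zeros((4, 3)))
        mask = build_mask(panel, "block", block_intervals=[(0, 2), (2, 3)])
        assert list(mask.run_counts()) == [1, 0, 0]

    def test_blocks_must_tile(self):
        panel = panel_from(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="tile|cover"):
            build_mask(panel, "block", block_intervals=[(0, 2)])

    def test_bp_blocks_and_stragglers(self, tmp_path):
        # variants at pos 100..500; blocks [50,250) and [250,380)
        path = tmp_path / "blocks.txt"
        path.write_text("1 50 250\n1 250 380\n")
        blocks = read_ld_blocks(path)
        panel = panel_from(np.zeros((4, 5)))
        intervals = blocks_to_index_intervals(panel.variants, blocks)
        # pos 100,200 -> block 1; 300 -> block 2; 400,500 -> singletons
        assert intervals == [(0, 2), (2, 3), (3, 4), (4, 5)]


class TestPairwiseCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        panel = panel_from(rng.integers(0, 3, (20, 2)).astype(float))
        assert pairwise_correlation(panel, 0, 0) == pytest.approx(1.0)

    @pytest.mark.parametrize("policy", ["mean_impute", "pairwise_complete"])
    def test_matches_textbook_pearson_without_missingness(self, policy):
        d = np.array([[0, 0], [1, 0], [1, 1], [2, 1], [2, 2], [0, 1]],
                     dtype=float)
        panel = panel_from(d)
        expected = np.corrcoef(d[:, 0], d[:, 1])[0, 1]
        assert pairwise_correlation(panel, 0, 1, policy) == pytest.approx(expected)

    def test_mean_impute_equals_explicit_substitution(self):
        d = np.array([[0, 0], [1, 0], [np.nan, 1], [2, 1], [2, 2], [0, 1]])
        panel = panel_from(d)
        filled = d.copy()
        filled[2, 0] = np.nanmean(d[:, 0])
        expected = np.corrcoef(filled[:, 0], filled[:, 1])[0, 1]
        assert pairwise_correlation(panel, 0, 1, "mean_impute") == \
            pytest.approx(expected)

    def test_pairwise_complete_drops_samples(self):
        d = np.array([[0, 0], [1, 0], [np.nan, 1], [2, 1], [2, 2], [0, 1]])
        panel = panel_from(d)
        ok = ~np.isnan(d[:, 0])
        expected = np.corrcoef(d[ok, 0], d[ok, 1])[0, 1]
        assert pairwise_correlation(panel, 0, 1, "pairwise_complete") == \
            pytest.approx(expected)

    def test_zero_variance_rejected(self):
        d = np.column_stack([np.ones(6), np.arange(6, dtype=float)])
        panel = panel_from(d)
        with pytest.raises(ValueError, match="variance"):
            pairwise_correlation(panel, 0, 1)


class TestComputeLD:
    def test_empty_mask_gives_empty_data(self):
        rng = np.random.default_rng(3)
        panel = panel_from(rng.integers(0, 3, (30, 3)).astype(float))
        mask = build_mask(panel, "block",
                          block_intervals=[(0, 1), (1, 2), (2, 3)])
        store = compute_ld(panel, mask)
        assert len(store.data) == 0
        assert list(store.indptr) == [0, 0, 0, 0]

    def test_dense_oracle_three_variants(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, (200, 3)).astype(float)
        panel = panel_from(d)
        mask = build_mask(panel, "block", block_intervals=[(0, 3)])
        spec = QuantizationSpec("int16")
        store = compute_ld(panel, mask, qspec=spec)
        oracle = np.corrcoef(d.T)
        assert np.max(np.abs(store.to_dense() - oracle)) <= \
            spec.resolution / 2 + 1e-5

    def test_windowed_pairs_respect_cm_bound(self):
        cfg = simulate.SimulationConfig(n_samples=500, n_variants=100,
                                        block_size=25, rho=0.6, seed=5)
        panel = simulate.simulate_genotypes(cfg)
        mask = build_mask(panel, "windowed", window_cm=3.0)
        store = compute_ld(panel, mask)
        cm = panel.variants["cm"].to_numpy()
        for i in range(100):
            start, vals = store.row_neighbors(i)
            for k in range(len(vals)):
                assert abs(cm[start + k] - cm[i]) <= 3.0 + 1e-12

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, (100, 5)).astype(float)
        panel = panel_from(d)
        perm = rng.permutation(100)
        panel_perm = panel_from(d[perm])
        mask = build_mask(panel, "block", block_intervals=[(0, 5)])
        s1 = compute_ld(panel, mask)
        s2 = compute_ld(panel_perm, mask)
        np.testing.assert_allclose(s1.data, s2.data, atol=1e-6)

    def test_attrs_record_provenance(self):
        rng = np.random.default_rng(7)
        panel = panel_from(rng.integers(0, 3, (50, 4)).astype(float))
        mask = build_mask(panel, "windowed", window_cm=2.0)
        store = compute_ld(panel, mask, policy="mean_impute",
                           qspec=QuantizationSpec("int8"))
        assert store.attrs["estimator"] == "windowed"
        assert store.attrs["missing_policy"] == "mean_impute"
        assert store.attrs["sample_size"] == 50
        assert store.spec.dtype_name == "int8"


class TestSpectrumOfEstimators:
    def test_block_mean_impute_is_psd_up_to_quantization(self):
        cfg = simulate.SimulationConfig(n_samples=300, n_variants=60,
                                        block_size=20, rho=0.8,
                                        missing_rate=0.05, seed=8)
        panel = simulate.simulate_genotypes(cfg)
        mask = build_mask(panel, "block",
                          block_intervals=cfg.block_intervals())
        spec = QuantizationSpec("int16")
        store = compute_ld(panel, mask, policy="mean_impute", qspec=spec)
        lam_min = np.linalg.eigvalsh(store.to_dense())[0]
        assert lam_min >= -spec.resolution * 60

    def test_pairwise_complete_can_break_psd(self):
        # entries estimated on disjoint sample subsets can be mutually
        # inconsistent: r12 ~ +1 and r13 ~ +1 but r23 ~ -1
        x1 = np.array([0, 2, 0, 2, np.nan, np.nan, np.nan, np.nan, 0, 2])
        x2 = np.array([0, 2, np.nan, np.nan, 0, 2, 0, 2, 0, 2])
        x3 = np.array([np.nan, np.nan, 0, 2, 2, 0, 2, 0, 0, 2])
        panel = panel_from(np.column_stack([x1, x2, x3]))
        mask = build_mask(panel, "block", block_intervals=[(0, 3)])
        store = compute_ld(panel, mask, policy="pairwise_complete")
        lam_min = np.linalg.eigvalsh(store.to_dense())[0]
        assert lam_min < -0.1
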