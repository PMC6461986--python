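"""Genotype generator, LD, effective SNP number, pruning, PCA."""

import numpy as np
import pytest
from scipy import stats

from mgba import genosim
from mgba.genosim import (EffectiveSnpCount, LDMatrix, calibrate_ld_strength,
                          classify_proportion, compute_ld, compute_pcs,
                          effective_number_from_pcorr, effective_snp_number,
                          generate_region, ld_prune, pvalue_correlation,
                          stabilize_correlation)

from conftest import panel_from_dosages


class TestGenerateRegion:
    def test_seeded_determinism(self):
        a = generate_region(100, 20, 0.7, seed=5)
        b = generate_region(100, 20, 0.7, seed=5)
        assert np.array_equal(a.dosages, b.dosages)
        assert np.array_equal(a.positions, b.positions)

    @pytest.mark.parametrize("kwargs", [
        {"n_snps": 19},
        {"ld_strength": 1.0},
        {"ld_strength": -0.1},
        {"maf_law": ("uniform", 0.005, 0.5)},
    ])
    def test_input_validation(self, kwargs):
        base = {"n_samples": 100, "n_snps": 20, "ld_strength": 0.5, "seed": 0}
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_region(**base)

    def test_independent_snps_have_negligible_ld(self):
        panel = generate_region(2000, 60, 0.0, seed=3)
        r = compute_ld(panel).r
        off = np.abs(r[np.triu_indices_from(r, k=1)])
        assert np.mean(off < 0.1) > 0.95
        assert off.mean() < 0.03

    def test_common_snps_only(self):
        panel = generate_region(2000, 60, 0.5, seed=4)
        assert (panel.maf >= 0.01).all()
        assert (panel.maf <= 0.5).all()

    def test_positions_strictly_increasing_within_region(self):
        panel = generate_region(50, 20, 0.3, seed=1)
        assert (np.diff(panel.positions) > 0).all()
        assert panel.positions[-1] <= 10_000

    def test_strong_ld_reaches_low_class(self):
        # oracle: realized effective proportion averaged over seeds
        props = []
        for s in range(10):
            p = generate_region(1000, 60, 0.95, seed=s)
            props.append(effective_snp_number(compute_ld(p)).proportion)
        assert np.mean(props) < 0.40

    def test_empirical_maf_tracks_target(self):
        hap = genosim.generate_haplotypes(2000, 30, 0.2, seed=8)
        emp = hap.haplotypes.mean(axis=0)
        assert np.all(np.abs(emp - hap.maf_target) < 0.05)


class TestComputeLd:
    def test_duplicated_column_is_perfectly_correlated(self):
        d = np.array([[0, 0, 2], [1, 1, 0], [2, 2, 1], [0, 0, 0],
                      [1, 1, 2], [2, 2, 1]])
        r = compute_ld(panel_from_dosages(d)).r
        assert r[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_computed_pearson(self):
        # oracle: direct evaluation of the Pearson formula
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 2, 0],
                      [0, 1, 1], [1, 2, 2], [2, 0, 0]], dtype=float)
        r = compute_ld(panel_from_dosages(d)).r
        for i in range(3):
            for j in range(3):
                x, y = d[:, i], d[:, j]
                xc, yc = x - x.mean(), y - y.mean()
                expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
                assert r[i, j] == pytest.approx(expected, abs=1e-9)

    def test_monomorphic_column_raises_with_snp_name(self):
        d = np.array([[1, 1], [1, 0], [1, 2], [1, 1]])
        with pytest.raises(ValueError, match="snp0"):
            compute_ld(panel_from_dosages(d))

    def test_needs_two_snps(self):
        with pytest.raises(ValueError):
            compute_ld(panel_from_dosages([[0], [1], [2]]))


class TestStabilize:
    def test_clips_to_psd_with_unit_diagonal(self):
        m = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        s = stabilize_correlation(m)
        assert np.linalg.eigvalsh(s).min() >= 0
        assert np.allclose(np.diag(s), 1.0)

    def test_psd_input_unchanged(self):
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.allclose(stabilize_correlation(m), m)


class TestEffectiveSnpNumber:
    def test_identical_snps_collapse_to_one(self):
        ld = LDMatrix(np.ones((5, 5)))
        eff = effective_snp_number(ld)
        assert eff.m_e == pytest.approx(1.0, abs=1e-9)
        assert eff.class_label == "low"

    def test_identity_ld_keeps_all(self):
        eff = effective_snp_number(LDMatrix(np.eye(60)))
        assert eff.m_e == pytest.approx(60.0)
        assert eff.proportion == pytest.approx(1.0)
        assert eff.class_label == "high"

    def test_block_diagonal_perfect_blocks_count_blocks(self):
        # B perfectly-correlated blocks -> m_e = B exactly
        blocks = [3, 4, 5]
        m = sum(blocks)
        r = np.zeros((m, m))
        start = 0
        for b in blocks:
            r[start:start + b, start:start + b] = 1.0
            start += b
        eff = effective_snp_number(LDMatrix(r))
        assert eff.m_e == pytest.approx(len(blocks), abs=1e-8)

    def test_duplicate_snp_never_counts_as_extra_test(self):
        # a perfect copy of an existing SNP must not add an independent
        # test's worth to m_e (strict non-increase does not hold for the
        # eigenvalue estimator: duplicating one SNP of an r=0.5 pair moves
        # m_e from 1.50 to 1.63)
        panel = generate_region(500, 20, 0.5, seed=9)
        me0 = effective_snp_number(compute_ld(panel)).m_e
        dup = np.column_stack([panel.dosages, panel.dosages[:, 5]])
        pos = np.append(panel.positions, panel.positions[-1] + 1)
        me1 = effective_snp_number(
            compute_ld(panel_from_dosages(dup, pos))).m_e
        assert me1 < me0 + 0.5

    def test_class_boundaries_exact(self):
        assert classify_proportion(0.399) == "low"
        assert classify_proportion(0.40) == "moderate"
        assert classify_proportion(0.60) == "moderate"
        assert classify_proportion(0.601) == "high"

    def test_real_gene_proportion_is_low_class(self):
        # 90.6 effective of 422 total = 21.5% -> low
        assert classify_proportion(90.6 / 422) == "low"

    def test_pcorr_fallback_abs_r(self):
        r = np.array([[1.0, 0.6], [0.6, 1.0]])
        pc = pvalue_correlation(r, method="abs_r")
        assert pc[0, 1] == pytest.approx(0.6)
        poly = pvalue_correlation(r, method="polynomial")
        assert poly[0, 1] != pytest.approx(0.6, abs=1e-3)


class TestLdPrune:
    def test_identity_ld_retains_all(self):
        panel = generate_region(500, 20, 0.0, seed=11)
        kept = ld_prune(panel, r2_threshold=0.5)
        assert kept == list(range(20))

    def test_duplicate_keeps_first_by_position(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(50, 1)).astype(float)
        noise = rng.integers(0, 3, size=(50, 18)).astype(float)
        d = np.column_stack([g, g, noise])
        kept = ld_prune(panel_from_dosages(d), r2_threshold=0.1)
        assert 0 in kept and 1 not in kept

    def test_matches_independent_greedy_oracle(self):
        panel = generate_region(800, 30, 0.85, seed=13)
        kept = ld_prune(panel, r2_threshold=0.5, window=50)
        # oracle: independent greedy re-implementation on the same r^2
        r2 = np.corrcoef(panel.dosages, rowvar=False) ** 2
        expected = []
        for i in range(30):
            if all(r2[i, j] <= 0.5 for j in expected if i - j <= 50):
                expected.append(i)
        assert kept == expected

    def test_appending_excluded_snp_leaves_retained_set(self):
        panel = generate_region(800, 30, 0.85, seed=13)
        kept = ld_prune(panel, r2_threshold=0.5)
        dup = np.column_stack([panel.dosages, panel.dosages[:, kept[0]]])
        pos = np.append(panel.positions, panel.positions[-1] + 1)
        kept2 = ld_prune(panel_from_dosages(dup, pos), r2_threshold=0.5)
        assert kept2 == kept

    def test_threshold_validation(self):
        panel = generate_region(100, 20, 0.0, seed=1)
        with pytest.raises(ValueError):
            ld_prune(panel, r2_threshold=0.0)


class TestComputePcs:
    def test_two_population_panel_separated_by_pc1(self):
        rng = np.random.default_rng(5)
        a = rng.choice([0.0, 2.0], size=20)
        b = 2.0 - a  # mirrored profile: every column stays polymorphic
        d = np.vstack([np.tile(a, (15, 1)), np.tile(b, (15, 1))])
        panel = panel_from_dosages(d)
        pc1 = compute_pcs(panel, 1)[:, 0]
        assert len(np.unique(np.round(pc1, 6))) == 2
        assert not np.isclose(pc1[0], pc1[-1])

    def test_scores_orthogonal(self, big_panel):
        s = compute_pcs(big_panel, 3)
        sc = s - s.mean(axis=0)
        g = sc.T @ sc
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-6

    def test_variance_explained_matches_eigendecomposition(self, small_panel):
        # oracle: eigenvalues of the standardized dosage covariance
        s = compute_pcs(small_panel, 2)
        x = small_panel.dosages - small_panel.dosages.mean(axis=0)
        x = x / x.std(axis=0)
        w = np.sort(np.linalg.eigvalsh(np.cov(x, rowvar=False)))[::-1]
        var_pc = s.var(axis=0, ddof=1)
        assert var_pc[0] == pytest.approx(w[0], rel=1e-8)
        assert var_pc[1] == pytest.approx(w[1], rel=1e-8)

    def test_k_too_large_raises(self, small_panel):
        with pytest.raises(ValueError):
            compute_pcs(small_panel, 20)

    def test_deterministic_sign(self, small_panel):
        a = compute_pcs(small_panel, 2)
        b = compute_pcs(small_panel, 2)
        assert np.array_equal(a, b)


def test_calibration_lands_in_requested_class():
    strength = calibrate_ld_strength("moderate", n_samples=400, n_snps=30,
                                     n_seeds=8, seed=3, tol=0.04)
    props = [effective_snp_number(compute_ld(
        generate_region(400, 30, strength, seed=100 + s))).proportion
        for s in range(8)]
    assert 0.38 < np.mean(props) < 0.62
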