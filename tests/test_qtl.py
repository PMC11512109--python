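import logging

import numpy as np
import pytest

from rootangle.qtl import (
    BVSPriors,
    ChainConfig,
    DesignMatrices,
    bayes_factors,
    center_genotypes,
    classify_qtls,
    cohens_d,
    run_bvs,
    simulate_qtl_data,
)


class TestCenterGenotypes:
    def test_centres_columns_to_zero_mean(self):
        g = center_genotypes(np.array([[-1], [0], [1]]))
        assert np.allclose(g.X.mean(axis=0), 0.0, atol=1e-12)
        assert g.X[:, 0].tolist() == [-1.0, 0.0, 1.0]

    def test_half_half_column(self):
        g = center_genotypes(np.array([[0], [0], [1], [1]]))
        assert g.X[:, 0].tolist() == [-0.5, -0.5, 0.5, 0.5]

    def test_monomorphic_dropped_with_warning(self, caplog):
        raw = np.array([[1, 0], [1, 1], [1, -1]])
        with caplog.at_level(logging.WARNING, logger="rootangle"):
            g = center_genotypes(raw, ids=["mono", "poly"])
        assert g.ids == ["poly"] and g.p == 1
        assert any("monomorphic" in rec.message for rec in caplog.records)

    def test_missing_or_bad_coding_rejected(self):
        with pytest.raises(ValueError):
            center_genotypes(np.array([[np.nan], [0.0], [1.0]]))
        with pytest.raises(ValueError):
            center_genotypes(np.array([[2], [0], [1]]))

    def test_maf_from_raw_coding(self):
        g = center_genotypes(np.array([[1], [1], [0], [-1]]))
        # +1 allele frequency 5/8 -> minor allele frequency 3/8
        assert g.maf[0] == pytest.approx(3 / 8)


class TestBayesFactors:
    @pytest.mark.parametrize(
        "pip,expected", [(0.5, 100.0), (1 / 101, 1.0), (0.2, 25.0)]
    )
    def test_prior_odds_convention(self, pip, expected):
        assert bayes_factors(np.array([pip]))[0] == pytest.approx(expected)

    def test_pip_of_one_is_infinite(self):
        assert np.isinf(bayes_factors(np.array([1.0]))[0])

    def test_rejects_out_of_range_pip(self):
        with pytest.raises(ValueError):
            bayes_factors(np.array([1.2]))


class TestClassifyQtls:
    def test_evidence_classes(self):
        bf = np.array([19.30, 4.11, 16.75, 5.81, 3.0, 5.0, 3.2, np.inf])
        assert classify_qtls(bf).tolist() == [
            "strong", "putative", "strong", "strong", "none", "putative",
            "putative", "strong",
        ]


class TestCohensD:
    def test_identical_group_means_zero(self):
        g = np.array([-1, -1, -1, 1, 1, 1])
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        assert cohens_d(y, g) == pytest.approx(0.0)

    def test_hand_arithmetic_example(self):
        # minor (+1) carriers have trait (1,2,3); majors (2,3,4); pooled sd 1
        g = np.array([0, 0, 1, -1, -1, -1])
        y = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])
        assert cohens_d(y, g) == pytest.approx(-1.0)

    def test_large_sample_consistency(self, rng):
        n = 10_000
        g = np.where(rng.random(n) < 0.3, 0, -1).astype(int)
        y = np.where(g >= 0, rng.normal(12, 1, n), rng.normal(10, 1, n))
        assert cohens_d(y, g) == pytest.approx(2.0, abs=0.1)

    def test_tiny_group_rejected(self):
        g = np.array([1, -1, -1, -1])
        with pytest.raises(ValueError):
            cohens_d(np.array([1.0, 2.0, 3.0, 4.0]), g)


class TestSimulateQtlData:
    def test_deterministic(self):
        out1 = simulate_qtl_data(n=50, p=30, n_qtl=2, rng_seed=5)
        out2 = simulate_qtl_data(n=50, p=30, n_qtl=2, rng_seed=5)
        assert (out1[0] == out2[0]).all()
        assert (out1[1].raw == out2[1].raw).all()

    def test_null_has_no_marker_effects(self):
        y, geno, design, truth = simulate_qtl_data(
            n=40, p=20, n_qtl=0, qtl_variance_fraction=0.0, rng_seed=1
        )
        assert truth["qtl_indices"].size == 0

    def test_variance_budget_enforced(self):
        with pytest.raises(ValueError, match="budget"):
            simulate_qtl_data(n=20, p=10, qtl_variance_fraction=0.95)

    def test_planted_fraction_of_variance(self):
        y, geno, design, truth = simulate_qtl_data(
            n=2000, p=50, n_qtl=3, qtl_variance_fraction=0.3, rng_seed=2
        )
        g = geno.X[:, truth["qtl_indices"]] @ truth["effects"]
        assert np.var(g) / np.var(y) == pytest.approx(0.3, abs=0.05)

    def test_design_factors_nested_and_complete(self):
        _, _, design, _ = simulate_qtl_data(n=100, p=10, rng_seed=3)
        for name in ("block", "position", "gdd"):
            assert design.factors[name].shape == (100,)
        # position levels nest within blocks
        blk, pos = design.factors["block"], design.factors["position"]
        assert (pos // 4 == blk).all()


class TestRunBvs:
    def test_same_seed_identical_results(self):
        y, geno, design, _ = simulate_qtl_data(n=60, p=40, n_qtl=1, rng_seed=7)
        chain = ChainConfig(iterations=400, burn_in=100, thinning=2, rng_seed=9)
        r1 = run_bvs(y, geno, design, chain=chain)
        r2 = run_bvs(y, geno, design, chain=chain)
        assert (r1.pip == r2.pip).all()
        assert (r1.beta_mean == r2.beta_mean).all()
        assert r1.pi0_mean == r2.pi0_mean

    def test_marker_order_exchangeability(self):
        y, geno, design, _ = simulate_qtl_data(n=60, p=30, n_qtl=2, rng_seed=11)
        chain = ChainConfig(iterations=300, burn_in=50, thinning=1, rng_seed=13)
        base = run_bvs(y, geno, design, chain=chain)
        perm = np.random.default_rng(0).permutation(geno.p)
        shuffled = center_genotypes(
            geno.raw[:, perm],
            ids=[geno.ids[j] for j in perm],
            chrom=geno.chrom[perm],
            pos=geno.pos[perm],
        )
        permuted = run_bvs(y, shuffled, design, chain=chain)
        assert np.array_equal(permuted.pip, base.pip[perm])
        assert np.array_equal(permuted.beta_mean, base.beta_mean[perm])

    def test_null_posterior_dominated_by_spike(self):
        y, geno, design, _ = simulate_qtl_data(
            n=100, p=100, n_qtl=0, qtl_variance_fraction=0.0, rng_seed=17
        )
        res = run_bvs(
            y, geno, design,
            chain=ChainConfig(iterations=1500, burn_in=300, thinning=3, rng_seed=19),
        )
        assert res.pi0_mean > 0.9
        assert res.pip.max() <= 1.0 and res.pip.min() >= 0.0

    def test_single_qtl_recovered(self):
        y, geno, design, truth = simulate_qtl_data(
            n=300, p=100, n_qtl=1, qtl_variance_fraction=0.25, rng_seed=23
        )
        res = run_bvs(
            y, geno, design,
            chain=ChainConfig(iterations=1500, burn_in=300, thinning=3, rng_seed=29),
        )
        q = truth["qtl_indices"][0]
        assert res.pip[q] > 0.5
        assert res.pip[q] == res.pip.max()

    def test_ridge_limit_with_zeta_fixed(self):
        y, geno, _, _ = simulate_qtl_data(
            n=50, p=20, n_qtl=3, qtl_variance_fraction=0.4, rng_seed=1
        )
        tau1, sige = 0.05, 0.5
        res = run_bvs(
            y, geno, None,
            chain=ChainConfig(iterations=4000, burn_in=500, thinning=1, rng_seed=2),
            include_intercept=False,
            fix_zeta=np.ones(geno.p, bool),
            fix_variances={"tau1sq": tau1, "sigma_e2": sige},
        )
        ridge = np.linalg.solve(
            geno.X.T @ geno.X + (sige / tau1) * np.eye(geno.p), geno.X.T @ y
        )
        assert np.abs(res.beta_mean - ridge).max() <= 0.05 * np.abs(ridge).max()

    def test_divergence_guard_on_bad_input(self):
        y, geno, design, _ = simulate_qtl_data(n=30, p=10, rng_seed=3)
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            run_bvs(y, geno, design, chain=ChainConfig(iterations=10, burn_in=1))

    def test_result_frame_schema(self):
        y, geno, design, _ = simulate_qtl_data(n=40, p=12, rng_seed=31)
        res = run_bvs(
            y, geno, design,
            chain=ChainConfig(iterations=200, burn_in=50, thinning=1, rng_seed=3),
        )
        frame = res.to_frame()
        assert list(frame.columns) == [
            "snpID", "chr", "pos", "MAF", "effect", "effect_sd", "PIP", "BF",
            "class",
        ]
        assert len(frame) == geno.p
        assert set(frame["class"]) <= {"strong", "putative", "none"}


class TestPriorsAndConfig:
    def test_prior_inclusion_odds(self):
        assert BVSPriors().prior_inclusion_odds == pytest.approx(1 / 100)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            BVSPriors(tau_ratio=1.5)
        with pytest.raises(ValueError):
            ChainConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            DesignMatrices(factors={"block": np.array([-1, 0])})
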