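import numpy as np
import pytest

from cerna import (
    NullModel,
    ValidationError,
    build_null_model,
    empirical_pvalue,
    generate_dataset,
    mscor,
    partial_correlation,
    pearson_cor,
)
from cerna.simulate import GeneratorSpec


class TestPartialCorrelation:
    def test_empty_conditioning_set_equals_pearson(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert partial_correlation(a, b) == pearson_cor(a, b)
        assert partial_correlation(a, b, np.empty((30, 0))) == pearson_cor(a, b)

    def test_single_conditioner_matches_textbook_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, m = rng.normal(size=(3, 50))
            r_ab, r_am, r_bm = pearson_cor(a, b), pearson_cor(a, m), pearson_cor(b, m)
            closed = (r_ab - r_am * r_bm) / np.sqrt((1 - r_am**2) * (1 - r_bm**2))
            assert partial_correlation(a, b, m) == pytest.approx(closed, abs=1e-10)
            assert partial_correlation(a, b, m, method="residuals") == pytest.approx(
                closed, abs=1e-10
            )

    def test_dual_implementations_agree(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            k = int(rng.integers(1, 6))
            a, b = rng.normal(size=(2, 100))
            M = rng.normal(size=(100, k))
            p1 = partial_correlation(a, b, M, method="inversion")
            p2 = partial_correlation(a, b, M, method="residuals")
            assert p1 == pytest.approx(p2, abs=1e-10)

    def test_conditional_independence_detected(self):
        rng = np.random.default_rng(3)
        n = 10_000
        M = rng.normal(size=(n, 2))
        a = M.sum(axis=1) + rng.normal(size=n)
        b = M.sum(axis=1) + rng.normal(size=n)
        assert abs(partial_correlation(a, b, M)) < 0.05

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValidationError):
            partial_correlation(
                rng.normal(size=5), rng.normal(size=5), rng.normal(size=(5, 3))
            )

    def test_rank_deficient_strict_mode(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 30))
        m = rng.normal(size=30)
        M = np.column_stack([m, m])  # exactly collinear conditioners
        with pytest.raises(ValidationError):
            partial_correlation(a, b, M, strict=True)


class TestMscor:
    def test_empty_M_gives_zero(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 20))
        assert mscor(a, b) == 0.0

    def test_symmetric_in_a_b(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 40))
        M = rng.normal(size=(40, 3))
        assert mscor(a, b, M) == mscor(b, a, M)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 40))
        M = rng.normal(size=(40, 2))
        base = mscor(a, b, M)
        assert mscor(3.5 * a + 2.0, b, M) == pytest.approx(base, abs=1e-12)
        assert mscor(a, 0.1 * b - 7.0, M) == pytest.approx(base, abs=1e-12)
        assert mscor(a, b, 10.0 * M + 1.0) == pytest.approx(base, abs=1e-12)

    def test_shared_regulator_construct_matches_analytic_value(self):
        # a = -m + e, b = -m + e', unit variances: cor = 1/2 and a,b are
        # conditionally independent given m, so pcor = 0 and mscor = 1/2
        rng = np.random.default_rng(3)
        n = 10_000
        m = rng.standard_normal(n)
        a = -m + rng.standard_normal(n)
        b = -m + rng.standard_normal(n)
        assert mscor(a, b, m[:, None]) == pytest.approx(0.5, abs=0.03)

    def test_irrelevant_conditioners_give_near_zero_mscor(self):
        rng = np.random.default_rng(4)
        n = 10_000
        z = rng.standard_normal(n)
        a = z + rng.standard_normal(n)
        b = z + rng.standard_normal(n)
        M = rng.standard_normal((n, 3))  # independent of both genes
        assert abs(mscor(a, b, M)) < 0.05


class TestNullModel:
    def test_stratum_draws_centred_at_zero(self):
        nm = NullModel(n_samples=100, n_draws=500, seed=0)
        draws = nm.draws(m=2, cor=0.45)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean()) < 3 * se + 1e-3

    def test_null_spread_shrinks_with_sample_size(self):
        small = NullModel(n_samples=50, n_draws=500, seed=1).draws(2, 0.45)
        big = NullModel(n_samples=5000, n_draws=500, seed=1).draws(2, 0.45)
        assert big.std() < small.std()

    def test_lazy_and_eager_builds_are_identical(self):
        eager = build_null_model(n_samples=60, n_draws=200, seed=9)
        lazy = NullModel(n_samples=60, n_draws=200, seed=9)
        for (mk, ck), draws in list(eager.strata.items())[:5]:
            cor = 0.5 * (
                eager.cor_bin_edges[ck] + eager.cor_bin_edges[ck + 1]
            )
            np.testing.assert_array_equal(lazy.draws(mk, cor), draws)

    def test_serialization_round_trip_and_determinism(self, tmp_path):
        nm1 = NullModel(n_samples=40, n_draws=150, seed=5)
        nm1.ensure_stratum(1, 0.3)
        nm2 = NullModel(n_samples=40, n_draws=150, seed=5)
        nm2.ensure_stratum(1, 0.3)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        nm1.to_json(p1)
        nm2.to_json(p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = NullModel.from_json(p1)
        np.testing.assert_array_equal(
            back.draws(1, 0.3), nm1.draws(1, 0.3)
        )

    def test_large_m_capped_into_top_bin(self):
        nm = NullModel(n_samples=30, n_draws=100, seed=0)
        assert nm.m_key(25) == nm.m_key(9) == 9

    def test_out_of_range_cor_rejected(self):
        nm = NullModel(n_samples=30, n_draws=100, seed=0)
        with pytest.raises(ValidationError):
            nm.cor_bin(-0.2)
        with pytest.raises(ValidationError):
            nm.cor_bin(1.2)

    def test_empty_stratum_specification_rejected(self):
        with pytest.raises(ValidationError):
            NullModel(n_samples=30, n_draws=100, seed=0, m_bins=[])


class TestEmpiricalPvalue:
    @pytest.fixture
    def tiny_null(self):
        nm = NullModel(n_samples=30, n_draws=100, seed=0)
        nm.strata[(1, 4)] = np.array([0.1, 0.2, 0.3])
        return nm

    def test_hand_counted_tail(self, tiny_null):
        assert empirical_pvalue(tiny_null, 0.15, 1, 0.45) == pytest.approx(3 / 4)

    def test_observation_above_all_draws(self, tiny_null):
        assert empirical_pvalue(tiny_null, 0.99, 1, 0.45) == pytest.approx(1 / 4)

    def test_observation_below_all_draws(self, tiny_null):
        assert empirical_pvalue(tiny_null, -0.5, 1, 0.45) == pytest.approx(1.0)

    def test_add_one_convention_with_999_draws(self):
        nm = NullModel(n_samples=30, n_draws=999, seed=0)
        nm.strata[(1, 4)] = np.linspace(-0.1, 0.1, 999)
        assert empirical_pvalue(nm, 0.5, 1, 0.45) == pytest.approx(1 / 1000)

    def test_missing_stratum_named_in_error(self, tiny_null):
        with pytest.raises(ValidationError, match="m=3"):
            empirical_pvalue(tiny_null, 0.1, 3, 0.45)


class TestScoreCandidates:
    def test_planted_triplets_scored_decoys_dropped(self, benchmark_run):
        truth = benchmark_run["truth"]
        pred = {i.pair for i in benchmark_run["interactions"]}
        assert len(pred & truth.true_pairs) >= 4
        assert len(pred & truth.decoy_pairs) <= 1
        for it in benchmark_run["interactions"]:
            assert it.mscor > 0 and it.cor_ab > 0
            assert it.mscor == pytest.approx(it.cor_ab - it.pcor_ab, abs=1e-9)

    def test_empty_candidate_list_gives_empty_output(self, benchmark_data):
        from cerna import score_candidates

        dataset, _ = benchmark_data
        nm = NullModel(n_samples=dataset.n_samples, n_draws=100, seed=0)
        assert score_candidates(dataset, [], [], nm) == []

    def test_null_calibration_of_empirical_pvalues(self):
        # genes correlated, miRNAs independent: p-values should be uniform,
        # so the rejection rate at 0.05 stays within its binomial CI
        rng = np.random.default_rng(17)
        nm = NullModel(n_samples=100, n_draws=500, seed=23)
        edges = nm.cor_bin_edges
        ps = []
        while len(ps) < 400:
            ci = int(rng.integers(0, 10))
            k = 0.5 * (edges[ci] + edges[ci + 1])
            L = np.linalg.cholesky([[1.0, k], [k, 1.0]])
            g = rng.standard_normal((100, 2)) @ L.T
            M = rng.standard_normal((100, 2))
            cor = pearson_cor(g[:, 0], g[:, 1])
            if not (0 < cor <= 1):
                continue
            ms = cor - partial_correlation(g[:, 0], g[:, 1], M)
            nm.ensure_stratum(2, cor)
            ps.append(empirical_pvalue(nm, ms, 2, cor))
        rate = np.mean(np.asarray(ps) <= 0.05)
        ci_half = 1.96 * np.sqrt(0.05 * 0.95 / len(ps))
        assert abs(rate - 0.05) <= ci_half + 0.01
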