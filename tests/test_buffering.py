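import numpy as np
import pytest

from bufferscape import (
    KernelSequence,
    elasticity_analysis,
    perturb_series_variance,
    pf_contribution,
    stage_buffering_profile,
    stochastic_elasticity_matrix,
)
from conftest import make_sequence


class TestPerturbSeriesVariance:
    def test_constant_series_is_fixed_point(self):
        np.testing.assert_array_equal(
            perturb_series_variance(np.array([3.0, 3.0, 3.0])), [3.0, 3.0, 3.0]
        )

    def test_forced_two_point_example(self):
        out = perturb_series_variance(np.array([0.0, 2.0]), delta=1.0)
        np.testing.assert_allclose(out, [1.0 - np.sqrt(2), 1.0 + np.sqrt(2)], rtol=1e-14)

    def test_mean_preserved_and_variance_scaled(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 1.5, size=200)
        y = perturb_series_variance(x, delta=1e-5)
        assert abs(y.mean() - x.mean()) < 1e-14
        assert y.var(ddof=1) == pytest.approx(x.var(ddof=1) * (1 + 1e-5), rel=1e-12)

    def test_sign_flip_warns(self):
        with pytest.warns(RuntimeWarning, match="sign"):
            perturb_series_variance(np.array([0.001, 2.0]), delta=10.0)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            perturb_series_variance(np.array([1.0, 2.0]), delta=0.0)


def scalar_oracle_elasticity(a, burn_in, delta):
    """Brute-force E for a 1x1 kernel series: recompute lambda_s on the
    explicitly deviation-scaled series ((1+delta) on deviations, the same
    convention the implementation perturbs with)."""
    lam = np.exp(np.mean(np.log(a[burn_in:])))
    b = a.mean() + (a - a.mean()) * (1.0 + delta)
    lam_p = np.exp(np.mean(np.log(b[burn_in:])))
    return (lam_p - lam) / (delta * lam), lam


class TestStochasticElasticityMatrix:
    def test_constant_sequence_gives_zero_elasticities(self, reference_species):
        seq = make_sequence(reference_species, sigma2_prop=0.0, T=60)
        res = stochastic_elasticity_matrix(seq, burn_in=20, seed=0)
        assert np.all(res.E == 0.0)
        assert res.sum_E == 0.0

    def test_scalar_model_matches_brute_force_oracle(self):
        sigma = 0.05
        a = np.exp(np.where(np.arange(400) % 2 == 0, sigma, -sigma))
        seq = KernelSequence(A=a.reshape(-1, 1, 1))
        res = stochastic_elasticity_matrix(
            seq, n0=np.array([1.0]), burn_in=100, delta=1e-5
        )
        e_oracle, lam_oracle = scalar_oracle_elasticity(a, burn_in=100, delta=1e-5)
        assert res.lambda_s == pytest.approx(lam_oracle, rel=1e-12)
        assert res.E[0, 0] == pytest.approx(e_oracle, rel=1e-8)

    def test_reference_species_is_imperfectly_buffered(self, reference_sequence):
        # environmental variance always costs growth: sum_E < 0
        res = stochastic_elasticity_matrix(reference_sequence, burn_in=100, seed=1)
        assert res.sum_E < 0.0

    def test_deterministic_given_kernels_and_n0(self, reference_species):
        seq = make_sequence(reference_species, T=120)
        n0 = np.full(seq.n_mesh, 1.0 / seq.n_mesh)
        a = stochastic_elasticity_matrix(seq, n0=n0, burn_in=40)
        b = stochastic_elasticity_matrix(seq, n0=n0, burn_in=40)
        np.testing.assert_array_equal(a.E, b.E)

    def test_weighted_and_simplified_forms_agree(self):
        # identity E = [var/lam]*(lam* - lam)/(delta*var) = (lam* - lam)/(delta*lam)
        # against the expm1 evaluation; delta is taken large enough that the
        # subtraction lam* - lam keeps 12 significant digits in doubles
        sigma, delta = 0.2, 0.5
        a = np.exp(np.where(np.arange(400) % 2 == 0, sigma, -sigma))
        seq = KernelSequence(A=a.reshape(-1, 1, 1))
        res = stochastic_elasticity_matrix(
            seq, n0=np.array([1.0]), burn_in=100, delta=delta, keep_perturbed_lambdas=True
        )
        lam, lam_p = res.lambda_s, res.lambda_s_pert[(0, 0)]
        var = a.var(ddof=1)
        literal = (var / lam) * (lam_p - lam) / (delta * var)
        assert res.E[0, 0] == pytest.approx(literal, rel=1e-12)

    def test_variance_monotonicity(self, reference_species):
        # more environmental variance -> less buffered (sum_E more negative)
        n0 = np.full(60, 1.0 / 60)
        sums = []
        for s2p in (0.9, 1.1):
            seq = make_sequence(reference_species, sigma2_prop=s2p, T=300, seed=1)
            sums.append(
                stochastic_elasticity_matrix(seq, n0=n0, burn_in=100).sum_E
            )
        assert sums[1] < sums[0]


class TestSubkernelElasticities:
    def test_zero_fertility_gives_zero_F_sum(self, reference_species):
        import dataclasses

        from bufferscape import LinearPredictorSpec

        ipm = dataclasses.replace(
            reference_species,
            offspring=LinearPredictorSpec(-800.0, (), "log"),
            p_repro=None,
        )
        seq = make_sequence(ipm, T=120)
        res = elasticity_analysis(seq, n0=np.full(60, 1 / 60), burn_in=40)
        assert res.sum_E_F == 0.0

    def test_partition_additivity_with_static_fertility(self, constant_fertility_species):
        # only P varies in time, so the subkernel sums partition sum_E exactly
        seq = make_sequence(constant_fertility_species, T=300, seed=1)
        res = elasticity_analysis(seq, n0=np.full(60, 1 / 60), burn_in=100)
        assert res.sum_E_F == 0.0
        assert res.sum_E_P + res.sum_E_F == pytest.approx(res.sum_E, rel=1e-8)

    def test_partition_additivity_general_first_order(self, reference_sequence):
        # P and F overlap in time-varying elements; additivity holds to the
        # first order of the finite difference
        res = elasticity_analysis(reference_sequence, n0=np.full(60, 1 / 60), burn_in=100)
        assert res.sum_E_P + res.sum_E_F == pytest.approx(res.sum_E, rel=1e-3)

    def test_scalar_split_with_constant_F_matches_whole_kernel(self):
        sigma = 0.08
        p = np.exp(np.where(np.arange(300) % 2 == 0, sigma, -sigma))
        f = np.full(300, 0.3)
        seq = KernelSequence(
            A=(p + f).reshape(-1, 1, 1),
            P=p.reshape(-1, 1, 1),
            F=f.reshape(-1, 1, 1),
        )
        res = elasticity_analysis(seq, n0=np.array([1.0]), burn_in=100)
        k = p + f
        e_oracle, _ = scalar_oracle_elasticity(k, burn_in=100, delta=res.delta)
        assert res.sum_E_F == 0.0
        assert res.sum_E_P == pytest.approx(e_oracle, rel=1e-6)
        assert res.sum_E == pytest.approx(e_oracle, rel=1e-6)

    def test_dimension_mismatch_rejected(self, reference_sequence):
        bad = KernelSequence(
            A=reference_sequence.A,
            P=reference_sequence.P[:10],
            F=reference_sequence.F[:10],
        )
        with pytest.raises(ValueError):
            elasticity_analysis(bad, n0=np.full(60, 1 / 60), burn_in=40)


class TestSummaries:
    @pytest.mark.parametrize(
        "p,f,expected", [(-0.2, -0.2, 0.0), (-0.1, -0.3, 0.2), (-0.3, -0.1, -0.2)]
    )
    def test_pf_contribution(self, p, f, expected):
        assert pf_contribution(p, f) == pytest.approx(expected)

    def test_pf_contribution_rejects_non_finite(self):
        with pytest.raises(ValueError):
            pf_contribution(np.nan, 0.0)

    def test_stage_profile_is_column_sums(self):
        E = np.zeros((4, 4))
        E[1, 2] = -0.1
        profile = stage_buffering_profile(E)
        np.testing.assert_allclose(profile, [0.0, 0.0, -0.1, 0.0])
        assert profile.sum() == pytest.approx(E.sum(), abs=1e-12)

    def test_profile_sum_equals_sum_E(self, reference_species):
        seq = make_sequence(reference_species, T=120)
        res = stochastic_elasticity_matrix(seq, n0=np.full(60, 1 / 60), burn_in=40)
        assert stage_buffering_profile(res.E).sum() == pytest.approx(
            res.sum_E, abs=1e-12
        )
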