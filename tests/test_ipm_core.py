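import dataclasses

import numpy as np
import pytest

from bufferscape import (
    Driver,
    EnvironmentalIPM,
    InvalidModelError,
    LinearPredictorSpec,
    SizeMesh,
    SpecificationError,
    build_kernel,
    build_kernel_sequence,
    dominant_eigenvalue,
    evaluate_predictor,
    mean_kernel,
)
from bufferscape.ipm_core import model_from_dict, model_to_dict, load_model, save_model
from bufferscape.synthetic_species import lambda1_at_mean_environment, make_reference_species


class TestSizeMesh:
    def test_midpoint_formula(self):
        mesh = SizeMesh(alpha=1.0, omega=3.0, n_mesh=4)
        assert mesh.width == pytest.approx(0.5)
        np.testing.assert_allclose(mesh.midpoints, [1.25, 1.75, 2.25, 2.75])

    @pytest.mark.parametrize("alpha,omega,n", [(3.0, 1.0, 4), (1.0, 1.0, 4), (0.0, 1.0, 1)])
    def test_invalid_mesh_rejected(self, alpha, omega, n):
        with pytest.raises(InvalidModelError):
            SizeMesh(alpha=alpha, omega=omega, n_mesh=n)


class TestEvaluatePredictor:
    @pytest.mark.parametrize(
        "spec,z,drivers,expected",
        [
            (LinearPredictorSpec(0.7, (), "identity"), 1.0, {}, 0.7),
            (LinearPredictorSpec(0.0, (), "logit"), 1.0, {}, 0.5),
            (LinearPredictorSpec(np.log(2.0), (), "log"), 1.0, {}, 2.0),
            # eta = 1 + 2*3 + 0.5*9 + 4*2 + 0.25*(2*3) = 21.0
            (
                LinearPredictorSpec(
                    1.0,
                    (("size", 2.0), ("size^2", 0.5), ("env", 4.0), ("env:size", 0.25)),
                    "identity",
                ),
                3.0,
                {"env": 2.0},
                21.0,
            ),
        ],
    )
    def test_links_and_terms(self, spec, z, drivers, expected):
        assert evaluate_predictor(spec, z, drivers) == pytest.approx(expected)

    def test_unresolvable_variable_named_in_error(self):
        spec = LinearPredictorSpec(0.0, (("rainfall", 1.0),), "identity")
        with pytest.raises(SpecificationError, match="rainfall"):
            evaluate_predictor(spec, 1.0, {})

    def test_unknown_link_rejected(self):
        with pytest.raises(InvalidModelError):
            LinearPredictorSpec(0.0, (), "probit")


def _minimal_ipm(survival_intercept=800.0, offspring_intercept=-800.0, growth_intercept=5.0):
    """A driverless IPM with extreme intercepts to force exact 0/1 rates."""
    return EnvironmentalIPM(
        mesh=SizeMesh(alpha=0.0, omega=10.0, n_mesh=60),
        survival=LinearPredictorSpec(survival_intercept, (), "logit"),
        growth_mean=LinearPredictorSpec(growth_intercept, (), "identity"),
        growth_sd=0.8,
        p_repro=LinearPredictorSpec(800.0, (), "logit"),
        offspring=LinearPredictorSpec(offspring_intercept, (), "log"),
        recruit_mean=5.0,
        recruit_sd=0.8,
    )


class TestBuildKernel:
    def test_zero_survival_gives_zero_P(self):
        ks = build_kernel(_minimal_ipm(survival_intercept=-800.0), {})
        assert np.all(ks.P == 0.0)

    def test_zero_offspring_gives_K_equal_P(self):
        ks = build_kernel(_minimal_ipm(offspring_intercept=-800.0), {})
        np.testing.assert_array_equal(ks.K, ks.P)

    def test_column_sums_near_one_when_growth_well_inside_domain(self):
        # survival == 1 and the growth mean sits 6.25 SD from both bounds,
        # so each P column integrates the Gaussian almost completely
        ks = build_kernel(_minimal_ipm(offspring_intercept=-800.0), {})
        np.testing.assert_allclose(ks.P.sum(axis=0), 1.0, atol=1e-6)

    def test_K_equals_P_plus_F_exactly(self, reference_species):
        ks = build_kernel(reference_species, {"env": 0.7})
        np.testing.assert_array_equal(ks.K, ks.P + ks.F)
        assert ks.K.min() >= 0.0

    def test_deterministic_bitwise(self, reference_species):
        a = build_kernel(reference_species, {"env": -0.3})
        b = build_kernel(reference_species, {"env": -0.3})
        np.testing.assert_array_equal(a.K, b.K)

    def test_missing_driver_value_rejected(self, reference_species):
        with pytest.raises(SpecificationError, match="env"):
            build_kernel(reference_species, {})

    def test_renormalized_growth_columns_sum_to_survival(self, reference_species):
        ks = build_kernel(reference_species, {"env": 0.0}, renormalize_growth=True)
        z = reference_species.mesh.midpoints
        s = evaluate_predictor(reference_species.survival, z, {"env": 0.0})
        np.testing.assert_allclose(ks.P.sum(axis=0), s, rtol=1e-12)

    def test_invalid_growth_sd_rejected(self):
        with pytest.raises(InvalidModelError):
            dataclasses.replace(_minimal_ipm(), growth_sd=0.0)


class TestMeanKernel:
    def test_constant_sequence_is_identity(self, reference_sequence):
        const = np.repeat(reference_sequence.A[:1], 5, axis=0)
        np.testing.assert_allclose(
            mean_kernel(const), reference_sequence.A[0], rtol=1e-15
        )

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(42)
        A = rng.uniform(size=(7, 3, 3))
        expected = np.zeros((3, 3))
        for t in range(7):
            for i in range(3):
                for j in range(3):
                    expected[i, j] += A[t, i, j] / 7
        np.testing.assert_allclose(mean_kernel(A), expected, rtol=1e-12)

    def test_two_scalar_kernels(self):
        assert mean_kernel(np.array([[[0.0]], [[2.0]]]))[0, 0] == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidModelError):
            mean_kernel(np.empty((0, 2, 2)))


class TestDominantEigenvalue:
    @pytest.mark.parametrize(
        "M,expected",
        [
            ([[0.0, 2.0], [0.5, 0.0]], 1.0),  # periodic: exercises the fallback
            (np.eye(3), 1.0),
            ([[1.0, 1.0], [1.0, 1.0]], 2.0),
        ],
    )
    def test_known_spectra(self, M, expected):
        assert dominant_eigenvalue(np.asarray(M)) == pytest.approx(expected, rel=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidModelError):
            dominant_eigenvalue(np.array([[np.nan, 0.0], [0.0, 1.0]]))

    def test_agrees_with_eigvals_on_random_kernel(self, reference_sequence):
        M = mean_kernel(reference_sequence)
        expected = np.max(np.abs(np.linalg.eigvals(M)))
        assert dominant_eigenvalue(M) == pytest.approx(expected, rel=1e-8)


def test_discretization_convergence():
    # doubling the mesh changes lambda_1 at mean environment by < 1%
    lam_60 = lambda1_at_mean_environment(make_reference_species(n_mesh=60))
    lam_120 = lambda1_at_mean_environment(make_reference_species(n_mesh=120))
    assert abs(lam_120 - lam_60) / lam_60 < 0.01


class TestKernelSequence:
    def test_constant_env_gives_identical_kernels(self, reference_species):
        env = np.zeros((5, 1))
        seq = build_kernel_sequence(reference_species, env)
        assert len(seq) == 5
        for t in range(1, 5):
            np.testing.assert_array_equal(seq.A[t], seq.A[0])

    def test_rowwise_equality_with_build_kernel(self, reference_species):
        env = np.linspace(-1, 1, 4)[:, None]
        seq = build_kernel_sequence(reference_species, env)
        for t in range(4):
            ks = build_kernel(reference_species, {"env": env[t, 0]})
            np.testing.assert_array_equal(seq.A[t], ks.K)
            np.testing.assert_array_equal(seq.P[t], ks.P)

    def test_column_driver_mismatch_rejected(self, reference_species):
        with pytest.raises(SpecificationError):
            build_kernel_sequence(reference_species, np.zeros((5, 2)))

    def test_element_series_accessor(self, reference_sequence):
        np.testing.assert_array_equal(
            reference_sequence.element_series(3, 7), reference_sequence.A[:, 3, 7]
        )


class TestModelJSON:
    def test_round_trip_is_idempotent(self, reference_species, tmp_path):
        path = tmp_path / "model.json"
        save_model(reference_species, path)
        loaded = load_model(path)
        assert model_to_dict(loaded) == model_to_dict(reference_species)
        # and the kernels are bitwise identical
        np.testing.assert_array_equal(
            build_kernel(loaded, {"env": 0.4}).K,
            build_kernel(reference_species, {"env": 0.4}).K,
        )

    def test_missing_field_reported(self):
        with pytest.raises(SpecificationError, match="mesh"):
            model_from_dict({"vital_rates": {}})

    def test_undeclared_driver_rejected(self):
        doc = model_to_dict(make_reference_species())
        doc["drivers"] = []
        with pytest.raises(InvalidModelError, match="env"):
            model_from_dict(doc)
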