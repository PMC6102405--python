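"""Equation layout, record translation, right-hand side and dense oracle."""

import numpy as np
import pytest

from blupcg import (
    ConfigurationError,
    DataError,
    DimensionError,
    ModelSpec,
    PhenotypeTable,
    ResolvedEffect,
    build_dense_C,
    build_designs,
    build_layout,
    build_record_design,
    build_rhs,
    legendre_basis,
    random_mme_case,
    record_residual_inverse,
)


class TestLegendreBasis:
    def test_order_zero_is_constant(self):
        np.testing.assert_allclose(
            legendre_basis(3.7, 0.0, 10.0, 0), [np.sqrt(0.5)]
        )

    def test_all_polynomials_are_one_at_upper_bound(self):
        # P_k(1) = 1, so only the normalization remains
        np.testing.assert_allclose(
            legendre_basis(10.0, 0.0, 10.0, 2),
            [np.sqrt(0.5), np.sqrt(1.5), np.sqrt(2.5)],
        )

    def test_midpoint_second_order_value(self):
        # x = 0: P2(0) = (3·0 − 1)/2 = −1/2
        phi = legendre_basis(5.0, 0.0, 10.0, 2)
        assert phi[2] == pytest.approx(np.sqrt(2.5) * (-0.5))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            legendre_basis(11.0, 0.0, 10.0, 2)


def _mean_only_model(t=1):
    traits = [f"t{k}" for k in range(t)]
    return ModelSpec(
        trait_names=traits,
        effects=[ResolvedEffect(name="mean", kind="fixed_class", n_levels=1)],
        residual_covs={1: np.eye(t)},
    )


class TestLayout:
    def test_fixed_class_two_levels_one_trait(self):
        model = ModelSpec(
            trait_names=["y"],
            effects=[
                ResolvedEffect(
                    name="herd", kind="fixed_class", n_levels=2, level_column="h"
                )
            ],
            residual_covs={1: np.eye(1)},
        )
        layout = build_layout(model)
        assert layout.n_equations == 2
        assert layout.offsets == [0]

    def test_random_regression_effect_equation_count(self):
        model = ModelSpec(
            trait_names=["a", "b", "c"],
            effects=[
                ResolvedEffect(name="mean", kind="fixed_class", n_levels=1),
                ResolvedEffect(
                    name="animal",
                    kind="random",
                    n_levels=10,
                    level_column="id",
                    covariate_column="dim",
                    legendre=(4, 0.0, 305.0),
                    covariance=np.eye(15),
                ),
            ],
            residual_covs={1: np.eye(3)},
        )
        layout = build_layout(model)
        # 5 coefficients × 3 traits × 10 levels for the RRM effect
        assert layout.n_equations == 3 + 150
        assert layout.offsets == [0, 3]

    def test_trait_consecutive_ordering(self):
        model = _mean_only_model(t=3)
        layout = build_layout(model)
        assert [layout.eq_index(0, 1, 0, k) for k in range(3)] == [0, 1, 2]

    def test_zero_levels_rejected(self):
        with pytest.raises(ConfigurationError):
            ResolvedEffect(name="bad", kind="fixed_class", n_levels=0)


class TestRecordResidualInverse:
    def test_full_observation_inverts_R(self, rng):
        a = rng.standard_normal((3, 3))
        R = a @ a.T + np.eye(3)
        out = record_residual_inverse(R, np.arange(3), 1.0)
        np.testing.assert_allclose(out, np.linalg.inv(R), atol=1e-10)

    def test_single_trait_scalar_inverse(self):
        R = np.diag([2.0, 3.0, 4.0])
        np.testing.assert_allclose(
            record_residual_inverse(R, np.array([1]), 1.0), [[1 / 3]]
        )

    def test_weighted_submatrix_inverse(self):
        R = np.array([[2.0, 0.5, 0.2], [0.5, 1.5, 0.3], [0.2, 0.3, 1.0]])
        obs = np.array([0, 2])
        out = record_residual_inverse(R, obs, 2.5)
        np.testing.assert_allclose(
            out, 2.5 * np.linalg.inv(R[np.ix_(obs, obs)]), atol=1e-12
        )

    def test_invalid_weight_rejected(self):
        with pytest.raises(DataError):
            record_residual_inverse(np.eye(2), np.array([0]), 0.0)


class TestRecordDesign:
    def test_mean_only_single_one(self):
        model = _mean_only_model()
        layout = build_layout(model)
        table = PhenotypeTable(y=np.array([[2.0]]), trait_names=["t0"])
        ds = build_record_design(0, table, model, layout)
        assert ds.eq.tolist() == [0]
        assert ds.val.tolist() == [1.0]

    def test_missing_trait_has_no_equations(self):
        model = _mean_only_model(t=3)
        layout = build_layout(model)
        table = PhenotypeTable(
            y=np.array([[1.0, 2.0, np.nan]]), trait_names=model.trait_names
        )
        ds = build_record_design(0, table, model, layout)
        assert 2 not in ds.eq.tolist()  # trait-3 equation untouched
        assert ds.observed.tolist() == [0, 1]

    def test_legendre_values_placed_at_coefficient_equations(self):
        model = ModelSpec(
            trait_names=["y"],
            effects=[
                ResolvedEffect(name="mean", kind="fixed_class", n_levels=1),
                ResolvedEffect(
                    name="pe",
                    kind="random",
                    n_levels=3,
                    level_column="id",
                    covariate_column="dim",
                    legendre=(2, 0.0, 10.0),
                    covariance=np.eye(3),
                ),
            ],
            residual_covs={1: np.eye(1)},
        )
        layout = build_layout(model)
        table = PhenotypeTable(
            y=np.array([[1.0]]),
            trait_names=["y"],
            class_codes={"id": np.array([2])},
            covariates={"dim": np.array([4.0])},
        )
        ds = build_record_design(0, table, model, layout)
        phi = legendre_basis(4.0, 0.0, 10.0, 2)
        # level 2 of 3, coefficients at offset 1 + (2-1)*3
        assert ds.eq.tolist() == [0, 4, 5, 6]
        np.testing.assert_allclose(ds.val[1:], phi)

    def test_missing_covariate_rejected(self):
        model = ModelSpec(
            trait_names=["y"],
            effects=[
                ResolvedEffect(
                    name="slope",
                    kind="fixed_regression",
                    n_levels=1,
                    covariate_column="x",
                )
            ],
            residual_covs={1: np.eye(1)},
        )
        layout = build_layout(model)
        table = PhenotypeTable(
            y=np.array([[1.0]]),
            trait_names=["y"],
            covariates={"x": np.array([np.nan])},
        )
        with pytest.raises(DataError):
            build_record_design(0, table, model, layout)


class TestRhs:
    def test_single_record_mean_only(self):
        model = _mean_only_model()
        layout = build_layout(model)
        table = PhenotypeTable(y=np.array([[2.0]]), trait_names=["t0"])
        designs = build_designs(table, model, layout)
        np.testing.assert_allclose(build_rhs(designs, 1), [2.0])

    def test_duplicating_records_doubles_rhs(self, rng):
        table, model, layout = random_mme_case(rng)
        designs = build_designs(table, model, layout)
        b1 = build_rhs(designs, layout.n_equations)
        b2 = build_rhs(designs + designs, layout.n_equations)
        np.testing.assert_allclose(b2, 2 * b1, atol=1e-12)

    def test_matches_dense_assembly_oracle(self, rng):
        # independent dense X'R⁻¹y accumulation
        table, model, layout = random_mme_case(rng)
        designs = build_designs(table, model, layout)
        b = build_rhs(designs, layout.n_equations)
        oracle = np.zeros(layout.n_equations)
        for ds in designs:
            W = np.zeros((layout.n_equations, len(ds.observed)))
            W[ds.eq, ds.slot] = ds.val
            oracle += W @ ds.r_inv @ ds.y
        np.testing.assert_allclose(b, oracle, atol=1e-10)


class TestDenseOracle:
    def test_no_records_gives_pure_kinship_part(self):
        model = ModelSpec(
            trait_names=["y"],
            effects=[
                ResolvedEffect(
                    name="u",
                    kind="random",
                    n_levels=4,
                    level_column="id",
                    covariance=np.array([[2.0]]),
                )
            ],
            residual_covs={1: np.eye(1)},
        )
        layout = build_layout(model)
        C = build_dense_C([], model, layout)
        np.testing.assert_allclose(C, 0.5 * np.eye(4))

    def test_identity_kinship_unit_variance_is_identity_block(self):
        model = ModelSpec(
            trait_names=["y"],
            effects=[
                ResolvedEffect(
                    name="u",
                    kind="random",
                    n_levels=3,
                    level_column="id",
                    covariance=np.array([[1.0]]),
                )
            ],
            residual_covs={1: np.eye(1)},
        )
        layout = build_layout(model)
        np.testing.assert_allclose(build_dense_C([], model, layout), np.eye(3))

    def test_symmetric_positive_semidefinite(self, rng):
        for _ in range(5):
            table, model, layout = random_mme_case(rng)
            designs = build_designs(table, model, layout)
            C = build_dense_C(designs, model, layout)
            assert np.abs(C - C.T).max() < 1e-10
            assert np.linalg.eigvalsh(C).min() > -1e-8

    def test_size_guard_refuses_large_systems(self, rng):
        model = ModelSpec(
            trait_names=["y"],
            effects=[
                ResolvedEffect(
                    name="u",
                    kind="random",
                    n_levels=5000,
                    level_column="id",
                    covariance=np.array([[1.0]]),
                )
            ],
            residual_covs={1: np.eye(1)},
        )
        layout = build_layout(model)
        with pytest.raises(DimensionError):
            build_dense_C([], model, layout)
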