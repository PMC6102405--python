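"""Preconditioner, iteration-on-data products and the PCG loop."""

import itertools

import numpy as np
import pytest

from blupcg import (
    DegenerateInputError,
    DimensionError,
    ModelSpec,
    PhenotypeTable,
    PreconditionerBlocks,
    ResolvedEffect,
    apply_preconditioner,
    build_dense_C,
    build_designs,
    build_layout,
    build_operator,
    build_preconditioner,
    build_rhs,
    convergence_value,
    invert_preconditioner,
    iod_matvec,
    make_partition,
    pcg_solve,
    random_mme_case,
    random_spd,
)
from blupcg.simulate import SimConfig, simulate_genotypes, simulate_pedigree, simulate_phenotypes


def _setup(rng):
    table, model, layout = random_mme_case(rng)
    designs = build_designs(table, model, layout)
    op = build_operator(designs, model, layout)
    C = build_dense_C(designs, model, layout)
    return table, model, layout, designs, op, C


def _gblup_case(rng, n=30, t=3, tol_weights=True):
    """Small genomic BLUP with correlated traits for solver checks."""
    cfg = SimConfig(
        n_founders=10,
        n_generations=3,
        offspring_per_generation=10,
        m_snps=200,
        t_traits=t,
        use_weights=tol_weights,
        seed=0,
    )
    ped = simulate_pedigree(cfg, rng)
    geno = simulate_genotypes(ped, cfg, rng)
    table, _ = simulate_phenotypes(geno, cfg, rng)
    from blupcg import RelationshipInverse, ensure_invertible, vanraden_G

    G = ensure_invertible(vanraden_G(geno), diag_load=0.01)
    model = ModelSpec(
        trait_names=table.trait_names,
        effects=[
            ResolvedEffect(name="mean", kind="fixed_class", n_levels=1),
            ResolvedEffect(
                name="animal",
                kind="random",
                n_levels=ped.n,
                level_column="id",
                kinship_inv=RelationshipInverse.from_dense(np.linalg.inv(G)),
                covariance=cfg.genetic_cov,
            ),
        ],
        residual_covs={1: cfg.residual_cov},
    )
    layout = build_layout(model)
    designs = build_designs(table, model, layout)
    op = build_operator(designs, model, layout)
    return table, model, layout, designs, op


class TestPreconditioner:
    def test_single_trait_blocks_equal_C_diagonal(self, rng):
        while True:  # draw a single-trait case
            table, model, layout, designs, op, C = _setup(rng)
            if layout.trait_count == 1 and all(
                t_eff == 1 for _, _, t_eff in layout.effect_dims
            ):
                break
        pb = build_preconditioner(designs, model, layout)
        flat = np.concatenate([arr.ravel() for arr in pb.blocks])
        np.testing.assert_allclose(flat, np.diag(C), atol=1e-10)

    def test_blocks_equal_dense_diagonal_slices(self, rng):
        for _ in range(5):
            table, model, layout, designs, op, C = _setup(rng)
            pb = build_preconditioner(designs, model, layout)
            for ei, arr in enumerate(pb.blocks):
                off = layout.offsets[ei]
                nb, s, _ = arr.shape
                for k in range(nb):
                    st = off + k * s
                    np.testing.assert_allclose(
                        arr[k], C[st : st + s, st : st + s], atol=1e-9
                    )

    def test_no_records_leaves_only_prior_part(self):
        model = ModelSpec(
            trait_names=["y"],
            effects=[
                ResolvedEffect(
                    name="u",
                    kind="random",
                    n_levels=3,
                    level_column="id",
                    covariance=np.array([[4.0]]),
                )
            ],
            residual_covs={1: np.eye(1)},
        )
        layout = build_layout(model)
        pb = build_preconditioner([], model, layout)
        np.testing.assert_allclose(pb.blocks[0].ravel(), [0.25, 0.25, 0.25])


class TestInvertPreconditioner:
    def test_scalar_block(self):
        model = _model_one_random(np.array([[0.25]]))  # G0⁻¹ diag → block [4]
        layout = build_layout(model)
        pb = build_preconditioner([], model, layout)
        inv = invert_preconditioner(pb, model)
        np.testing.assert_allclose(inv.blocks[0], np.full((4, 1, 1), 0.25))

    def test_zero_block_becomes_identity(self, caplog):
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
        pb = build_preconditioner([], model, layout)
        with caplog.at_level("WARNING"):
            inv = invert_preconditioner(pb, model)
        np.testing.assert_allclose(inv.blocks[0], np.ones((2, 1, 1)))
        assert any("zero preconditioner blocks" in r.message for r in caplog.records)

    def test_random_spd_blocks_invert_to_identity(self, rng):
        model = _model_one_random(random_spd(rng, 3))
        layout = build_layout(model)
        pb = build_preconditioner([], model, layout)
        inv = invert_preconditioner(pb, model)
        for a, ai in zip(pb.blocks[0], inv.blocks[0]):
            np.testing.assert_allclose(a @ ai, np.eye(3), atol=1e-10)


def _model_one_random(cov, levels=4):
    t = 1 if cov.shape[0] == 1 else cov.shape[0]
    return ModelSpec(
        trait_names=[f"t{k}" for k in range(t)],
        effects=[
            ResolvedEffect(
                name="u",
                kind="random",
                n_levels=levels,
                level_column="id",
                covariance=cov,
            )
        ],
        residual_covs={1: np.eye(t)},
    )


class TestApplyPreconditioner:
    def test_identity_blocks_return_input(self, rng):
        model = _model_one_random(np.eye(2))
        layout = build_layout(model)
        pb = PreconditionerBlocks.identity(layout)
        r = rng.standard_normal(layout.n_equations)
        np.testing.assert_allclose(apply_preconditioner(pb, r), r)

    def test_two_by_two_block(self):
        model = _model_one_random(np.array([[0.5, 0.0], [0.0, 0.25]]), levels=1)
        layout = build_layout(model)
        pb = build_preconditioner([], model, layout)  # block [[2,0],[0,4]]
        inv = invert_preconditioner(pb, model)
        np.testing.assert_allclose(
            apply_preconditioner(inv, np.array([2.0, 4.0])), [1.0, 1.0]
        )

    def test_matches_dense_block_diagonal_multiply(self, rng):
        table, model, layout, designs, op, C = _setup(rng)
        pb = invert_preconditioner(build_preconditioner(designs, model, layout), model)
        dense = np.zeros((layout.n_equations, layout.n_equations))
        for ei, arr in enumerate(pb.blocks):
            off = layout.offsets[ei]
            nb, s, _ = arr.shape
            for k in range(nb):
                st = off + k * s
                dense[st : st + s, st : st + s] = arr[k]
        r = rng.standard_normal(layout.n_equations)
        np.testing.assert_allclose(apply_preconditioner(pb, r), dense @ r, atol=1e-10)


class TestIodMatvec:
    def test_zero_vector(self, rng):
        *_, op, C = _setup(rng)
        np.testing.assert_allclose(iod_matvec(op, np.zeros(op.n_equations)), 0.0)

    def test_single_record_identity_residual_mean_only(self):
        model = ModelSpec(
            trait_names=["y"],
            effects=[ResolvedEffect(name="mean", kind="fixed_class", n_levels=1)],
            residual_covs={1: np.eye(1)},
        )
        layout = build_layout(model)
        table = PhenotypeTable(y=np.array([[3.0]]), trait_names=["y"])
        designs = build_designs(table, model, layout)
        op = build_operator(designs, model, layout)
        np.testing.assert_allclose(iod_matvec(op, np.array([1.0])), [1.0])

    def test_matches_dense_oracle_many_directions(self, rng):
        table, model, layout, designs, op, C = _setup(rng)
        for _ in range(20):
            d = rng.standard_normal(layout.n_equations)
            v = iod_matvec(op, d)
            ref = C @ d
            assert np.linalg.norm(v - ref) <= 1e-8 * max(np.linalg.norm(ref), 1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        *_, op, C = _setup(rng)
        with pytest.raises(DimensionError):
            iod_matvec(op, np.zeros(op.n_equations + 1))

    def test_partition_invariance(self, rng):
        table, model, layout, designs, op, C = _setup(rng)
        d = rng.standard_normal(layout.n_equations)
        results = []
        for workers in (1, 2, 4, 8):
            part = make_partition(
                table.q,
                [np.ones(L) for _, L, _, _, _ in op.random_terms],
                workers,
            )
            results.append(iod_matvec(op, d, part))
        for a, b in itertools.combinations(results, 2):
            assert np.abs(a - b).max() < 1e-10


class TestConvergenceValue:
    def test_exact_solution_gives_zero(self):
        assert convergence_value(np.array([1.0, 2.0]), np.zeros(2)) == 0.0

    def test_zero_start_gives_one(self, rng):
        b = rng.standard_normal(5)
        assert convergence_value(b, b) == pytest.approx(1.0)

    def test_homogeneity(self, rng):
        b = rng.standard_normal(5)
        assert convergence_value(b, b / 2) == pytest.approx(0.5)

    def test_zero_rhs_rejected(self):
        with pytest.raises(DegenerateInputError):
            convergence_value(np.zeros(3), np.zeros(3))


class TestMakePartition:
    def test_single_worker(self):
        part = make_partition(10, [], 1)
        assert part.record_ranges == [(0, 10)]

    def test_even_split(self):
        part = make_partition(10, [], 3)
        sizes = sorted(hi - lo for lo, hi in part.record_ranges)
        assert sizes == [3, 3, 4]

    def test_weighted_levels_match_brute_force_optimum(self):
        weights = np.array([8.0, 1.0, 1.0, 8.0])
        part = make_partition(4, [weights], 2)
        got = max(weights[lo:hi].sum() for lo, hi in part.level_ranges[0])
        # brute force over all contiguous 2-way splits
        best = min(
            max(weights[:cut].sum(), weights[cut:].sum()) for cut in range(1, 4)
        )
        assert got == pytest.approx(best)

    def test_workers_clamped_to_records(self, caplog):
        with caplog.at_level("WARNING"):
            part = make_partition(3, [], 8)
        assert part.workers == 3


class TestPcgSolve:
    def test_identity_system_converges_first_round(self, rng):
        model = _model_one_random(np.array([[1.0]]), levels=5)
        layout = build_layout(model)
        op = build_operator([], model, layout)
        pb = PreconditionerBlocks.identity(layout)
        b = rng.standard_normal(5)
        res = pcg_solve(op, pb, b, tolerance=1e-13)
        assert res.status == "converged"
        assert res.rounds == 1
        np.testing.assert_allclose(res.x, b, atol=1e-12)

    def test_matches_dense_solve_on_toy_gblup(self, rng):
        table, model, layout, designs, op = _gblup_case(rng)
        C = build_dense_C(designs, model, layout)
        b = build_rhs(designs, layout.n_equations)
        pb = invert_preconditioner(build_preconditioner(designs, model, layout), model)
        res = pcg_solve(op, pb, b, tolerance=1e-13, max_rounds=5000)
        assert res.status == "converged"
        xd = np.linalg.solve(C, b)
        assert np.linalg.norm(res.x - xd) / np.linalg.norm(xd) < 1e-6

    def test_block_preconditioner_not_slower_than_identity(self, rng):
        table, model, layout, designs, op = _gblup_case(rng)
        b = build_rhs(designs, layout.n_equations)
        pb = invert_preconditioner(build_preconditioner(designs, model, layout), model)
        res_block = pcg_solve(op, pb, b, tolerance=1e-10, max_rounds=5000)
        res_ident = pcg_solve(
            op, PreconditionerBlocks.identity(layout), b,
            tolerance=1e-10, max_rounds=5000,
        )
        assert res_block.rounds <= res_ident.rounds

    def test_refresh_agrees_with_recursion(self, rng):
        table, model, layout, designs, op = _gblup_case(rng)
        b = build_rhs(designs, layout.n_equations)
        pb = invert_preconditioner(build_preconditioner(designs, model, layout), model)
        res = pcg_solve(
            op, pb, b, tolerance=1e-13, max_rounds=500, refresh_interval=10
        )
        assert res.refresh_gaps  # at least one refresh happened
        for _, gap in res.refresh_gaps:
            assert gap < 1e-6

    def test_converged_exit_satisfies_tolerance(self, rng):
        table, model, layout, designs, op = _gblup_case(rng)
        b = build_rhs(designs, layout.n_equations)
        pb = invert_preconditioner(build_preconditioner(designs, model, layout), model)
        res = pcg_solve(op, pb, b, tolerance=1e-11)
        assert res.status == "converged" and res.c <= 1e-11
        assert res.trace[-1] == res.c

    def test_max_rounds_status(self, rng):
        table, model, layout, designs, op = _gblup_case(rng)
        b = build_rhs(designs, layout.n_equations)
        pb = invert_preconditioner(build_preconditioner(designs, model, layout), model)
        res = pcg_solve(op, pb, b, tolerance=1e-13, max_rounds=2)
        assert res.status == "max_rounds" and res.rounds == 2

    def test_error_energy_norm_decreases_monotonically(self, rng):
        # CG minimizes the C-norm of the error over growing Krylov spaces,
        # so ‖x_k − x*‖_C must fall every round on an SPD system
        table, model, layout, designs, op = _gblup_case(rng)
        C = build_dense_C(designs, model, layout)
        b = build_rhs(designs, layout.n_equations)
        x_star = np.linalg.solve(C, b)
        pbi = invert_preconditioner(build_preconditioner(designs, model, layout), model)
        x = np.zeros_like(b)
        r = b.copy()
        z = apply_preconditioner(pbi, r)
        d = z.copy()
        rz = float(r @ z)
        energies = [float((x - x_star) @ C @ (x - x_star))]
        for _ in range(30):
            v = iod_matvec(op, d)
            step = rz / float(d @ v)
            x += step * d
            r = r - step * v
            z = apply_preconditioner(pbi, r)
            rz_new = float(r @ z)
            energies.append(float((x - x_star) @ C @ (x - x_star)))
            d = z + (rz_new / rz) * d
            rz = rz_new
        assert all(b < a * (1 + 1e-10) for a, b in zip(energies, energies[1:]))

    def test_solution_partition_invariant(self, rng):
        table, model, layout, designs, op = _gblup_case(rng, t=2)
        b = build_rhs(designs, layout.n_equations)
        pb = invert_preconditioner(build_preconditioner(designs, model, layout), model)
        sols = []
        for workers in (1, 2, 4, 8):
            part = make_partition(
                table.q, [np.ones(L) for _, L, _, _, _ in op.random_terms], workers
            )
            sols.append(pcg_solve(op, pb, b, tolerance=1e-12, partition=part).x)
        for a, bb in itertools.combinations(sols, 2):
            assert np.abs(a - bb).max() < 1e-10
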