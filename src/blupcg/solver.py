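"""Matrix-free preconditioned conjugate gradient for the MME.

The coefficient matrix ``C`` is never stored: each product ``C·d`` is
computed by *iteration on data* — streaming the per-record design vectors
for the least-squares part (``Σ_j w_j R_j⁻¹ w_j' d``, evaluated right to
left) and applying ``(K⁻¹⊗I)(I⊗G₀⁻¹)d`` per random effect.

The preconditioner ``M`` is block diagonal with one dense ``t×t`` trait
block per (level, coefficient) pair of each effect; its inverse is obtained
by inverting each block.  Convergence is monitored with the relative
residual ``c = ‖b − Cx‖₂ / ‖b‖₂``, tracked through the PCG residual
recursion and refreshed with the exact formula ``r = b − Cx`` every
``refresh_interval`` rounds to purge accumulated rounding error.

Work can be partitioned across notional workers (contiguous record ranges
and level ranges).  Partial sums are combined in worker-index order, so the
result is reproducible and agrees across worker counts to ~1e−10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, DimensionError, NumericalError
from .model import (
    EquationLayout,
    MmeOperator,
    ModelSpec,
    RecordDesign,
    VarianceComponents,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreconditionerBlocks",
    "Partition",
    "PcgResult",
    "build_preconditioner",
    "invert_preconditioner",
    "apply_preconditioner",
    "make_partition",
    "iod_matvec",
    "convergence_value",
    "pcg_solve",
]


# ---------------------------------------------------------------------------
# preconditioner
# ---------------------------------------------------------------------------

@dataclass
class PreconditionerBlocks:
    """Dense trait blocks of the block-diagonal preconditioner.

    ``blocks[i]`` stacks the (level × coefficient) blocks of effect ``i``
    as an array of shape ``(n_levels·n_coef, t_eff, t_eff)``, aligned with
    the trait-consecutive equation layout.
    """

    layout: EquationLayout
    blocks: list[np.ndarray]
    inverted: bool = False

    @classmethod
    def identity(cls, layout: EquationLayout) -> "PreconditionerBlocks":
        blocks = []
        for L, ncoef, t_eff in layout.effect_dims:
            blocks.append(np.tile(np.eye(t_eff), (L * ncoef, 1, 1)))
        return cls(layout, blocks, inverted=True)


def build_preconditioner(
    designs: list[RecordDesign],
    model: ModelSpec,
    layout: EquationLayout,
    varcomp: VarianceComponents | None = None,
) -> PreconditionerBlocks:
    """Assemble M: the trait-diagonal blocks of the coefficient matrix.

    Two tasks contribute, mirroring the partition of ``C``: per-record
    least-squares additions (only positions inside a block receive them)
    and, per level of each random effect, the diagonal kinship entry times
    the coefficient-diagonal blocks of ``G₀⁻¹``.
    """
    if varcomp is None:
        varcomp = VarianceComponents.from_model(model)
    blocks = [
        np.zeros((L * ncoef, t_eff, t_eff)) for L, ncoef, t_eff in layout.effect_dims
    ]

    # map equation index -> (effect, block index within effect, position in block)
    n = layout.n_equations
    eq_eff = np.empty(n, dtype=np.int64)
    eq_blk = np.empty(n, dtype=np.int64)
    eq_pos = np.empty(n, dtype=np.int64)
    for ei, (L, ncoef, t_eff) in enumerate(layout.effect_dims):
        off = layout.offsets[ei]
        dim = L * ncoef * t_eff
        rel = np.arange(dim)
        eq_eff[off : off + dim] = ei
        eq_blk[off : off + dim] = rel // t_eff
        eq_pos[off : off + dim] = rel % t_eff

    # task 1: per-record least-squares additions
    for ds in designs:
        k = len(ds.eq)
        if k == 0:
            continue
        a = np.repeat(np.arange(k), k)
        bb = np.tile(np.arange(k), k)
        ea, eb = ds.eq[a], ds.eq[bb]
        same = (eq_eff[ea] == eq_eff[eb]) & (eq_blk[ea] == eq_blk[eb])
        a, bb, ea, eb = a[same], bb[same], ea[same], eb[same]
        vals = ds.val[a] * ds.val[bb] * ds.r_inv[ds.slot[a], ds.slot[bb]]
        for ei in np.unique(eq_eff[ea]):
            m = eq_eff[ea] == ei
            np.add.at(
                blocks[ei],
                (eq_blk[ea[m]], eq_pos[ea[m]], eq_pos[eb[m]]),
                vals[m],
            )

    # task 2: per-level kinship ⊗ covariance additions
    for ei, eff in enumerate(model.effects):
        if eff.kind != "random":
            continue
        L, ncoef, t_eff = layout.effect_dims[ei]
        kdiag = (
            np.ones(L)
            if eff.kinship_inv is None
            else np.asarray(eff.kinship_inv.matrix.diagonal())
        )
        g0_inv = varcomp.g0_inv[eff.name]
        coef_blocks = g0_inv.reshape(ncoef, t_eff, ncoef, t_eff)
        cdiag = np.stack([coef_blocks[c, :, c, :] for c in range(ncoef)])
        blocks[ei] += np.einsum("l,cij->lcij", kdiag, cdiag).reshape(
            L * ncoef, t_eff, t_eff
        )
    return PreconditionerBlocks(layout, blocks, inverted=False)


def invert_preconditioner(pb: PreconditionerBlocks, model: ModelSpec | None = None) -> PreconditionerBlocks:
    """Invert each diagonal block; exactly-zero blocks become identity.

    Zero blocks arise for equations with neither data nor prior (e.g. an
    unobserved fixed-effect level); substituting the identity leaves their
    solutions at zero.  A singular nonzero block raises, naming the effect
    and level.
    """
    inv_blocks: list[np.ndarray] = []
    n_zero = 0
    for ei, arr in enumerate(pb.blocks):
        out = np.empty_like(arr)
        zero = np.all(arr == 0.0, axis=(1, 2))
        n_zero += int(zero.sum())
        out[zero] = np.eye(arr.shape[1])
        nz = np.flatnonzero(~zero)
        for b in nz:
            try:
                out[b] = np.linalg.inv(arr[b])
            except np.linalg.LinAlgError as exc:
                _, ncoef, _ = pb.layout.effect_dims[ei]
                name = model.effects[ei].name if model is not None else f"effect {ei}"
                raise NumericalError(
                    f"singular preconditioner block for {name}, "
                    f"level {b // ncoef + 1}, coefficient {b % ncoef}"
                ) from exc
        inv_blocks.append(out)
    if n_zero:
        logger.warning(
            "%d zero preconditioner blocks replaced by identity "
            "(equations with no data and no prior)",
            n_zero,
        )
    return PreconditionerBlocks(pb.layout, inv_blocks, inverted=True)


def apply_preconditioner(pb: PreconditionerBlocks, r: np.ndarray) -> np.ndarray:
    """Blockwise product M⁻¹·r (equals the dense block-diagonal multiply)."""
    if len(r) != pb.layout.n_equations:
        raise DimensionError("vector length does not match the equation layout")
    out = np.empty_like(r)
    for ei, arr in enumerate(pb.blocks):
        nb, s, _ = arr.shape
        off = pb.layout.offsets[ei]
        seg = r[off : off + nb * s].reshape(nb, s)
        out[off : off + nb * s] = np.einsum("bij,bj->bi", arr, seg).ravel()
    return out


# ---------------------------------------------------------------------------
# work partitioning
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """Contiguous record and level ranges assigned to notional workers."""

    workers: int
    record_ranges: list[tuple[int, int]]
    level_ranges: list[list[tuple[int, int]]] = field(default_factory=list)


def _balanced_contiguous(weights: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Split weights into ≤k contiguous ranges minimizing the max range sum."""
    n = len(weights)
    if n == 0:
        return [(0, 0)] * k
    if k >= n:
        return [(i, i + 1) for i in range(n)] + [(n, n)] * (k - n)

    def feasible(cap: float) -> list[tuple[int, int]] | None:
        ranges = []
        start, acc = 0, 0.0
        for i, w in enumerate(weights):
            if w > cap:
                return None
            if acc + w > cap and i > start:
                ranges.append((start, i))
                start, acc = i, 0.0
            acc += w
        ranges.append((start, n))
        if len(ranges) > k:
            return None
        return ranges + [(n, n)] * (k - len(ranges))

    lo, hi = float(np.max(weights)), float(np.sum(weights))
    best = feasible(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = feasible(mid)
        if r is None:
            lo = mid
        else:
            hi, best = mid, r
        if hi - lo <= 1e-9 * max(1.0, hi):
            break
    return best


def make_partition(
    q: int, level_weights: list[np.ndarray], workers: int
) -> Partition:
    """Assign contiguous record and level ranges to workers.

    Record ranges differ in length by at most one; level ranges of each
    random effect are balanced by their weight (nonzero counts of the
    kinship inverse rows).
    """
    if workers < 1:
        raise DimensionError("worker count must be ≥ 1")
    if q > 0 and workers > q:
        logger.warning("workers (%d) exceed records (%d); clamping", workers, q)
        workers = q
    base, rem = divmod(q, workers)
    record_ranges = []
    start = 0
    for wkr in range(workers):
        size = base + (1 if wkr < rem else 0)
        record_ranges.append((start, start + size))
        start += size
    level_ranges = [
        _balanced_contiguous(np.asarray(w, dtype=np.float64), workers)
        for w in level_weights
    ]
    return Partition(workers, record_ranges, level_ranges)


# ---------------------------------------------------------------------------
# iteration-on-data products
# ---------------------------------------------------------------------------

def iod_matvec(
    op: MmeOperator, d: np.ndarray, partition: Partition | None = None
) -> np.ndarray:
    """Compute ``v = C·d`` by streaming data; ``C`` is never materialized.

    Least-squares part per worker range: ``t1 = W d``, ``t2 = R⁻¹ t1``,
    ``t = W' t2`` (right to left); worker partials are summed in
    worker-index order.  Random part per effect: ``s1 = (I⊗G₀⁻¹)d`` then
    ``s = (K⁻¹⊗I)s1``; kinship rows are computed independently, so level
    partitioning cannot change the result.
    """
    d = np.asarray(d, dtype=np.float64)
    if d.shape != (op.n_equations,):
        raise DimensionError(
            f"vector length {d.shape} does not match {op.n_equations} equations"
        )
    v = np.zeros(op.n_equations)
    ranges = partition.record_ranges if partition is not None else [(0, op.q)]
    for Wk, Rk in op.record_slices(ranges):
        t1 = Wk @ d
        t2 = Rk @ t1
        v += Wk.T @ t2
    for off, L, p, K, g0_inv in op.random_terms:
        db = d[off : off + L * p].reshape(L, p)
        s1 = db @ g0_inv
        s = s1 if K is None else K @ s1
        v[off : off + L * p] += s.ravel()
    return v


# ---------------------------------------------------------------------------
# PCG
# ---------------------------------------------------------------------------

def convergence_value(b: np.ndarray, r_current: np.ndarray) -> float:
    """Relative residual ``c = ‖r‖₂ / ‖b‖₂`` (with r approximating b − Cx)."""
    nb = float(np.linalg.norm(b))
    if nb == 0.0:
        raise DegenerateInputError("right-hand side is zero: nothing to solve")
    return float(np.linalg.norm(r_current)) / nb


@dataclass
class PcgResult:
    """Outcome of a PCG solve, including the per-round convergence trace."""

    x: np.ndarray
    c: float
    rounds: int
    status: str  # converged | max_rounds
    trace: list[float]
    refresh_gaps: list[tuple[int, float]] = field(default_factory=list)


def pcg_solve(
    op: MmeOperator,
    blocks_inv: PreconditionerBlocks,
    b: np.ndarray,
    tolerance: float = 1e-13,
    max_rounds: int = 5000,
    refresh_interval: int = 100,
    partition: Partition | None = None,
) -> PcgResult:
    """Preconditioned conjugate gradient with periodic exact residual refresh.

    Starts from ``x₀ = 0`` (so ``c`` starts at exactly 1).  One coefficient
    product and one preconditioner application per round; the residual is
    updated by the recursion ``r ← r − α v`` except on rounds that are
    multiples of ``refresh_interval``, where the exact ``r = b − Cx`` is
    computed (one extra product) and the recursion/exact gap is recorded.
    """
    if tolerance <= 0:
        raise DimensionError("tolerance must be positive")
    if refresh_interval < 1:
        raise DimensionError("refresh_interval must be ≥ 1")
    b = np.asarray(b, dtype=np.float64)
    norm_b = float(np.linalg.norm(b))
    x = np.zeros_like(b)
    r = b.copy()
    c = convergence_value(b, r)  # exactly 1 at the zero start
    trace: list[float] = []
    refresh_gaps: list[tuple[int, float]] = []
    if c <= tolerance:  # degenerate but well-defined
        return PcgResult(x, c, 0, "converged", trace, refresh_gaps)
    z = apply_preconditioner(blocks_inv, r)
    d = z.copy()
    rz = float(r @ z)
    status = "max_rounds"
    rounds = 0
    for k in range(1, max_rounds + 1):
        rounds = k
        v = iod_matvec(op, d, partition)
        dv = float(d @ v)
        if not np.isfinite(dv) or dv == 0.0:
            raise NumericalError(f"PCG breakdown at round {k}: d'Cd = {dv}")
        step = rz / dv
        x += step * d
        if k % refresh_interval == 0:
            r_rec = r - step * v
            r = b - iod_matvec(op, x, partition)
            refresh_gaps.append((k, float(np.linalg.norm(r_rec - r)) / norm_b))
        else:
            r = r - step * v
        c = convergence_value(b, r)
        trace.append(c)
        if not np.isfinite(c):
            raise NumericalError(f"PCG diverged at round {k}: c = {c}")
        if c <= tolerance:
            status = "converged"
            break
        z = apply_preconditioner(blocks_inv, r)
        rz_new = float(r @ z)
        beta = rz_new / rz
        rz = rz_new
        d = z + beta * d
    return PcgResult(x, c, rounds, status, trace, refresh_gaps)
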