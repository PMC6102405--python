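"""Mixed model equations for multi-trait genetic evaluation.

Translates a model specification plus phenotype records into the MME

    [ X'R⁻¹X          X'R⁻¹Z                ] [f]   [X'R⁻¹y]
    [ Z'R⁻¹X   Z'R⁻¹Z + K⁻¹ ⊗ G₀⁻¹          ] [u] = [Z'R⁻¹y]

without ever assembling the coefficient matrix ``C`` in production: records
are translated into sparse per-record design vectors (the least-squares
part) and random effects contribute Kronecker products of a kinship inverse
``K⁻¹`` with the effect-covariance inverse ``G₀⁻¹``.

Equation ordering is *trait-consecutive*: within an effect, equations are
level-major, then regression coefficient, with the trait index innermost,
so the t×t trait blocks used by the preconditioner are contiguous.

Missing traits are handled per record by restricting the residual
covariance ``R`` to the observed traits before inversion; a record weight
multiplies the restricted inverse (i.e. divides the residual variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numpy.polynomial import legendre as npleg

from .exceptions import (
    ConfigurationError,
    DataError,
    DimensionError,
    NumericalError,
)
from .kinship import RelationshipInverse

__all__ = [
    "PhenotypeTable",
    "ResolvedEffect",
    "ModelSpec",
    "VarianceComponents",
    "EquationLayout",
    "RecordDesign",
    "MmeOperator",
    "legendre_basis",
    "build_layout",
    "record_residual_inverse",
    "build_record_design",
    "build_designs",
    "build_rhs",
    "build_dense_C",
    "build_operator",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Renumbered phenotype records.

    ``y`` is (q, t) with ``NaN`` marking a missing trait; categorical
    columns hold 1-based consecutive level codes; every record must have at
    least one observed trait.
    """

    y: np.ndarray
    trait_names: list[str]
    class_codes: dict[str, np.ndarray] = field(default_factory=dict)
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    weights: np.ndarray | None = None
    residual_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=np.float64))
        if self.y.shape[1] != len(self.trait_names):
            raise DimensionError("trait count does not match observation columns")
        if np.any(np.all(np.isnan(self.y), axis=1)):
            raise DataError("a record has no observed trait")
        if self.weights is None:
            self.weights = np.ones(self.q)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights <= 0):
            raise DataError("record weights must be strictly positive")
        if self.residual_class is None:
            self.residual_class = np.ones(self.q, dtype=np.int64)
        self.residual_class = np.asarray(self.residual_class, dtype=np.int64)

    @property
    def q(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_traits(self) -> int:
        return int(self.y.shape[1])


@dataclass
class ResolvedEffect:
    """One model effect with its levels and (for random effects) covariance.

    ``level_column`` names the categorical column giving the level of each
    record (``None`` means a single level, e.g. an overall mean).  For
    regressions, ``covariate_column`` names the covariable; if ``legendre``
    is set to ``(order, t_min, t_max)`` the covariable is expanded into
    ``order+1`` normalized Legendre basis values, otherwise the raw value is
    the single regression covariable.  ``traits`` restricts the effect to a
    subset of traits (``None`` = all).
    """

    name: str
    kind: str  # fixed_class | fixed_regression | random
    n_levels: int
    level_column: str | None = None
    covariate_column: str | None = None
    legendre: tuple[int, float, float] | None = None
    traits: list[str] | None = None
    kinship_inv: RelationshipInverse | None = None  # None → identity
    covariance: np.ndarray | None = None
    level_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_class", "fixed_regression", "random"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.n_levels < 1:
            raise ConfigurationError(f"effect {self.name!r} has no levels")
        if self.kind != "fixed_class" and self.covariate_column is None and (
            self.legendre is not None
        ):
            raise ConfigurationError(
                f"effect {self.name!r}: a Legendre regression needs a covariate column"
            )
        if self.covariance is not None:
            self.covariance = np.asarray(self.covariance, dtype=np.float64)

    @property
    def n_coef(self) -> int:
        if self.legendre is not None:
            return self.legendre[0] + 1
        return 1

    def trait_idx(self, trait_names: list[str]) -> np.ndarray:
        if self.traits is None:
            return np.arange(len(trait_names))
        try:
            return np.array([trait_names.index(t) for t in self.traits])
        except ValueError as exc:
            raise ConfigurationError(
                f"effect {self.name!r} names a trait not in the model"
            ) from exc


@dataclass
class ModelSpec:
    """Traits, effects and residual covariances defining one evaluation."""

    trait_names: list[str]
    effects: list[ResolvedEffect]
    residual_covs: dict[int, np.ndarray]  # residual class code → t×t R
    weight_column: str | None = None

    def __post_init__(self) -> None:
        t = len(self.trait_names)
        if not self.effects:
            raise ConfigurationError("model has no effects")
        for code, R in self.residual_covs.items():
            R = np.asarray(R, dtype=np.float64)
            if R.shape != (t, t):
                raise ConfigurationError(
                    f"residual covariance for class {code} is not {t}×{t}"
                )
            self.residual_covs[code] = 0.5 * (R + R.T)
        for eff in self.effects:
            t_eff = len(eff.trait_idx(self.trait_names))
            if eff.kind == "random":
                p = eff.n_coef * t_eff
                if eff.covariance is None or eff.covariance.shape != (p, p):
                    raise ConfigurationError(
                        f"random effect {eff.name!r} needs a covariance of order {p}"
                    )
                if eff.kinship_inv is not None and eff.kinship_inv.order != eff.n_levels:
                    raise DimensionError(
                        f"kinship inverse order {eff.kinship_inv.order} does not "
                        f"match the {eff.n_levels} levels of effect {eff.name!r}"
                    )


@dataclass
class VarianceComponents:
    """Inverted (co)variance matrices, verified against their inputs."""

    g0: dict[str, np.ndarray]
    g0_inv: dict[str, np.ndarray]
    residual: dict[int, np.ndarray]

    @classmethod
    def from_model(cls, model: ModelSpec) -> "VarianceComponents":
        g0: dict[str, np.ndarray] = {}
        g0_inv: dict[str, np.ndarray] = {}
        for eff in model.effects:
            if eff.kind != "random":
                continue
            cov = eff.covariance
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(
                    f"covariance of effect {eff.name!r} is not positive definite"
                ) from exc
            inv = np.linalg.inv(cov)
            if not np.allclose(cov @ inv, np.eye(cov.shape[0]), atol=1e-8):
                raise NumericalError(
                    f"covariance inverse of effect {eff.name!r} failed verification"
                )
            g0[eff.name] = cov
            g0_inv[eff.name] = 0.5 * (inv + inv.T)
        for code, R in model.residual_covs.items():
            try:
                np.linalg.cholesky(R)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(
                    f"residual covariance for class {code} is not positive definite"
                ) from exc
        return cls(g0=g0, g0_inv=g0_inv, residual=dict(model.residual_covs))


# ---------------------------------------------------------------------------
# equation layout
# ---------------------------------------------------------------------------

@dataclass
class EquationLayout:
    """Index map from (effect, level, coefficient, trait) to equations.

    Also carries the trait-block partition used by the block-diagonal
    preconditioner: one ``t_eff × t_eff`` block per (level, coefficient)
    pair of each effect.
    """

    n_equations: int
    offsets: list[int]
    effect_dims: list[tuple[int, int, int]]  # (n_levels, n_coef, t_eff)
    trait_count: int
    block_start: np.ndarray = field(repr=False, default=None)
    block_size: np.ndarray = field(repr=False, default=None)
    block_effect: np.ndarray = field(repr=False, default=None)

    def eq_index(self, effect_i: int, level: int, coef: int, trait_pos: int) -> int:
        """Equation of (effect, 1-based level, coefficient, within-effect trait)."""
        L, c, t_eff = self.effect_dims[effect_i]
        return self.offsets[effect_i] + ((level - 1) * c + coef) * t_eff + trait_pos

    @property
    def n_blocks(self) -> int:
        return len(self.block_start)


def build_layout(model: ModelSpec) -> EquationLayout:
    """Lay out equations: fixed then random effects, traits innermost."""
    offsets: list[int] = []
    dims: list[tuple[int, int, int]] = []
    total = 0
    starts: list[np.ndarray] = []
    sizes: list[np.ndarray] = []
    beff: list[np.ndarray] = []
    for i, eff in enumerate(model.effects):
        t_eff = len(eff.trait_idx(model.trait_names))
        offsets.append(total)
        dims.append((eff.n_levels, eff.n_coef, t_eff))
        nb = eff.n_levels * eff.n_coef
        starts.append(total + t_eff * np.arange(nb, dtype=np.int64))
        sizes.append(np.full(nb, t_eff, dtype=np.int64))
        beff.append(np.full(nb, i, dtype=np.int64))
        total += nb * t_eff
    return EquationLayout(
        n_equations=total,
        offsets=offsets,
        effect_dims=dims,
        trait_count=len(model.trait_names),
        block_start=np.concatenate(starts),
        block_size=np.concatenate(sizes),
        block_effect=np.concatenate(beff),
    )


# ---------------------------------------------------------------------------
# Legendre covariables
# ---------------------------------------------------------------------------

def legendre_basis(
    time: float | np.ndarray, t_min: float, t_max: float, order: int
) -> np.ndarray:
    """Normalized Legendre basis values at a standardized time point.

    The time is mapped to ``x = 2(time − t_min)/(t_max − t_min) − 1`` and
    the basis is ``φ_k(x) = √((2k+1)/2) P_k(x)`` for ``k = 0..order``.
    """
    if t_min >= t_max:
        raise ConfigurationError("Legendre range needs t_min < t_max")
    tarr = np.asarray(time, dtype=np.float64)
    if np.any(tarr < t_min) or np.any(tarr > t_max):
        raise DataError(f"time {time} outside Legendre range [{t_min}, {t_max}]")
    x = 2.0 * (tarr - t_min) / (t_max - t_min) - 1.0
    van = npleg.legvander(np.atleast_1d(x), order)
    phi = van * np.sqrt((2.0 * np.arange(order + 1) + 1.0) / 2.0)
    return phi[0] if np.ndim(time) == 0 else phi


# ---------------------------------------------------------------------------
# per-record translation
# ---------------------------------------------------------------------------

@dataclass
class RecordDesign:
    """Sparse design of one record: W_j entries, R_j⁻¹ and observations.

    ``eq``/``slot``/``val`` are parallel arrays giving, for each nonzero of
    the (equations × observed traits) design matrix ``W_j``, the equation
    row, the observed-trait column and the design value.
    """

    eq: np.ndarray
    slot: np.ndarray
    val: np.ndarray
    r_inv: np.ndarray
    y: np.ndarray
    observed: np.ndarray


def record_residual_inverse(
    R: np.ndarray, observed: np.ndarray, weight: float = 1.0
) -> np.ndarray:
    """Weighted inverse of the residual covariance on the observed traits.

    Missing traits are dropped by restricting ``R`` before inversion; the
    record weight multiplies the inverse (equivalently divides the residual
    variance).
    """
    observed = np.asarray(observed, dtype=np.int64)
    if observed.size == 0:
        raise DataError("a record must observe at least one trait")
    if weight <= 0:
        raise DataError("record weight must be strictly positive")
    sub = np.asarray(R, dtype=np.float64)[np.ix_(observed, observed)]
    try:
        np.linalg.cholesky(sub)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "restricted residual covariance is not positive definite"
        ) from exc
    inv = np.linalg.inv(sub)
    return weight * 0.5 * (inv + inv.T)


def build_record_design(
    j: int,
    table: PhenotypeTable,
    model: ModelSpec,
    layout: EquationLayout,
    _rinv_cache: dict | None = None,
) -> RecordDesign:
    """Translate record ``j`` into its sparse design vector and R_j⁻¹."""
    yj = table.y[j]
    observed = np.flatnonzero(~np.isnan(yj))
    key = (int(table.residual_class[j]), tuple(observed))
    if _rinv_cache is not None and key in _rinv_cache:
        base_inv = _rinv_cache[key]
    else:
        code = int(table.residual_class[j])
        if code not in model.residual_covs:
            raise DataError(f"record {j}: no residual covariance for class {code}")
        base_inv = record_residual_inverse(model.residual_covs[code], observed, 1.0)
        if _rinv_cache is not None:
            _rinv_cache[key] = base_inv
    r_inv = float(table.weights[j]) * base_inv

    slot_of_trait = {int(g): s for s, g in enumerate(observed)}
    eqs: list[int] = []
    slots: list[int] = []
    vals: list[float] = []
    for ei, eff in enumerate(model.effects):
        L, ncoef, t_eff = layout.effect_dims[ei]
        if eff.level_column is not None:
            col = table.class_codes.get(eff.level_column)
            if col is None:
                raise DataError(f"phenotypes lack class column {eff.level_column!r}")
            lvl = int(col[j])
            if not 1 <= lvl <= L:
                raise DataError(
                    f"record {j}: level code {lvl} of effect {eff.name!r} "
                    f"outside 1..{L}"
                )
        else:
            lvl = 1
        if eff.covariate_column is not None:
            cov_col = table.covariates.get(eff.covariate_column)
            if cov_col is None:
                raise DataError(
                    f"phenotypes lack covariate column {eff.covariate_column!r}"
                )
            cval = float(cov_col[j])
            if np.isnan(cval):
                raise DataError(
                    f"record {j}: missing covariate {eff.covariate_column!r} "
                    f"for effect {eff.name!r}"
                )
            if eff.legendre is not None:
                order, lo, hi = eff.legendre
                coef_vals = legendre_basis(cval, lo, hi, order)
            else:
                coef_vals = np.array([cval])
        else:
            coef_vals = np.array([1.0])
        tidx = eff.trait_idx(model.trait_names)
        for c, v in enumerate(coef_vals):
            base = layout.eq_index(ei, lvl, c, 0)
            for pos, g in enumerate(tidx):
                s = slot_of_trait.get(int(g))
                if s is not None:
                    eqs.append(base + pos)
                    slots.append(s)
                    vals.append(float(v))
    return RecordDesign(
        eq=np.asarray(eqs, dtype=np.int64),
        slot=np.asarray(slots, dtype=np.int64),
        val=np.asarray(vals, dtype=np.float64),
        r_inv=r_inv,
        y=yj[observed],
        observed=observed,
    )


def build_designs(
    table: PhenotypeTable, model: ModelSpec, layout: EquationLayout
) -> list[RecordDesign]:
    cache: dict = {}
    return [
        build_record_design(j, table, model, layout, _rinv_cache=cache)
        for j in range(table.q)
    ]


# ---------------------------------------------------------------------------
# right-hand side and dense oracle
# ---------------------------------------------------------------------------

def build_rhs(designs: list[RecordDesign], n_equations: int) -> np.ndarray:
    """Accumulate ``b = Σ_j W_j (R_j⁻¹ y_j)`` record by record."""
    b = np.zeros(n_equations)
    for ds in designs:
        t2 = ds.r_inv @ ds.y
        np.add.at(b, ds.eq, ds.val * t2[ds.slot])
    return b


def build_dense_C(
    designs: list[RecordDesign],
    model: ModelSpec,
    layout: EquationLayout,
    varcomp: VarianceComponents | None = None,
    max_equations: int = 3000,
) -> np.ndarray:
    """Dense assembly of the MME coefficient matrix (test oracle only).

    Sums per-record outer products ``W_j R_j⁻¹ W_j'`` and adds, per random
    effect, ``K⁻¹ ⊗ G₀⁻¹`` mapped onto the layout (kinship index major,
    covariance index minor).  Refuses systems larger than
    ``max_equations`` — production solves never materialize ``C``.
    """
    n = layout.n_equations
    if n > max_equations:
        raise DimensionError(
            f"dense oracle refused: {n} equations exceed the {max_equations} guard"
        )
    if varcomp is None:
        varcomp = VarianceComponents.from_model(model)
    C = np.zeros((n, n))
    for ds in designs:
        contrib = np.outer(ds.val, ds.val) * ds.r_inv[np.ix_(ds.slot, ds.slot)]
        np.add.at(C, (ds.eq[:, None], ds.eq[None, :]), contrib)
    for ei, eff in enumerate(model.effects):
        if eff.kind != "random":
            continue
        L, ncoef, t_eff = layout.effect_dims[ei]
        K = (
            np.eye(L)
            if eff.kinship_inv is None
            else eff.kinship_inv.to_dense()
        )
        block = np.kron(K, varcomp.g0_inv[eff.name])
        off = layout.offsets[ei]
        dim = L * ncoef * t_eff
        C[off : off + dim, off : off + dim] += block
    return C


# ---------------------------------------------------------------------------
# matrix-free operator data
# ---------------------------------------------------------------------------

class MmeOperator:
    """Data needed to apply the MME coefficient matrix without storing it.

    The least-squares part is held as a global sparse design ``W`` (stacked
    observed-trait rows × equations) together with the block-diagonal
    ``R⁻¹`` of per-record residual inverses; the random part as one
    ``(K⁻¹, G₀⁻¹)`` pair per random effect.  The actual product (iteration
    on data, right-to-left) lives in :mod:`blupcg.solver`.
    """

    def __init__(
        self,
        layout: EquationLayout,
        W: sp.csr_matrix,
        r_inv_block: sp.csr_matrix,
        y_stacked: np.ndarray,
        record_rows: np.ndarray,
        random_terms: list[tuple[int, int, int, sp.csr_matrix | None, np.ndarray]],
    ) -> None:
        self.layout = layout
        self.W = W
        self.r_inv_block = r_inv_block
        self.y_stacked = y_stacked
        self.record_rows = record_rows  # per-record row offsets into W (q+1,)
        self.random_terms = random_terms  # (offset, L, p, K_inv or None, G0_inv)
        self._slices: dict = {}

    @property
    def n_equations(self) -> int:
        return self.layout.n_equations

    @property
    def q(self) -> int:
        return len(self.record_rows) - 1

    def rhs(self) -> np.ndarray:
        """b = W' R⁻¹ y over all records."""
        return self.W.T @ (self.r_inv_block @ self.y_stacked)

    def record_slices(self, ranges: list[tuple[int, int]]):
        """Cache (W, R⁻¹) row-slices for the record ranges of a partition."""
        key = tuple(ranges)
        if key not in self._slices:
            out = []
            for lo, hi in ranges:
                r0, r1 = int(self.record_rows[lo]), int(self.record_rows[hi])
                out.append(
                    (self.W[r0:r1], self.r_inv_block[r0:r1, r0:r1])
                )
            self._slices[key] = out
        return self._slices[key]


def build_operator(
    designs: list[RecordDesign],
    model: ModelSpec,
    layout: EquationLayout,
    varcomp: VarianceComponents | None = None,
) -> MmeOperator:
    """Assemble the matrix-free operator from per-record designs."""
    if varcomp is None:
        varcomp = VarianceComponents.from_model(model)
    q = len(designs)
    record_rows = np.zeros(q + 1, dtype=np.int64)
    for j, ds in enumerate(designs):
        record_rows[j + 1] = record_rows[j] + len(ds.observed)
    n_rows = int(record_rows[-1])

    w_rows: list[np.ndarray] = []
    w_cols: list[np.ndarray] = []
    w_vals: list[np.ndarray] = []
    r_rows: list[np.ndarray] = []
    r_cols: list[np.ndarray] = []
    r_vals: list[np.ndarray] = []
    y_stacked = np.zeros(n_rows)
    for j, ds in enumerate(designs):
        base = record_rows[j]
        w_rows.append(base + ds.slot)
        w_cols.append(ds.eq)
        w_vals.append(ds.val)
        o = len(ds.observed)
        rr, cc = np.meshgrid(np.arange(o), np.arange(o), indexing="ij")
        r_rows.append(base + rr.ravel())
        r_cols.append(base + cc.ravel())
        r_vals.append(ds.r_inv.ravel())
        y_stacked[base : base + o] = ds.y
    def _cat(parts: list[np.ndarray], dtype) -> np.ndarray:
        return np.concatenate(parts) if parts else np.array([], dtype=dtype)

    W = sp.coo_matrix(
        (_cat(w_vals, float), (_cat(w_rows, np.int64), _cat(w_cols, np.int64))),
        shape=(n_rows, layout.n_equations),
    ).tocsr()
    Rblk = sp.coo_matrix(
        (_cat(r_vals, float), (_cat(r_rows, np.int64), _cat(r_cols, np.int64))),
        shape=(n_rows, n_rows),
    ).tocsr()

    random_terms: list[tuple[int, int, int, sp.csr_matrix | None, np.ndarray]] = []
    for ei, eff in enumerate(model.effects):
        if eff.kind != "random":
            continue
        L, ncoef, t_eff = layout.effect_dims[ei]
        K = None if eff.kinship_inv is None else eff.kinship_inv.matrix
        random_terms.append(
            (layout.offsets[ei], L, ncoef * t_eff, K, varcomp.g0_inv[eff.name])
        )
    return MmeOperator(layout, W, Rblk, y_stacked, record_rows, random_terms)
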