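"""Relationship (kinship) matrices and their inverses.

Builds the pieces a mixed-model genetic evaluation needs:

* the numerator relationship matrix ``A`` from a pedigree (tabular method)
  and its sparse inverse via Henderson's rules with inbreeding
  (Meuwissen–Luo ancestor tracing);
* the genomic relationship matrix ``G`` from SNP allele counts
  (VanRaden method 1), with invertibility safeguards (diagonal loading,
  nearest-positive-definite projection);
* blending/tuning of ``G`` toward the pedigree submatrix ``A22`` of the
  genotyped individuals, so the two matrices are on a compatible scale;
* the single-step hybrid inverse ``H⁻¹`` that combines ``A⁻¹`` with a
  genomic correction on the genotyped block.

All pedigrees are assumed topologically ordered (parents precede
offspring); the I/O layer reorders on read.  Individual indices are
0-based internally; ``-1`` marks an unknown parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

from .exceptions import DegenerateInputError, DimensionError, NumericalError

logger = logging.getLogger(__name__)

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "RelationshipInverse",
    "BlendTuneResult",
    "tabular_A",
    "inbreeding",
    "a_inverse",
    "a22",
    "vanraden_G",
    "nearest_positive_definite",
    "ensure_invertible",
    "blend_tune",
    "h_inverse",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """A topologically ordered pedigree.

    Parameters
    ----------
    sire, dam
        0-based parent index per individual, ``-1`` for unknown.  Both must
        be strictly smaller than the individual's own index.
    labels
        Original identifiers, in pedigree order (optional).
    genotyped
        Indices of genotyped individuals, in genotype-file order (optional).
    """

    sire: np.ndarray
    dam: np.ndarray
    labels: list[str] | None = None
    genotyped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if self.sire.shape != self.dam.shape:
            raise DimensionError("sire and dam arrays differ in length")
        idx = np.arange(self.n)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par >= idx):
                bad = int(np.argmax(par >= idx))
                raise DimensionError(
                    f"{name} of individual {bad} is not earlier in the pedigree; "
                    "pedigree must be topologically ordered"
                )
        if self.genotyped is not None:
            self.genotyped = np.asarray(self.genotyped, dtype=np.int64)

    @property
    def n(self) -> int:
        return int(self.sire.shape[0])

    @property
    def genotyped_mask(self) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        if self.genotyped is not None:
            mask[self.genotyped] = True
        return mask


@dataclass
class GenotypeMatrix:
    """SNP allele counts (0/1/2) for the genotyped individuals.

    ``S`` holds counts of the second allele; missing entries are flagged in
    ``missing`` and the stored value there is arbitrary.  ``p`` is the
    observed second-allele frequency per locus, computed from non-missing
    entries only.
    """

    S: np.ndarray
    missing: np.ndarray | None = None
    labels: list[str] | None = None
    p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        if self.S.ndim != 2:
            raise DimensionError("genotype matrix must be 2-D")
        if self.missing is None:
            self.missing = np.zeros(self.S.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.S.shape:
            raise DimensionError("missing-mask shape differs from genotype matrix")
        with np.errstate(invalid="ignore"):
            Sm = np.where(self.missing, np.nan, self.S)
            counts = np.sum(~self.missing, axis=0)
            psum = np.nansum(Sm, axis=0)
        # loci with no observed genotypes get p = 0 (monomorphic, zero weight)
        self.p = np.where(counts > 0, psum / np.maximum(2 * counts, 1), 0.0)

    @property
    def n_individuals(self) -> int:
        return int(self.S.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.S.shape[1])


@dataclass
class RelationshipInverse:
    """A symmetric (sparse) kinship-matrix inverse of a given order."""

    order: int
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (self.order, self.order):
            raise DimensionError(
                f"matrix shape {self.matrix.shape} does not match order {self.order}"
            )

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    @classmethod
    def identity(cls, order: int) -> "RelationshipInverse":
        return cls(order, sp.identity(order, format="csr"))

    @classmethod
    def from_dense(cls, a: np.ndarray) -> "RelationshipInverse":
        a = np.asarray(a, dtype=np.float64)
        return cls(a.shape[0], sp.csr_matrix(a))


@dataclass
class BlendTuneResult:
    """Outcome of matching G's diagonal/off-diagonal averages to A22's."""

    alpha: float
    beta: float
    g_star: np.ndarray


# ---------------------------------------------------------------------------
# pedigree relationship matrix
# ---------------------------------------------------------------------------

def tabular_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    ``a_ii = 1 + F_i`` with ``F_i`` the inbreeding coefficient (half the
    relationship between the parents); ``a_ij`` for ``j < i`` is the mean of
    the relationships of ``j`` with ``i``'s parents.  Intended as a test
    oracle and for desk-scale ``A22`` extraction, not for large pedigrees.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        rel = np.zeros(i)
        if s >= 0:
            rel += A[:i, s]
        if d >= 0:
            rel += A[:i, d]
        A[:i, i] = A[i, :i] = 0.5 * rel
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def inbreeding(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Inbreeding coefficients and Mendelian-sampling variances.

    Uses ancestor tracing (Meuwissen–Luo): for each individual the diagonal
    ``a_ii = Σ_j L_ij² d_j`` is accumulated over ancestors, where ``L`` is
    the Cholesky path matrix of ``A = L D L'`` and ``d_j`` the within-family
    (Mendelian sampling) variance.  Returns ``(F, d)``.
    """
    n = ped.n
    F = np.zeros(n)
    d = np.ones(n)
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, de = sire[i], dam[i]
        if s >= 0 and de >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[de])
        elif s >= 0:
            d[i] = 0.75 - 0.25 * F[s]
        elif de >= 0:
            d[i] = 0.75 - 0.25 * F[de]
        else:
            d[i] = 1.0
        if s < 0 or de < 0:
            continue  # F stays 0: coancestry with an unknown parent is 0
        # accumulate a_ii = sum of L² d over the ancestor closure of i
        paths: dict[int, float] = {i: 1.0}
        aii = 0.0
        while paths:
            j = max(paths)
            lj = paths.pop(j)
            aii += lj * lj * d[j]
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                paths[sj] = paths.get(sj, 0.0) + 0.5 * lj
            if dj >= 0:
                paths[dj] = paths.get(dj, 0.0) + 0.5 * lj
        F[i] = aii - 1.0
    return F, d


def a_inverse(ped: Pedigree) -> RelationshipInverse:
    """Sparse inverse of the numerator relationship matrix.

    Henderson's rules with inbreeding: each individual contributes at most
    nine entries (itself, its parents, and the parent pairs), scaled by the
    reciprocal of its Mendelian-sampling variance.
    """
    _, d = inbreeding(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(ped.n):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * alpha)
    m = sp.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n)).tocsr()
    return RelationshipInverse(ped.n, m)


def a22(ped: Pedigree, indices: np.ndarray | None = None) -> np.ndarray:
    """Pedigree relationships among the genotyped individuals.

    Slices the tabular ``A`` to the genotyped rows/columns, in
    genotype-file order.
    """
    if indices is None:
        indices = ped.genotyped
    if indices is None or len(indices) == 0:
        raise DegenerateInputError("no genotyped individuals: A22 is empty")
    indices = np.asarray(indices, dtype=np.int64)
    A = tabular_A(ped)
    return A[np.ix_(indices, indices)]


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------

def vanraden_G(geno: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix, VanRaden method 1.

    ``G = (S − P)(S − P)' / (2 Σ_j p_j (1 − p_j))`` where column ``j`` of
    ``P`` is ``2 p_j`` with ``p_j`` the observed second-allele frequency.
    Missing genotypes are imputed to the locus mean ``2 p_j``, which leaves
    the centered column sums at zero.
    """
    p = geno.p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise DegenerateInputError(
            "all loci are monomorphic: VanRaden denominator 2Σp(1−p) is zero"
        )
    Z = np.where(geno.missing, 0.0, geno.S - 2.0 * p)
    G = (Z @ Z.T) / denom
    return 0.5 * (G + G.T)


def nearest_positive_definite(
    a: np.ndarray,
    eig_floor: float = 1e-8,
    tol: float = 1e-10,
    max_sweeps: int = 100,
) -> np.ndarray:
    """Project a symmetric matrix to the nearest one with eigenvalues ≥ floor.

    Alternating projection between the symmetric cone (symmetrisation) and
    the spectral constraint (eigenvalue clipping); for an already-symmetric
    input one sweep is the exact Frobenius-norm projection.  Stops when the
    iterate moves less than ``tol`` in Frobenius norm.
    """
    x = np.asarray(a, dtype=np.float64)
    for _ in range(max_sweeps):
        y = 0.5 * (x + x.T)
        w, v = np.linalg.eigh(y)
        x_new = (v * np.maximum(w, eig_floor)) @ v.T
        if np.linalg.norm(x_new - x, ord="fro") < tol:
            return 0.5 * (x_new + x_new.T)
        x = x_new
    return 0.5 * (x + x.T)


def ensure_invertible(
    G: np.ndarray,
    diag_load: float = 0.0,
    use_nearest_pd: bool = False,
    eig_floor: float = 1e-8,
) -> np.ndarray:
    """Make ``G`` safely factorizable.

    Applies, in order: the nearest-positive-definite projection (if
    requested) and diagonal loading ``G + diag_load·I`` (if positive), then
    verifies positive definiteness with a Cholesky factorization.
    """
    out = np.asarray(G, dtype=np.float64)
    if use_nearest_pd:
        out = nearest_positive_definite(out, eig_floor=eig_floor)
    if diag_load > 0.0:
        out = out + diag_load * np.eye(out.shape[0])
    try:
        np.linalg.cholesky(out)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "relationship matrix is not positive definite after safeguards; "
            "increase diag_load or enable the nearest-PD projection"
        ) from exc
    return out


# ---------------------------------------------------------------------------
# blending and single-step hybrid inverse
# ---------------------------------------------------------------------------

def _avg_diag_offdiag(B: np.ndarray) -> tuple[float, float]:
    n = B.shape[0]
    dg = float(np.trace(B)) / n
    off = (float(B.sum()) - float(np.trace(B))) / (n * (n - 1))
    return dg, off


def blend_tune(G: np.ndarray, A22: np.ndarray) -> BlendTuneResult:
    """Rescale G so its diagonal/off-diagonal averages match A22's.

    Solves the 2×2 system
    ``Avg(diag G)·β + α = Avg(diag A22)``,
    ``Avg(offdiag G)·β + α = Avg(offdiag A22)``
    and returns ``G* = β G + α`` (α added to every entry).
    """
    if G.shape != A22.shape or G.shape[0] < 2:
        raise DimensionError("G and A22 must be square of the same order ≥ 2")
    dg_g, off_g = _avg_diag_offdiag(G)
    dg_a, off_a = _avg_diag_offdiag(A22)
    det = dg_g - off_g
    if abs(det) < 1e-14 * max(1.0, abs(dg_g)):
        raise NumericalError(
            "blending system is singular: Avg(diag(G)) equals Avg(offdiag(G))"
        )
    beta = (dg_a - off_a) / det
    alpha = dg_a - dg_g * beta
    return BlendTuneResult(alpha=alpha, beta=beta, g_star=beta * G + alpha)


def _pd_inverse(a: np.ndarray, what: str) -> np.ndarray:
    try:
        c = cho_factor(a)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"{what} is not positive definite") from exc
    return cho_solve(c, np.eye(a.shape[0]))


def h_inverse(
    a_inv: RelationshipInverse,
    a22_mat: np.ndarray,
    g_star: np.ndarray,
    tau: float = 1.0,
    w: float = 0.0,
    omega: float = 1.0,
    genotyped: np.ndarray | None = None,
) -> RelationshipInverse:
    """Single-step hybrid relationship-matrix inverse.

    ``H⁻¹ = A⁻¹ + [τ((1−w)G* + w A22)⁻¹ − ω A22⁻¹]`` on the genotyped
    block, zero elsewhere.  ``τ`` scales the genomic information, ``ω`` the
    pedigree information removed, and ``w`` mixes a residual-polygenic share
    of ``A22`` into the genomic term.

    ``genotyped`` gives the pedigree indices of the genotyped individuals in
    the same order as the rows of ``g_star``/``a22_mat``.
    """
    if g_star.shape != a22_mat.shape:
        raise DimensionError("G* and A22 are not conformable")
    n2 = g_star.shape[0]
    if genotyped is None:
        genotyped = np.arange(a_inv.order - n2, a_inv.order)
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if len(genotyped) != n2:
        raise DimensionError("genotyped index count does not match G* order")
    inner = (1.0 - w) * g_star + w * a22_mat
    block = tau * _pd_inverse(inner, "(1−w)G* + wA22") - omega * _pd_inverse(
        a22_mat, "A22"
    )
    rr, cc = np.meshgrid(genotyped, genotyped, indexing="ij")
    add = sp.coo_matrix(
        (block.ravel(), (rr.ravel(), cc.ravel())),
        shape=(a_inv.order, a_inv.order),
    )
    return RelationshipInverse(a_inv.order, (a_inv.matrix + add.tocsr()).tocsr())
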