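"""File formats: parameter file, phenotypes, pedigree, genotypes, kinships.

All data files are whitespace-delimited plain text; the phenotype file has
a header line naming its columns.  Categorical columns may contain
arbitrary alpha-numeric labels — they are renumbered to consecutive
integer codes (1..L, first-appearance order) before modelling, and the
renumber maps restore the original labels on output.  Kinship inverses are
exchanged as 1-based ``row col value`` triplets storing one triangle;
symmetry is restored by mirroring on read.

The parameter file is organised in keyword sections: a section keyword on
its own line (``EFFECT`` / ``COVARIANCE`` / ``RESIDUAL_COVARIANCE`` take a
name on the same line), ``key = value`` pairs beneath it, ``#`` comments
anywhere.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import (
    ConfigurationError,
    DataError,
    DimensionError,
    FormatError,
    ParseError,
)
from .kinship import (
    GenotypeMatrix,
    Pedigree,
    RelationshipInverse,
    a22,
    a_inverse,
    blend_tune,
    ensure_invertible,
    h_inverse,
    vanraden_G,
)
from .model import ModelSpec, PhenotypeTable, ResolvedEffect

logger = logging.getLogger(__name__)

__all__ = [
    "RenumberMap",
    "renumber",
    "ParameterSpec",
    "EffectDecl",
    "read_parameter_file",
    "read_pedigree",
    "read_genotypes",
    "read_kinship_inverse",
    "write_kinship_inverse",
    "write_solutions",
    "read_solutions",
    "Problem",
    "load_problem",
]


# ---------------------------------------------------------------------------
# renumbering
# ---------------------------------------------------------------------------

@dataclass
class RenumberMap:
    """Bijection between raw categorical labels and codes 1..L.

    Codes are assigned in order of first appearance; numerals are treated
    as labels like any other string.
    """

    labels: list[str] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def add(self, label: str) -> int:
        code = self.index.get(label)
        if code is None:
            self.labels.append(label)
            code = len(self.labels)
            self.index[label] = code
        return code

    def encode(self, column) -> np.ndarray:
        return np.array([self.add(str(v)) for v in column], dtype=np.int64)

    def code(self, label: str) -> int:
        try:
            return self.index[str(label)]
        except KeyError as exc:
            raise DataError(f"label {label!r} not in renumber map") from exc

    def label(self, code: int) -> str:
        if not 1 <= code <= len(self.labels):
            raise DimensionError(f"code {code} outside 1..{len(self.labels)}")
        return self.labels[code - 1]


def renumber(column) -> tuple[np.ndarray, RenumberMap]:
    """Recode labels to consecutive integers 1..L in first-appearance order."""
    rmap = RenumberMap()
    codes = rmap.encode(column)
    return codes, rmap


# ---------------------------------------------------------------------------
# parameter file
# ---------------------------------------------------------------------------

@dataclass
class EffectDecl:
    """One effect as declared in the parameter file (unresolved)."""

    name: str
    kind: str
    column: str | None = None
    covariate: str | None = None
    legendre: tuple[int, float, float] | None = None
    traits: list[str] | None = None
    kinship: str = "identity"
    kinship_file: str | None = None
    levels: int | None = None
    covariance: str | None = None


@dataclass
class ParameterSpec:
    """Fully parsed parameter file with defaults applied."""

    trait_names: list[str]
    effects: list[EffectDecl]
    covariances: dict[str, np.ndarray]
    residual_covs: dict[str, np.ndarray]
    residual_class_column: str | None = None
    weight_column: str | None = None
    phenotype_file: str | None = None
    pedigree_file: str | None = None
    genotype_file: str | None = None
    unknown_parent: str = "0"
    missing_value: str = "NA"
    tau: float = 1.0
    w: float = 0.0
    omega: float = 1.0
    diag_load: float = 0.0
    use_nearest_pd: bool = False
    tolerance: float = 1e-13
    max_rounds: int = 5000
    refresh_interval: int = 100


_SECTIONS = {
    "DATAFILES",
    "TRAITS",
    "EFFECT",
    "COVARIANCE",
    "RESIDUAL",
    "RESIDUAL_COVARIANCE",
    "HYBRID",
    "GOPTIONS",
    "SOLVER",
}

_SECTION_KEYS = {
    "DATAFILES": {"phenotypes", "pedigree", "genotypes", "unknown_parent", "missing_value"},
    "TRAITS": {"names"},
    "EFFECT": {
        "kind", "column", "covariate", "legendre", "traits",
        "kinship", "kinship_file", "levels", "covariance",
    },
    "RESIDUAL": {"classes_column", "weight_column"},
    "HYBRID": {"tau", "w", "omega"},
    "GOPTIONS": {"diag_load", "nearest_pd"},
    "SOLVER": {"tolerance", "max_rounds", "refresh_interval"},
}

_KINSHIP_SOURCES = {"identity", "pedigree", "genomic", "hybrid", "user_file"}


def _parse_matrix(entries: list[tuple[int, str, str]], where: str, basedir: Path) -> np.ndarray:
    rows: dict[int, list[float]] = {}
    for lineno, key, value in entries:
        if key == "file":
            return _read_symmetric_matrix(basedir / value)
        if not key.startswith("row"):
            raise ParseError(f"line {lineno}: unknown key {key!r} in {where}")
        try:
            idx = int(key[3:])
            rows[idx] = [float(v) for v in value.split()]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad matrix row in {where}") from exc
    if not rows:
        raise ConfigurationError(f"{where}: no matrix rows given")
    n = max(rows)
    if sorted(rows) != list(range(1, n + 1)) or any(len(r) != n for r in rows.values()):
        raise ConfigurationError(f"{where}: matrix rows do not form a square matrix")
    m = np.array([rows[i] for i in range(1, n + 1)])
    if not np.allclose(m, m.T, atol=1e-8):
        raise ConfigurationError(f"{where}: matrix is not symmetric")
    return 0.5 * (m + m.T)


def _read_symmetric_matrix(path: Path) -> np.ndarray:
    m = np.loadtxt(path, ndmin=2)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-8):
        raise FormatError(f"{path}: not a square symmetric matrix")
    return 0.5 * (m + m.T)


def read_parameter_file(path) -> ParameterSpec:
    """Parse the keyword-section parameter file and apply defaults."""
    path = Path(path)
    basedir = path.parent
    sections: list[tuple[str, str | None, list[tuple[int, str, str]]]] = []
    current: list[tuple[int, str, str]] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                if current is None:
                    raise ParseError(
                        f"line {lineno}: key=value pair before any section"
                    )
                key, _, value = line.partition("=")
                current.append((lineno, key.strip().lower(), value.strip()))
                continue
            tokens = line.split()
            kw = tokens[0].upper()
            if kw not in _SECTIONS:
                raise ParseError(
                    f"line {lineno}: unknown section keyword {tokens[0]!r}"
                )
            name = tokens[1] if len(tokens) > 1 else None
            if kw in ("EFFECT", "COVARIANCE", "RESIDUAL_COVARIANCE") and name is None:
                raise ParseError(f"line {lineno}: section {kw} needs a name")
            current = []
            sections.append((kw, name, current))

    spec = ParameterSpec(trait_names=[], effects=[], covariances={}, residual_covs={})
    seen_traits = False
    for kw, name, entries in sections:
        if kw in ("COVARIANCE", "RESIDUAL_COVARIANCE"):
            mat = _parse_matrix(entries, f"{kw} {name}", basedir)
            if kw == "COVARIANCE":
                spec.covariances[name] = mat
            else:
                spec.residual_covs[name] = mat
            continue
        if kw == "EFFECT":
            eff = EffectDecl(name=name, kind="")
            for lineno, key, value in entries:
                if key not in _SECTION_KEYS["EFFECT"]:
                    raise ParseError(f"line {lineno}: unknown key {key!r} in EFFECT")
                if key == "legendre":
                    parts = value.split()
                    if len(parts) != 3:
                        raise ParseError(
                            f"line {lineno}: legendre needs 'order t_min t_max'"
                        )
                    eff.legendre = (int(parts[0]), float(parts[1]), float(parts[2]))
                elif key == "traits":
                    eff.traits = value.split()
                elif key == "levels":
                    eff.levels = int(value)
                else:
                    setattr(eff, key, value)
            if eff.kind not in ("fixed_class", "fixed_regression", "random"):
                raise ConfigurationError(
                    f"EFFECT {name}: kind must be fixed_class, fixed_regression "
                    f"or random (got {eff.kind!r})"
                )
            if eff.kinship not in _KINSHIP_SOURCES:
                raise ConfigurationError(
                    f"EFFECT {name}: unknown kinship source {eff.kinship!r}"
                )
            spec.effects.append(eff)
            continue
        for lineno, key, value in entries:
            if key not in _SECTION_KEYS[kw]:
                raise ParseError(f"line {lineno}: unknown key {key!r} in {kw}")
        kv = {k: v for _, k, v in entries}
        if kw == "DATAFILES":
            spec.phenotype_file = kv.get("phenotypes", spec.phenotype_file)
            spec.pedigree_file = kv.get("pedigree", spec.pedigree_file)
            spec.genotype_file = kv.get("genotypes", spec.genotype_file)
            spec.unknown_parent = kv.get("unknown_parent", spec.unknown_parent)
            spec.missing_value = kv.get("missing_value", spec.missing_value)
        elif kw == "TRAITS":
            spec.trait_names = kv.get("names", "").split()
            seen_traits = True
        elif kw == "RESIDUAL":
            spec.residual_class_column = kv.get("classes_column")
            spec.weight_column = kv.get("weight_column")
        elif kw == "HYBRID":
            spec.tau = float(kv.get("tau", spec.tau))
            spec.w = float(kv.get("w", spec.w))
            spec.omega = float(kv.get("omega", spec.omega))
        elif kw == "GOPTIONS":
            spec.diag_load = float(kv.get("diag_load", spec.diag_load))
            spec.use_nearest_pd = kv.get("nearest_pd", "no").lower() in (
                "yes", "true", "1", "on",
            )
        elif kw == "SOLVER":
            spec.tolerance = float(kv.get("tolerance", spec.tolerance))
            spec.max_rounds = int(kv.get("max_rounds", spec.max_rounds))
            spec.refresh_interval = int(kv.get("refresh_interval", spec.refresh_interval))

    if not seen_traits or not spec.trait_names:
        raise ConfigurationError("mandatory TRAITS section missing or empty")
    if not spec.effects:
        raise ConfigurationError("at least one EFFECT section is required")
    for eff in spec.effects:
        if eff.kind == "random" and eff.covariance not in spec.covariances:
            raise ConfigurationError(
                f"random effect {eff.name!r} needs a COVARIANCE section "
                f"(covariance = {eff.covariance!r} not found)"
            )
    if not spec.residual_covs:
        raise ConfigurationError("a RESIDUAL_COVARIANCE section is required")
    if spec.tolerance <= 0:
        raise ConfigurationError("solver tolerance must be positive")
    if spec.refresh_interval < 1:
        raise ConfigurationError("refresh_interval must be ≥ 1")
    return spec


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def read_pedigree(path, unknown: str = "0") -> tuple[Pedigree, RenumberMap]:
    """Read individual/sire/dam triples and return a sorted pedigree.

    Individuals are reordered (if needed) so parents precede offspring,
    then renumbered 1..n in that order; the returned map carries the final
    codes.  Parents that never appear as individuals are auto-added as
    founders (logged); an individual among its own ancestors is an error.
    """
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(
                    f"{path} line {lineno}: pedigree needs ≥3 columns"
                )
            rows.append((parts[0], parts[1], parts[2]))

    parents_of: dict[str, tuple[str | None, str | None]] = {}
    order: list[str] = []

    def note(label: str) -> None:
        if label not in parents_of:
            parents_of[label] = (None, None)
            order.append(label)

    n_auto = 0
    for ind, s, d in rows:
        s = None if s == unknown else s
        d = None if d == unknown else d
        if ind in parents_of and parents_of[ind] != (None, None):
            raise FormatError(f"individual {ind!r} appears twice in the pedigree")
        if ind not in parents_of:
            order.append(ind)
        parents_of[ind] = (s, d)
        for p in (s, d):
            if p is not None and p not in parents_of:
                note(p)
                n_auto += 1
    if n_auto:
        logger.info("%d parents auto-added as founders", n_auto)

    # Kahn topological sort, stable in first-appearance order
    appear = {lab: i for i, lab in enumerate(order)}
    children: dict[str, list[str]] = {lab: [] for lab in order}
    indeg = {lab: 0 for lab in order}
    for lab in order:
        for p in parents_of[lab]:
            if p is not None:
                children[p].append(lab)
                indeg[lab] += 1
    heap = [appear[lab] for lab in order if indeg[lab] == 0]
    heapq.heapify(heap)
    sorted_labels: list[str] = []
    while heap:
        lab = order[heapq.heappop(heap)]
        sorted_labels.append(lab)
        for ch in children[lab]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                heapq.heappush(heap, appear[ch])
    if len(sorted_labels) != len(order):
        cyc = sorted(lab for lab in order if indeg[lab] > 0)
        raise FormatError(
            f"pedigree contains a cycle (an individual is its own ancestor): "
            f"{', '.join(cyc[:5])}"
        )

    rmap = RenumberMap()
    for lab in sorted_labels:
        rmap.add(lab)
    n = len(sorted_labels)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for lab in sorted_labels:
        i = rmap.code(lab) - 1
        s, d = parents_of[lab]
        if s is not None:
            sire[i] = rmap.code(s) - 1
        if d is not None:
            dam[i] = rmap.code(d) - 1
    return Pedigree(sire=sire, dam=dam, labels=list(sorted_labels)), rmap


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, missing: str = "NA") -> GenotypeMatrix:
    """Read one individual per row: ID then m allele counts in {0,1,2}."""
    labels: list[str] = []
    data: list[list[float]] = []
    mask: list[list[bool]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise FormatError(
                    f"{path} line {lineno}: ragged row "
                    f"({len(parts)} fields, expected {width})"
                )
            labels.append(parts[0])
            row: list[float] = []
            mrow: list[bool] = []
            for v in parts[1:]:
                if v == missing:
                    row.append(0.0)
                    mrow.append(True)
                elif v in ("0", "1", "2"):
                    row.append(float(v))
                    mrow.append(False)
                else:
                    raise FormatError(
                        f"{path} line {lineno}: genotype {v!r} not in "
                        f"{{0,1,2}} or {missing!r}"
                    )
            data.append(row)
            mask.append(mrow)
    if not data:
        raise FormatError(f"{path}: empty genotype file")
    return GenotypeMatrix(
        S=np.array(data), missing=np.array(mask, dtype=bool), labels=labels
    )


# ---------------------------------------------------------------------------
# kinship inverse triplets
# ---------------------------------------------------------------------------

def read_kinship_inverse(path, expected_order: int) -> RelationshipInverse:
    """Read 1-based ``row col value`` triplets; mirror one triangle."""
    entries: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path} line {lineno}: expected 'row col value'")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: bad triplet") from exc
            if not (1 <= i <= expected_order and 1 <= j <= expected_order):
                raise DimensionError(
                    f"{path} line {lineno}: index ({i},{j}) exceeds order "
                    f"{expected_order}"
                )
            key = (min(i, j) - 1, max(i, j) - 1)
            if key in entries and abs(entries[key] - v) > 1e-12 * max(1.0, abs(v)):
                raise FormatError(
                    f"{path} line {lineno}: duplicate entry ({i},{j}) with "
                    f"conflicting values"
                )
            entries[key] = v
    if not entries:
        logger.warning("%s: empty kinship-inverse file; using a zero matrix", path)
        return RelationshipInverse(
            expected_order, sp.csr_matrix((expected_order, expected_order))
        )
    rows, cols, vals = [], [], []
    for (i, j), v in entries.items():
        rows.append(i)
        cols.append(j)
        vals.append(v)
        if i != j:
            rows.append(j)
            cols.append(i)
            vals.append(v)
    m = sp.coo_matrix(
        (vals, (rows, cols)), shape=(expected_order, expected_order)
    ).tocsr()
    return RelationshipInverse(expected_order, m)


def write_kinship_inverse(path, rel: RelationshipInverse, threshold: float = 0.0) -> None:
    """Write the upper triangle of a symmetric inverse as 1-based triplets."""
    coo = sp.triu(rel.matrix).tocoo()
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if abs(v) > threshold:
                fh.write(f"{i + 1} {j + 1} {v:.12g}\n")


# ---------------------------------------------------------------------------
# solutions
# ---------------------------------------------------------------------------

def write_solutions(
    path,
    x: np.ndarray,
    model: ModelSpec,
    layout,
    convergence: float = float("nan"),
    rounds: int = 0,
    status: str = "unknown",
) -> None:
    """Write one row per equation with original level labels restored.

    Values are printed with 12 significant digits so a re-read reproduces
    them at that precision.  The header records the convergence value,
    round count and exit status.
    """
    with open(path, "w") as fh:
        fh.write(f"# status\t{status}\n")
        fh.write(f"# rounds\t{rounds}\n")
        fh.write(f"# convergence\t{convergence:.6e}\n")
        fh.write("effect\tlevel\tcoef\ttrait\tsolution\n")
        for ei, eff in enumerate(model.effects):
            L, ncoef, t_eff = layout.effect_dims[ei]
            tidx = eff.trait_idx(model.trait_names)
            for lvl in range(1, L + 1):
                label = (
                    eff.level_labels[lvl - 1]
                    if eff.level_labels is not None
                    else str(lvl)
                )
                for c in range(ncoef):
                    for pos, g in enumerate(tidx):
                        eq = layout.eq_index(ei, lvl, c, pos)
                        fh.write(
                            f"{eff.name}\t{label}\t{c}\t"
                            f"{model.trait_names[g]}\t{x[eq]:.12g}\n"
                        )


def read_solutions(path) -> tuple[pd.DataFrame, dict]:
    """Read a solutions file back; returns the table and the header fields."""
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = 0
    for line in lines:
        if not line.startswith("#"):
            break
        parts = line[1:].strip().split("\t")
        if len(parts) == 2:
            meta[parts[0]] = parts[1]
        body += 1
    from io import StringIO

    df = pd.read_csv(
        StringIO("".join(lines[body:])), sep="\t", dtype={"level": str},
        keep_default_na=False, na_values=[],
    )
    df["solution"] = df["solution"].astype(float)
    if "rounds" in meta:
        meta["rounds"] = int(meta["rounds"])
    if "convergence" in meta:
        meta["convergence"] = float(meta["convergence"])
    return df, meta


# ---------------------------------------------------------------------------
# end-to-end loading
# ---------------------------------------------------------------------------

@dataclass
class Problem:
    """Everything needed to set up and solve one evaluation."""

    spec: ParameterSpec
    table: PhenotypeTable
    model: ModelSpec
    pedigree: Pedigree | None = None
    pedigree_map: RenumberMap | None = None
    genotypes: GenotypeMatrix | None = None
    class_maps: dict[str, RenumberMap] = field(default_factory=dict)
    residual_map: RenumberMap | None = None


def _build_kinship_inverse(
    eff: EffectDecl,
    spec: ParameterSpec,
    basedir: Path,
    ped: Pedigree | None,
    geno: GenotypeMatrix | None,
    ped_map: RenumberMap | None,
) -> tuple[RelationshipInverse | None, int | None, list[str] | None]:
    """Kinship inverse, level count and level labels for one random effect."""
    if eff.kinship == "identity":
        return None, eff.levels, None
    if eff.kinship == "user_file":
        if eff.kinship_file is None:
            raise ConfigurationError(
                f"effect {eff.name!r}: kinship=user_file needs kinship_file"
            )
        fp = basedir / eff.kinship_file
        if eff.levels is None:
            order = 0
            with open(fp) as fh:
                for line in fh:
                    parts = line.split("#", 1)[0].split()
                    if len(parts) == 3:
                        order = max(order, int(parts[0]), int(parts[1]))
            if order == 0:
                raise ConfigurationError(
                    f"effect {eff.name!r}: cannot infer order of empty kinship "
                    "file; give levels = N"
                )
        else:
            order = eff.levels
        return read_kinship_inverse(fp, order), order, None
    if eff.kinship in ("pedigree", "hybrid"):
        if ped is None:
            raise ConfigurationError(
                f"effect {eff.name!r} needs a pedigree file"
            )
    if eff.kinship in ("genomic", "hybrid"):
        if geno is None:
            raise ConfigurationError(
                f"effect {eff.name!r} needs a genotype file"
            )
    if eff.kinship == "pedigree":
        return a_inverse(ped), ped.n, list(ped.labels)
    G = ensure_invertible(
        vanraden_G(geno),
        diag_load=spec.diag_load,
        use_nearest_pd=spec.use_nearest_pd,
    )
    if eff.kinship == "genomic":
        ginv = np.linalg.inv(G)
        return (
            RelationshipInverse.from_dense(0.5 * (ginv + ginv.T)),
            geno.n_individuals,
            list(geno.labels),
        )
    # hybrid: blend G toward A22 of the genotyped individuals, then H⁻¹
    gen_idx = np.array([ped_map.code(lab) - 1 for lab in geno.labels])
    ped.genotyped = gen_idx
    A22 = a22(ped, gen_idx)
    bt = blend_tune(G, A22)
    logger.info(
        "blend/tune for %s: beta=%.6g alpha=%.6g", eff.name, bt.beta, bt.alpha
    )
    hinv = h_inverse(
        a_inverse(ped), A22, bt.g_star,
        tau=spec.tau, w=spec.w, omega=spec.omega, genotyped=gen_idx,
    )
    return hinv, ped.n, list(ped.labels)


def load_problem(spec: ParameterSpec, basedir=".") -> Problem:
    """Read all data files and resolve the model ready for solving."""
    basedir = Path(basedir)
    if spec.phenotype_file is None:
        raise ConfigurationError("DATAFILES must name a phenotype file")
    pheno = pd.read_csv(
        basedir / spec.phenotype_file, sep=r"\s+", dtype=str, comment="#",
        keep_default_na=False, na_values=[],
    )

    ped = ped_map = geno = None
    if spec.pedigree_file is not None:
        ped, ped_map = read_pedigree(
            basedir / spec.pedigree_file, unknown=spec.unknown_parent
        )
    if spec.genotype_file is not None:
        geno = read_genotypes(
            basedir / spec.genotype_file, missing=spec.missing_value
        )

    def column(name: str) -> pd.Series:
        if name not in pheno.columns:
            raise ConfigurationError(
                f"phenotype file has no column {name!r} "
                f"(header: {', '.join(pheno.columns)})"
            )
        return pheno[name]

    def numeric(name: str) -> np.ndarray:
        col = column(name)
        out = np.empty(len(col), dtype=np.float64)
        for i, v in enumerate(col):
            if v == spec.missing_value:
                out[i] = np.nan
            else:
                try:
                    out[i] = float(v)
                except ValueError as exc:
                    raise FormatError(
                        f"column {name!r} has non-numeric value {v!r}"
                    ) from exc
        return out

    y = np.column_stack([numeric(t) for t in spec.trait_names])
    keep = ~np.all(np.isnan(y), axis=1)
    if not np.all(keep):
        logger.warning(
            "dropping %d records with no observed trait", int((~keep).sum())
        )
        pheno = pheno.loc[keep].reset_index(drop=True)
        y = y[keep]

    class_codes: dict[str, np.ndarray] = {}
    class_maps: dict[str, RenumberMap] = {}
    covariates: dict[str, np.ndarray] = {}
    effects: list[ResolvedEffect] = []
    for decl in spec.effects:
        kin = None
        n_levels = None
        labels: list[str] | None = None
        if decl.kind == "random":
            kin, n_levels, labels = _build_kinship_inverse(
                decl, spec, basedir, ped, geno, ped_map
            )
        if decl.column is not None:
            if decl.kind == "random" and decl.kinship in ("pedigree", "hybrid"):
                codes = np.array(
                    [ped_map.code(v) for v in column(decl.column)], dtype=np.int64
                )
                class_maps[decl.column] = ped_map
            elif decl.kind == "random" and decl.kinship == "genomic":
                gmap = RenumberMap()
                for lab in geno.labels:
                    gmap.add(lab)
                codes = np.array(
                    [gmap.code(v) for v in column(decl.column)], dtype=np.int64
                )
                class_maps[decl.column] = gmap
            elif decl.kind == "random" and decl.kinship == "user_file":
                try:
                    codes = column(decl.column).astype(int).to_numpy()
                except ValueError as exc:
                    raise FormatError(
                        f"column {decl.column!r} must hold integer codes "
                        "matching the user kinship file"
                    ) from exc
                if np.any(codes < 1) or np.any(codes > n_levels):
                    raise DimensionError(
                        f"codes in {decl.column!r} outside 1..{n_levels}"
                    )
            else:
                if decl.column in class_maps:
                    codes = class_maps[decl.column].encode(column(decl.column))
                else:
                    codes, cmap = renumber(column(decl.column))
                    class_maps[decl.column] = cmap
                if n_levels is None:
                    n_levels = int(len(class_maps[decl.column]))
                if labels is None and decl.column in class_maps:
                    labels = list(class_maps[decl.column].labels)
            class_codes[decl.column] = codes
        else:
            if n_levels is None:
                n_levels = 1
        if n_levels is None:
            n_levels = decl.levels or 1
        if decl.covariate is not None:
            covariates[decl.covariate] = numeric(decl.covariate)
        effects.append(
            ResolvedEffect(
                name=decl.name,
                kind=decl.kind,
                n_levels=int(n_levels),
                level_column=decl.column,
                covariate_column=decl.covariate,
                legendre=decl.legendre,
                traits=decl.traits,
                kinship_inv=kin,
                covariance=spec.covariances.get(decl.covariance)
                if decl.kind == "random"
                else None,
                level_labels=labels,
            )
        )

    weights = numeric(spec.weight_column) if spec.weight_column else None
    residual_map = None
    residual_class = None
    residual_covs: dict[int, np.ndarray] = {}
    if spec.residual_class_column:
        residual_class, residual_map = renumber(column(spec.residual_class_column))
        for label, mat in spec.residual_covs.items():
            if label == "default":
                continue
            residual_covs[residual_map.code(label)] = mat
        default = spec.residual_covs.get("default")
        for code in range(1, len(residual_map) + 1):
            if code not in residual_covs:
                if default is None:
                    raise ConfigurationError(
                        f"no residual covariance for class "
                        f"{residual_map.label(code)!r} and no default given"
                    )
                residual_covs[code] = default
    else:
        if "default" not in spec.residual_covs and len(spec.residual_covs) == 1:
            residual_covs[1] = next(iter(spec.residual_covs.values()))
        elif "default" in spec.residual_covs:
            residual_covs[1] = spec.residual_covs["default"]
        else:
            raise ConfigurationError(
                "multiple residual covariances given but no classes_column"
            )

    table = PhenotypeTable(
        y=y,
        trait_names=list(spec.trait_names),
        class_codes=class_codes,
        covariates=covariates,
        weights=weights,
        residual_class=residual_class,
    )
    model = ModelSpec(
        trait_names=list(spec.trait_names),
        effects=effects,
        residual_covs=residual_covs,
        weight_column=spec.weight_column,
    )
    return Problem(
        spec=spec,
        table=table,
        model=model,
        pedigree=ped,
        pedigree_map=ped_map,
        genotypes=geno,
        class_maps=class_maps,
        residual_map=residual_map,
    )
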