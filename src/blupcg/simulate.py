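"""Synthetic data with the covariance structure the models assume.

Generates pedigrees (random matings over discrete generations), genotypes
(founder allele frequencies Uniform(0.05, 0.95), offspring by gene
dropping), and phenotypes whose true genetic values are drawn with
covariance ``K ⊗ G₀`` (trait-consecutive ordering) and residuals with
covariance ``R / weight`` — i.e. exactly the model the MME assumes, so
solver output can be checked against a dense oracle and, statistically,
against the simulated truth.  A test-day generator produces random
regression records with Legendre covariables and per-period residual
variances.  ``random_mme_case`` draws small random models (traits, effect
mixtures, kinship sources, missing traits, weights, residual classes) for
oracle-equivalence testing.

Everything is driven by a :class:`numpy.random.Generator`; a fixed seed
reproduces every output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import BlupcgError, ConfigurationError
from .kinship import (
    GenotypeMatrix,
    Pedigree,
    RelationshipInverse,
    a22,
    a_inverse,
    blend_tune,
    ensure_invertible,
    h_inverse,
    tabular_A,
    vanraden_G,
)
from .model import (
    ModelSpec,
    PhenotypeTable,
    ResolvedEffect,
    build_layout,
    legendre_basis,
)

__all__ = [
    "SimConfig",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_testday",
    "random_spd",
    "random_mme_case",
    "write_pedigree_file",
    "write_genotype_file",
    "write_phenotype_file",
    "write_truth_file",
    "write_gblup_dataset",
]


def _default_g0() -> np.ndarray:
    return np.array([[0.30, 0.10, 0.05], [0.10, 0.25, 0.08], [0.05, 0.08, 0.35]])


def _default_r() -> np.ndarray:
    return np.array([[0.70, 0.20, 0.10], [0.20, 0.75, 0.15], [0.10, 0.15, 0.65]])


@dataclass
class SimConfig:
    """Study conditions for the generators.

    Defaults emulate a reduced-scale multi-trait GBLUP with de-regressed
    pseudo-phenotypes: three correlated traits, record weights acting as
    residual-precision multipliers, and a moderate missing-trait rate so
    records carry at most three (and often fewer) traits.
    """

    seed: int = 20180814
    n_founders: int = 100
    n_generations: int = 4
    offspring_per_generation: int = 120
    m_snps: int = 1000
    t_traits: int = 3
    genetic_cov: np.ndarray = field(default_factory=_default_g0)
    residual_cov: np.ndarray = field(default_factory=_default_r)
    missing_rate: float = 0.2
    phenotyped_fraction: float = 0.7
    use_weights: bool = True
    weight_range: tuple[float, float] = (0.5, 5.0)
    # random regression (test-day) settings
    rrm_genetic_order: int = 4
    rrm_pe_order: int = 3
    lactation_range: tuple[float, float] = (5.0, 305.0)
    n_testdays: int = 8
    n_periods: int = 4
    n_herds: int = 5

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be ≥ 2")
        t = self.t_traits
        self.genetic_cov = np.asarray(self.genetic_cov, dtype=np.float64)[:t, :t]
        self.residual_cov = np.asarray(self.residual_cov, dtype=np.float64)[:t, :t]
        for name, m in (("genetic", self.genetic_cov), ("residual", self.residual_cov)):
            try:
                np.linalg.cholesky(m)
            except np.linalg.LinAlgError as exc:
                raise ConfigurationError(
                    f"{name} covariance is not positive definite"
                ) from exc
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# pedigree and genotypes
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator) -> Pedigree:
    """Random matings over discrete generations; founders have no parents."""
    sire = [-1] * cfg.n_founders
    dam = [-1] * cfg.n_founders
    prev = list(range(cfg.n_founders))
    for _ in range(1, cfg.n_generations):
        cur = []
        for _ in range(cfg.offspring_per_generation):
            s, d = rng.choice(prev, size=2, replace=False)
            cur.append(len(sire))
            sire.append(int(s))
            dam.append(int(d))
        prev = cur
    n = len(sire)
    labels = [f"ID{i + 1:06d}" for i in range(n)]
    return Pedigree(sire=np.array(sire), dam=np.array(dam), labels=labels)


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator
) -> GenotypeMatrix:
    """Gene dropping: founder alleles Bernoulli(p), offspring inherit one
    allele per parent per locus."""
    n, m = ped.n, cfg.m_snps
    p = rng.uniform(0.05, 0.95, size=m)
    h1 = np.zeros((n, m), dtype=np.int8)
    h2 = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0:
            h1[i] = rng.random(m) < p
        else:
            pick = rng.integers(0, 2, size=m)
            h1[i] = np.where(pick == 0, h1[s], h2[s])
        if d < 0:
            h2[i] = rng.random(m) < p
        else:
            pick = rng.integers(0, 2, size=m)
            h2[i] = np.where(pick == 0, h1[d], h2[d])
    S = (h1 + h2).astype(np.float64)
    labels = list(ped.labels) if ped.labels else [str(i + 1) for i in range(n)]
    return GenotypeMatrix(S=S, labels=labels)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _kinship_dense(source, cfg: SimConfig) -> tuple[np.ndarray, list[str]]:
    if isinstance(source, Pedigree):
        labels = list(source.labels) if source.labels else [
            str(i + 1) for i in range(source.n)
        ]
        return tabular_A(source), labels
    if isinstance(source, GenotypeMatrix):
        G = ensure_invertible(vanraden_G(source), diag_load=0.01)
        return G, list(source.labels)
    K = np.asarray(source, dtype=np.float64)
    return K, [str(i + 1) for i in range(K.shape[0])]


def simulate_phenotypes(
    source, cfg: SimConfig, rng: np.random.Generator
) -> tuple[PhenotypeTable, np.ndarray]:
    """One record per phenotyped individual under ``u ~ N(0, K⊗G₀)``.

    ``source`` is a pedigree, a genotype matrix or a dense kinship matrix.
    Residuals are ``N(0, R/w)`` with the record weight ``w`` drawn uniform
    over ``weight_range`` (all 1 when ``use_weights`` is off); each trait is
    masked missing at ``missing_rate`` with at least one trait kept.
    Returns the table and the full matrix of true genetic values.
    """
    K, labels = _kinship_dense(source, cfg)
    n = K.shape[0]
    t = cfg.t_traits
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    u = L @ rng.standard_normal((n, t)) @ np.linalg.cholesky(cfg.genetic_cov).T

    ids = np.flatnonzero(rng.random(n) < cfg.phenotyped_fraction)
    if ids.size == 0:
        ids = np.array([0])
    q = ids.size
    w = (
        rng.uniform(*cfg.weight_range, size=q)
        if cfg.use_weights
        else np.ones(q)
    )
    Lr = np.linalg.cholesky(cfg.residual_cov)
    e = rng.standard_normal((q, t)) @ Lr.T / np.sqrt(w)[:, None]
    y = u[ids] + e
    miss = rng.random((q, t)) < cfg.missing_rate
    for j in range(q):  # keep ≥1 observed trait
        if miss[j].all():
            miss[j, rng.integers(0, t)] = False
    y = np.where(miss, np.nan, y)
    table = PhenotypeTable(
        y=y,
        trait_names=[f"trait{k + 1}" for k in range(t)],
        class_codes={"id": ids + 1},
        weights=w if cfg.use_weights else None,
    )
    return table, u


def simulate_testday(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator
) -> tuple[PhenotypeTable, dict]:
    """Single-trait test-day records with random regressions.

    Per animal: genetic regression coefficients from ``A ⊗ G₀`` (Legendre
    order ``rrm_genetic_order``) and permanent-environment coefficients
    from ``I ⊗ P`` (order ``rrm_pe_order``); records at random days in
    milk with a herd-test-date class effect and a per-period residual
    variance (the lactation is split into ``n_periods`` equal periods).
    Returns the table and the truth (coefficients, period variances).
    """
    n = ped.n
    kg = cfg.rrm_genetic_order + 1
    kp = cfg.rrm_pe_order + 1
    G0 = random_spd(rng, kg, scale=0.3)
    P = random_spd(rng, kp, scale=0.2)
    r_periods = rng.uniform(0.4, 1.0, size=cfg.n_periods)

    A = tabular_A(ped)
    La = np.linalg.cholesky(A + 1e-8 * np.eye(n))
    a = La @ rng.standard_normal((n, kg)) @ np.linalg.cholesky(G0).T
    pe = rng.standard_normal((n, kp)) @ np.linalg.cholesky(P).T

    lo, hi = cfg.lactation_range
    edges = np.linspace(lo, hi, cfg.n_periods + 1)
    herd_effects = rng.normal(0.0, 1.0, size=cfg.n_herds * cfg.n_periods)

    ids, htds, dims, ys, periods = [], [], [], [], []
    for i in range(n):
        herd = rng.integers(0, cfg.n_herds)
        days = rng.uniform(lo, hi, size=cfg.n_testdays)
        for d in days:
            period = min(int(np.searchsorted(edges, d, side="right")) - 1,
                         cfg.n_periods - 1)
            htd = herd * cfg.n_periods + period
            phig = legendre_basis(d, lo, hi, cfg.rrm_genetic_order)
            phip = legendre_basis(d, lo, hi, cfg.rrm_pe_order)
            y = (
                herd_effects[htd]
                + phig @ a[i]
                + phip @ pe[i]
                + rng.normal(0.0, np.sqrt(r_periods[period]))
            )
            ids.append(i + 1)
            htds.append(htd + 1)
            dims.append(d)
            ys.append(y)
            periods.append(period + 1)
    table = PhenotypeTable(
        y=np.array(ys)[:, None],
        trait_names=["td"],
        class_codes={"id": np.array(ids), "htd": np.array(htds)},
        covariates={"dim": np.array(dims)},
        residual_class=np.array(periods),
    )
    truth = {
        "genetic_coefficients": a,
        "pe_coefficients": pe,
        "period_variances": r_periods,
        "G0": G0,
        "P": P,
        "herd_effects": herd_effects,
    }
    return table, truth


# ---------------------------------------------------------------------------
# random toy MMEs for oracle-equivalence testing
# ---------------------------------------------------------------------------

def random_spd(rng: np.random.Generator, p: int, scale: float = 1.0) -> np.ndarray:
    """Random well-conditioned symmetric positive definite matrix."""
    a = rng.standard_normal((p, p))
    m = a @ a.T / p + np.eye(p)
    return scale * 0.5 * (m + m.T)


def _random_kinship(
    rng: np.random.Generator, kind: str
) -> tuple[RelationshipInverse | None, int]:
    if kind == "identity":
        return None, int(rng.integers(4, 12))
    small = SimConfig(
        n_founders=int(rng.integers(4, 7)),
        n_generations=3,
        offspring_per_generation=int(rng.integers(3, 6)),
        m_snps=40,
        t_traits=1,
    )
    ped = simulate_pedigree(small, rng)
    if kind == "pedigree":
        return a_inverse(ped), ped.n
    geno = simulate_genotypes(ped, small, rng)
    if kind == "genomic":
        n2 = int(rng.integers(5, min(10, ped.n)))
        sub = GenotypeMatrix(S=geno.S[:n2], labels=geno.labels[:n2])
        G = ensure_invertible(vanraden_G(sub), diag_load=0.05)
        return RelationshipInverse.from_dense(np.linalg.inv(G)), n2
    # hybrid
    n2 = int(rng.integers(4, min(9, ped.n)))
    gen_idx = np.sort(rng.choice(ped.n, size=n2, replace=False))
    sub = GenotypeMatrix(
        S=geno.S[gen_idx], labels=[str(i) for i in gen_idx]
    )
    G = ensure_invertible(vanraden_G(sub), diag_load=0.05)
    A22 = a22(ped, gen_idx)
    gs = blend_tune(G, A22).g_star
    hin = h_inverse(
        a_inverse(ped), A22, gs, tau=1.6, w=0.1, omega=0.5, genotyped=gen_idx
    )
    return hin, ped.n


def random_mme_case(rng: np.random.Generator):
    """Draw a random small multi-trait mixed model with data.

    Mixes fixed class/regression and random effects over the four kinship
    sources, missing traits, record weights and residual classes; sized so
    the dense oracle stays a few hundred equations.  Returns
    ``(table, model, layout)``.
    """
    t = int(rng.integers(1, 4))
    traits = [f"t{k + 1}" for k in range(t)]
    q = int(rng.integers(20, 50))

    effects: list[ResolvedEffect] = []
    class_codes: dict[str, np.ndarray] = {}
    covariates: dict[str, np.ndarray] = {}

    # one fixed classification: either an overall mean or a class effect
    # (not both — together they would be confounded and C singular)
    if rng.random() < 0.5:
        L = int(rng.integers(2, 5))
        class_codes["grp"] = np.concatenate(
            [np.arange(1, L + 1), rng.integers(1, L + 1, size=q - L)]
        )  # every level observed at least once
        effects.append(
            ResolvedEffect(
                name="group", kind="fixed_class", n_levels=L, level_column="grp"
            )
        )
    else:
        effects.append(ResolvedEffect(name="mean", kind="fixed_class", n_levels=1))
    if rng.random() < 0.5:
        covariates["cov1"] = rng.uniform(-1.0, 1.0, size=q)
        effects.append(
            ResolvedEffect(
                name="slope",
                kind="fixed_regression",
                n_levels=1,
                covariate_column="cov1",
            )
        )

    n_random = int(rng.integers(1, 3))
    kinds = rng.choice(
        ["identity", "pedigree", "genomic", "hybrid"], size=n_random, replace=False
    )
    for ri, kind in enumerate(kinds):
        for _ in range(10):  # rare degenerate draws (non-PD blends) are redrawn
            try:
                kin, L = _random_kinship(rng, str(kind))
                break
            except BlupcgError:
                continue
        else:
            kin, L = _random_kinship(rng, "identity")
        use_legendre = rng.random() < 0.3
        if use_legendre:
            order = int(rng.integers(1, 3))
            legendre = (order, 0.0, 10.0)
            col = f"time{ri}"
            covariates[col] = rng.uniform(0.0, 10.0, size=q)
            ncoef = order + 1
        else:
            legendre = None
            col = None
            ncoef = 1
        lvl_col = f"lvl{ri}"
        class_codes[lvl_col] = rng.integers(1, L + 1, size=q)
        effects.append(
            ResolvedEffect(
                name=f"rand{ri}",
                kind="random",
                n_levels=L,
                level_column=lvl_col,
                covariate_column=col,
                legendre=legendre,
                kinship_inv=kin,
                covariance=random_spd(rng, ncoef * t, scale=0.5),
            )
        )

    n_classes = 2 if rng.random() < 0.4 else 1
    residual_covs = {
        c + 1: random_spd(rng, t, scale=1.0) for c in range(n_classes)
    }
    residual_class = rng.integers(1, n_classes + 1, size=q)
    weights = rng.uniform(0.5, 3.0, size=q) if rng.random() < 0.5 else None

    y = rng.standard_normal((q, t))
    if t > 1 and rng.random() < 0.7:
        miss = rng.random((q, t)) < 0.25
        # the first records cover every fixed level once; keep them fully
        # observed so no (level, trait) equation is left without data
        miss[:4] = False
        for j in range(q):
            if miss[j].all():
                miss[j, rng.integers(0, t)] = False
        y = np.where(miss, np.nan, y)

    table = PhenotypeTable(
        y=y,
        trait_names=traits,
        class_codes=class_codes,
        covariates=covariates,
        weights=weights,
        residual_class=residual_class,
    )
    model = ModelSpec(
        trait_names=traits, effects=effects, residual_covs=residual_covs
    )
    return table, model, build_layout(model)


# ---------------------------------------------------------------------------
# text writers (the exact formats the readers consume)
# ---------------------------------------------------------------------------

def write_pedigree_file(path, ped: Pedigree, unknown: str = "0") -> None:
    labels = ped.labels or [str(i + 1) for i in range(ped.n)]
    with open(path, "w") as fh:
        for i in range(ped.n):
            s = labels[ped.sire[i]] if ped.sire[i] >= 0 else unknown
            d = labels[ped.dam[i]] if ped.dam[i] >= 0 else unknown
            fh.write(f"{labels[i]} {s} {d}\n")


def write_genotype_file(path, geno: GenotypeMatrix, missing: str = "NA") -> None:
    with open(path, "w") as fh:
        for i in range(geno.n_individuals):
            vals = [
                missing if geno.missing[i, j] else str(int(geno.S[i, j]))
                for j in range(geno.n_loci)
            ]
            fh.write(geno.labels[i] + " " + " ".join(vals) + "\n")


def write_phenotype_file(
    path,
    table: PhenotypeTable,
    id_labels: dict[str, list[str]] | None = None,
    missing: str = "NA",
) -> None:
    """Write records with a header; categorical codes become labels if maps
    are given."""
    cols = (
        list(table.class_codes)
        + list(table.covariates)
        + list(table.trait_names)
        + ["weight", "rclass"]
    )
    with open(path, "w") as fh:
        fh.write(" ".join(cols) + "\n")
        for j in range(table.q):
            row: list[str] = []
            for name, codes in table.class_codes.items():
                code = int(codes[j])
                if id_labels and name in id_labels:
                    row.append(id_labels[name][code - 1])
                else:
                    row.append(str(code))
            for name, vals in table.covariates.items():
                row.append(f"{vals[j]:.10g}")
            for k in range(table.n_traits):
                v = table.y[j, k]
                row.append(missing if np.isnan(v) else f"{v:.10g}")
            row.append(f"{table.weights[j]:.10g}")
            row.append(str(int(table.residual_class[j])))
            fh.write(" ".join(row) + "\n")


def write_truth_file(path, u: np.ndarray, labels: list[str], trait_names: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("id trait true_value\n")
        for i, lab in enumerate(labels):
            for k, tn in enumerate(trait_names):
                fh.write(f"{lab} {tn} {u[i, k]:.10g}\n")


def write_gblup_dataset(outdir, cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Write a complete, solvable multi-trait GBLUP dataset.

    Emits pedigree, genotypes, phenotypes (with DRP-style weights), the
    truth file and a ready-to-run parameter file; returns the file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped = simulate_pedigree(cfg, rng)
    geno = simulate_genotypes(ped, cfg, rng)
    table, u = simulate_phenotypes(geno, cfg, rng)
    labels = list(geno.labels)

    paths = {
        "pedigree": outdir / "pedigree.txt",
        "genotypes": outdir / "genotypes.txt",
        "phenotypes": outdir / "phenotypes.txt",
        "truth": outdir / "truth.txt",
        "parameters": outdir / "model.par",
    }
    write_pedigree_file(paths["pedigree"], ped)
    write_genotype_file(paths["genotypes"], geno)
    write_phenotype_file(paths["phenotypes"], table, id_labels={"id": labels})
    write_truth_file(paths["truth"], u, labels, table.trait_names)

    t = cfg.t_traits
    lines = [
        "# synthetic multi-trait GBLUP with record weights",
        "DATAFILES",
        "  phenotypes = phenotypes.txt",
        "  genotypes = genotypes.txt",
        "TRAITS",
        "  names = " + " ".join(table.trait_names),
        "EFFECT mean",
        "  kind = fixed_class",
        "EFFECT animal",
        "  kind = random",
        "  column = id",
        "  kinship = genomic",
        "  covariance = G0",
        "COVARIANCE G0",
    ]
    for i in range(t):
        lines.append(
            f"  row{i + 1} = " + " ".join(f"{v:.10g}" for v in cfg.genetic_cov[i])
        )
    lines += ["RESIDUAL", "  weight_column = weight", "RESIDUAL_COVARIANCE default"]
    for i in range(t):
        lines.append(
            f"  row{i + 1} = " + " ".join(f"{v:.10g}" for v in cfg.residual_cov[i])
        )
    lines += ["GOPTIONS", "  diag_load = 0.01", "SOLVER", "  tolerance = 1e-12"]
    paths["parameters"].write_text("\n".join(lines) + "\n")
    return paths
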