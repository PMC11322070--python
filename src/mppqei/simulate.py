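"""Forward simulator for multi-parent populations in multi-environment trials.

Generates (i) chromosome mosaics of founder origin by explicit meiosis under
a Haldane (no-interference) model, (ii) exact IBD allele-copy sets on an
evaluation grid, optionally blurred toward the family prior to emulate the
uncertainty of marker-derived IBD, and (iii) MET phenotypes composed of
family-by-environment intercepts, QTL effects of any of the four
consistency types, a Kronecker-structured polygenic effect and
environment-specific residual noise.  All true components are returned for
recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    EvaluationGrid,
    GeneticMap,
    IBDSet,
    ObservationIndex,
    PhenotypeTable,
    PopulationDesign,
)

__all__ = [
    "ChromosomeMosaic",
    "TrueQTL",
    "PolygenicSpec",
    "SimulationConfig",
    "SimulationResult",
    "simulate_meiosis",
    "simulate_population",
    "mosaics_to_ibd",
    "simulate_phenotypes",
    "simulate_dataset",
]

EFFECT_TYPES = ("ecfc", "esfc", "ecfs", "esfs")
EFFECT_TYPE_NAMES = {
    "ecfc": "EC&FC", "esfc": "ES&FC", "ecfs": "EC&FS", "esfs": "ES&FS",
}


@dataclass(frozen=True)
class ChromosomeMosaic:
    """One homolog of one chromosome as contiguous founder segments.

    ``ends[i]`` is the cM end of segment i (ends[-1] = chromosome length);
    ``founders[i]`` is the founder index carried on [ends[i-1], ends[i]).
    """

    ends: np.ndarray
    founders: np.ndarray

    def __post_init__(self):
        if len(self.ends) != len(self.founders) or len(self.ends) == 0:
            raise ValueError("mosaic needs matching, non-empty ends/founders")
        if np.any(np.diff(self.ends) <= 0):
            raise ValueError("segment ends must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.ends[-1])

    def founder_at(self, pos) -> np.ndarray:
        """Founder index at position(s); right-closed at chromosome end."""
        idx = np.searchsorted(self.ends, np.asarray(pos, dtype=float), side="right")
        idx = np.minimum(idx, len(self.founders) - 1)
        return self.founders[idx]

    def simplify(self) -> "ChromosomeMosaic":
        keep = np.append(self.founders[:-1] != self.founders[1:], True)
        return ChromosomeMosaic(self.ends[keep], self.founders[keep])


# individual = dict chrom -> (ChromosomeMosaic, ChromosomeMosaic)
Individual = dict


def _founder_individual(gmap: GeneticMap, founder_code: int) -> Individual:
    out = {}
    for chrom in gmap.chromosomes:
        L = gmap.length(chrom)
        # zero-length chromosomes degenerate to a single point segment
        hom = ChromosomeMosaic(np.array([L if L > 0 else 1e-12]),
                               np.array([founder_code]))
        out[chrom] = (hom, hom)
    return out


def simulate_meiosis(homA: ChromosomeMosaic, homB: ChromosomeMosaic,
                     rng: np.random.Generator) -> ChromosomeMosaic:
    """One recombinant gamete from a pair of homologs (Haldane model).

    Crossover count ~ Poisson(length/100); crossover positions uniform on
    the chromosome; no interference.
    """
    L = homA.length
    n_cross = rng.poisson(L / 100.0) if L > 1e-9 else 0
    if n_cross == 0:
        src = homA if rng.integers(2) == 0 else homB
        return src
    xs = np.sort(rng.uniform(0.0, L, size=n_cross))
    cur = int(rng.integers(2))
    homs = (homA, homB)
    ends, founders = [], []
    prev = 0.0
    for x in np.append(xs, L):
        h = homs[cur]
        # copy h's segments overlapping (prev, x]
        i0 = int(np.searchsorted(h.ends, prev, side="right"))
        i1 = int(np.searchsorted(h.ends, x, side="left"))
        for i in range(i0, i1 + 1):
            seg_end = min(float(h.ends[i]), x)
            if seg_end > prev + 1e-12:
                ends.append(seg_end)
                founders.append(int(h.founders[i]))
                prev = seg_end
        if prev < x - 1e-12:
            ends.append(x)
            founders.append(int(h.founders[min(i1, len(h.founders) - 1)]))
            prev = x
        cur = 1 - cur
    ends[-1] = L
    return ChromosomeMosaic(np.asarray(ends), np.asarray(founders)).simplify()


def _cross(mother: Individual, father: Individual, rng) -> Individual:
    return {c: (simulate_meiosis(*mother[c], rng), simulate_meiosis(*father[c], rng))
            for c in mother}


def _self(ind: Individual, rng) -> Individual:
    return _cross(ind, ind, rng)


def _double_haploid(ind: Individual, rng) -> Individual:
    out = {}
    for c, (a, b) in ind.items():
        g = simulate_meiosis(a, b, rng)
        out[c] = (g, g)
    return out


def _magic_funnel_line(founder_inds: list[Individual], rng,
                       selfing_generations: int) -> Individual:
    """One RIL from a balanced funnel over a power-of-two founder set."""
    order = rng.permutation(len(founder_inds))
    layer = [founder_inds[i] for i in order]
    while len(layer) > 1:
        layer = [_cross(layer[2 * i], layer[2 * i + 1], rng)
                 for i in range(len(layer) // 2)]
    line = layer[0]
    for _ in range(selfing_generations):
        line = _self(line, rng)
    return line


def simulate_population(design: PopulationDesign, gmap: GeneticMap,
                        n_per_family: int, rng: np.random.Generator
                        ) -> tuple[list[str], dict[str, str], dict[str, Individual]]:
    """Simulate all offspring of a design.

    Returns (genotype labels, genotype->family map, genotype->mosaics).
    Biparental DH lines are one doubled gamete of the F1; biparental RILs
    are the F1 selfed for the configured number of generations (residual
    heterozygosity kept); MAGIC lines descend one balanced random funnel
    each, then the selfing series.
    """
    parent_code = {p: i for i, p in enumerate(design.parents)}
    founder_inds = {p: _founder_individual(gmap, parent_code[p]) for p in design.parents}
    genotypes, fam_of, mosaics = [], {}, {}
    if design.magic:
        P = design.n_parents
        if P & (P - 1) != 0:
            raise ValueError("balanced MAGIC funnel requires a power-of-two founder count")
        fam = design.families[0]
        finds = [founder_inds[p] for p in fam.parents]
        for i in range(n_per_family):
            label = f"{fam.name}_{i + 1:04d}"
            mosaics[label] = _magic_funnel_line(finds, rng, design.selfing_generations)
            genotypes.append(label)
            fam_of[label] = fam.name
        return genotypes, fam_of, mosaics
    for fam in design.families:
        p1, p2 = fam.parents
        f1 = _cross(founder_inds[p1], founder_inds[p2], rng)
        for i in range(n_per_family):
            label = f"{fam.name}_{i + 1:04d}"
            if design.offspring == "dh":
                ind = _double_haploid(f1, rng)
            else:
                ind = f1
                for _ in range(design.selfing_generations):
                    ind = _self(ind, rng)
            mosaics[label] = ind
            genotypes.append(label)
            fam_of[label] = fam.name
    return genotypes, fam_of, mosaics


def mosaics_to_ibd(genotypes: list[str], fam_of: dict[str, str],
                   mosaics: dict[str, Individual], design: PopulationDesign,
                   grid: EvaluationGrid, blur: float = 0.0) -> IBDSet:
    """Exact IBD allele-copy counts on the grid, optionally blurred.

    With ``blur`` in [0, 1) each row is mixed toward the family prior
    (uniform over the family's founders, scaled to sum 2):
    pi' = (1 - blur) * pi + blur * prior.  Row sums stay exactly 2.
    """
    if not 0.0 <= blur < 1.0:
        raise ValueError("blur must lie in [0, 1)")
    P = design.n_parents
    parent_code = {p: i for i, p in enumerate(design.parents)}
    priors = {}
    for fam in design.families:
        pr = np.zeros(P)
        for p in fam.parents:
            pr[parent_code[p]] = 2.0 / len(fam.parents)
        priors[fam.name] = pr
    pi = np.zeros((len(genotypes), grid.n_positions, P))
    chroms = grid.chromosomes
    chrom_pos = {c: grid.positions(c) for c in chroms}
    for gi, g in enumerate(genotypes):
        ind = mosaics[g]
        off = 0
        for chrom in chroms:
            pos = chrom_pos[chrom]
            a, b = ind[chrom]
            fa = a.founder_at(pos)
            fb = b.founder_at(pos)
            block = np.zeros((len(pos), P))
            np.add.at(block, (np.arange(len(pos)), fa), 1.0)
            np.add.at(block, (np.arange(len(pos)), fb), 1.0)
            pi[gi, off:off + len(pos)] = block
            off += len(pos)
        if blur > 0:
            pi[gi] = (1 - blur) * pi[gi] + blur * priors[fam_of[g]]
    return IBDSet(list(genotypes), list(design.parents), grid, pi,
                  family_of=dict(fam_of))


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

@dataclass
class TrueQTL:
    """A simulated QTL: position, consistency type and parental effects.

    ``effects`` may be given explicitly with the type's natural shape —
    ecfc: (P,); esfc: (J, P); ecfs: (C, 2); esfs: (J, C, 2) — or drawn
    i.i.d. normal with ``variance`` (scalar, or per-environment /
    per-family / per-(env, family) array matching the type).
    """

    chrom: str
    pos_cM: float
    effect_type: str
    effects: np.ndarray | None = None
    variance: float | np.ndarray | None = None

    def __post_init__(self):
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(f"unknown QTL effect type {self.effect_type!r}")
        if self.effects is None and self.variance is None:
            raise ValueError("TrueQTL needs either effects or a variance")

    def realize(self, P: int, J: int, C: int, rng) -> np.ndarray:
        shape = {"ecfc": (P,), "esfc": (J, P), "ecfs": (C, 2),
                 "esfs": (J, C, 2)}[self.effect_type]
        if self.effects is not None:
            eff = np.asarray(self.effects, dtype=float)
            if eff.shape != shape:
                raise ValueError(
                    f"{self.effect_type} effects must have shape {shape}, got {eff.shape}"
                )
            return eff
        var = np.asarray(self.variance, dtype=float)
        # broadcast per-component variances over the parent/slot axis
        if var.ndim == 0:
            sd = np.full(shape, np.sqrt(var))
        else:
            sd = np.sqrt(np.broadcast_to(var.reshape(var.shape + (1,) * (len(shape) - var.ndim)), shape))
        return rng.standard_normal(shape) * sd


@dataclass
class PolygenicSpec:
    """Kronecker polygenic covariance: Sigma_MET (J x J) x MPP structure.

    ``met_cov`` is the full between-environment genetic covariance matrix.
    The MPP factor is either per-family weights (id/idh; id = all ones) or a
    genotype kinship matrix (kin).
    """

    met_cov: np.ndarray
    mpp_weights: np.ndarray | None = None   # per family, id/idh
    kinship: np.ndarray | None = None       # G x G, kin

    @classmethod
    def from_corr(cls, variances, corr, mpp_weights=None, kinship=None):
        v = np.asarray(variances, dtype=float)
        J = len(v)
        R = np.asarray(corr, dtype=float)
        if R.ndim == 0:
            R = np.full((J, J), float(R))
            np.fill_diagonal(R, 1.0)
        sd = np.sqrt(v)
        return cls(R * np.outer(sd, sd), mpp_weights=mpp_weights, kinship=kinship)

    def validate(self, J: int, C: int):
        if self.met_cov.shape != (J, J):
            raise ValueError("met_cov has wrong shape")
        w = np.linalg.eigvalsh(self.met_cov)
        if w.min() < -1e-8:
            raise ValueError("met_cov is not positive semi-definite")
        if self.mpp_weights is not None and len(self.mpp_weights) != C:
            raise ValueError("mpp_weights must have one entry per family")


@dataclass
class SimulationConfig:
    design: PopulationDesign
    gmap: GeneticMap
    n_per_family: int
    n_env: int
    qtls: list[TrueQTL] = field(default_factory=list)
    polygenic: PolygenicSpec | None = None
    residual_var: float | np.ndarray = 1.0
    intercepts: np.ndarray | None = None   # C x J family-by-environment means
    trait: str = "trait"
    grid_step: float = 5.0
    ibd_blur: float = 0.0
    seed: int = 0

    @property
    def env_labels(self) -> list[str]:
        return [f"E{j + 1}" for j in range(self.n_env)]


@dataclass
class SimulationResult:
    config: SimulationConfig
    ibd: IBDSet
    phenotypes: PhenotypeTable
    obs: ObservationIndex
    true_effects: list[np.ndarray]
    true_polygenic: np.ndarray   # per observation
    true_residual: np.ndarray    # per observation
    seed: int


def _canonical_obs(genotypes, fam_of, env_labels, families, trait, values) -> ObservationIndex:
    recs = []
    fam_order = {f: i for i, f in enumerate(families)}
    for j, env in enumerate(env_labels):
        for g in sorted(genotypes, key=lambda g: (fam_order[fam_of[g]], g)):
            recs.append((g, fam_of[g], env, trait))
    df = pd.DataFrame(recs, columns=["genotype", "family", "env", "trait"])
    df["value"] = values
    env_idx = df["env"].map({e: i for i, e in enumerate(env_labels)}).to_numpy(np.intp)
    fam_idx = df["family"].map(fam_order).to_numpy(np.intp)
    return df, env_idx, fam_idx


def simulate_phenotypes(config: SimulationConfig, ibd: IBDSet,
                        rng: np.random.Generator | None = None) -> SimulationResult:
    """Run the observation model forward on a simulated IBD set.

    Y = family-by-environment intercepts + sum_q Z_q u_q + polygenic + residual,
    with Z_q built by :mod:`mppqei.qtl_design` for each QTL's type.
    """
    from . import qtl_design  # deferred: avoids a cycle at import time

    if rng is None:
        rng = np.random.default_rng(config.seed)
    design = config.design
    J, C, P = config.n_env, design.n_families, design.n_parents
    if config.polygenic is not None:
        config.polygenic.validate(J, C)
    genotypes = list(ibd.genotypes)
    fam_of = ibd.family_of
    families = [f.name for f in design.families]
    env_labels = config.env_labels
    G = len(genotypes)
    N = G * J

    df, env_idx, fam_idx = _canonical_obs(genotypes, fam_of, env_labels,
                                          families, config.trait, np.zeros(N))
    geno_idx = ibd.genotype_index(df["genotype"].tolist())
    obs = ObservationIndex(df, config.trait, env_labels, families,
                           geno_idx, env_idx, fam_idx, 0)

    y = np.zeros(N)
    if config.intercepts is not None:
        inter = np.asarray(config.intercepts, dtype=float)
        y += inter[fam_idx, env_idx]

    true_effects = []
    for q in config.qtls:
        gi = ibd.grid.nearest_index(q.chrom, q.pos_cM)
        dz = qtl_design.build_design(ibd, obs, grid_index=gi,
                                     effect_type=q.effect_type)
        u = q.realize(P, J, C, rng)
        true_effects.append(u)
        y += dz.matrix @ u.ravel()

    g_obs = np.zeros(N)
    if config.polygenic is not None:
        spec = config.polygenic
        Lm = np.linalg.cholesky(spec.met_cov + 1e-12 * np.eye(J))
        Zg = rng.standard_normal((G, J))
        if spec.kinship is not None:
            K = np.asarray(spec.kinship, dtype=float)
            Lk = np.linalg.cholesky(K + 1e-10 * np.eye(G))
            gmat = Lk @ Zg @ Lm.T
        else:
            w = np.ones(C) if spec.mpp_weights is None else np.asarray(spec.mpp_weights, float)
            fam_code = np.array([families.index(fam_of[g]) for g in genotypes])
            gmat = (np.sqrt(w[fam_code])[:, None]) * (Zg @ Lm.T)
        g_obs = gmat[geno_idx, env_idx]
        y += g_obs

    rv = np.asarray(config.residual_var, dtype=float)
    if rv.ndim == 0:
        rv = np.full(J, float(rv))
    eps = rng.standard_normal(N) * np.sqrt(rv[env_idx])
    y += eps

    df = df.assign(value=y)
    obs = ObservationIndex(df, config.trait, env_labels, families,
                           geno_idx, env_idx, fam_idx, 0)
    pheno = PhenotypeTable(df[["genotype", "family", "env", "trait", "value"]].copy())
    return SimulationResult(config, ibd, pheno, obs, true_effects, g_obs, eps, config.seed)


def simulate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> SimulationResult:
    """Population -> exact IBD -> phenotypes, all from one seeded stream."""
    from .core_data import build_grid

    if rng is None:
        rng = np.random.default_rng(config.seed)
    genotypes, fam_of, mosaics = simulate_population(
        config.design, config.gmap, config.n_per_family, rng)
    grid = build_grid(config.gmap, config.grid_step)
    ibd = mosaics_to_ibd(genotypes, fam_of, mosaics, config.design, grid,
                         blur=config.ibd_blur)
    return simulate_phenotypes(config, ibd, rng)
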