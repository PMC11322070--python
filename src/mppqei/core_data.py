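"""Core data model: genetic maps, evaluation grids, IBD probabilities and
phenotypic means for multi-environment trials on multi-parent populations.

The containers here are deliberately thin wrappers around pandas/numpy
objects.  All downstream modules rely on two conventions fixed in this
module:

* **Allele-copy convention** — IBD values are expected numbers of parental
  allele *copies*: for fully inbred diploid lines every (genotype, position)
  row of the ``pi`` tensor sums to 2.  Files that store parental-origin
  *probabilities* (rows summing to 1) are rescaled on read.

* **Canonical observation ordering** — observations are sorted by
  environment, then family, then genotype (see :func:`align`).  This makes
  the direct-sum block structures of the QTL design matrices literally
  block-diagonal and fixes the row order of the response vector and every
  design matrix.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataFormatError",
    "GeneticMap",
    "EvaluationGrid",
    "Family",
    "PopulationDesign",
    "IBDSet",
    "PhenotypeTable",
    "ObservationIndex",
    "read_map",
    "write_map",
    "build_grid",
    "read_ibd",
    "write_ibd",
    "read_phenotypes",
    "write_phenotypes",
    "align",
]


class DataFormatError(ValueError):
    """Raised when an input file violates the format or integrity rules."""


def _read_delimited(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited text file with a header line."""
    with open(path, "rt") as fh:
        head = fh.readline()
        if not head.strip():
            raise DataFormatError(f"{path}: empty input file")
        sep = "\t" if head.count("\t") >= head.count(",") else ","
        fh.seek(0)
        return pd.read_csv(fh, sep=sep, dtype={"genotype": str})


# ---------------------------------------------------------------------------
# Genetic map and evaluation grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker/locus positions (cM) per chromosome."""

    table: pd.DataFrame  # columns: chrom (str), pos_cM (float), sorted

    def __post_init__(self):
        t = self.table
        if t.empty:
            raise DataFormatError("genetic map is empty")
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_cM"].to_numpy()
            if np.any(pos < 0):
                raise DataFormatError(f"chromosome {chrom}: negative position")
            if np.any(np.diff(pos) <= 0):
                bad = sub.iloc[int(np.argmax(np.diff(pos) <= 0)) + 1]
                raise DataFormatError(
                    f"duplicated or unsorted position on chromosome {chrom} "
                    f"at {bad['pos_cM']} cM"
                )

    @classmethod
    def from_rows(cls, rows: Sequence[tuple]) -> "GeneticMap":
        df = pd.DataFrame(rows, columns=["chrom", "pos_cM"])
        df["chrom"] = df["chrom"].astype(str)
        df["pos_cM"] = df["pos_cM"].astype(float)
        df = df.sort_values(["chrom", "pos_cM"], kind="stable").reset_index(drop=True)
        return cls(df)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos_cM"].to_numpy()

    def length(self, chrom: str) -> float:
        return float(self.positions(chrom)[-1])


@dataclass(frozen=True)
class EvaluationGrid:
    """Fixed-step genome grid on which IBD values are evaluated."""

    table: pd.DataFrame  # columns: chrom, pos_cM
    step: float

    @property
    def n_positions(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos_cM"].to_numpy()

    def index_of(self, chrom: str, pos: float, atol: float = 1e-9) -> int:
        """Integer index of a grid point; raises KeyError if off-grid."""
        mask = (self.table["chrom"] == str(chrom)) & (
            np.abs(self.table["pos_cM"] - pos) <= atol
        )
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise KeyError(f"position {chrom}:{pos} is not on the grid")
        return int(idx[0])

    def nearest_index(self, chrom: str, pos: float) -> int:
        sub = self.table[self.table["chrom"] == str(chrom)]
        if sub.empty:
            raise KeyError(f"chromosome {chrom} not on grid")
        i = (sub["pos_cM"] - pos).abs().idxmin()
        return int(self.table.index.get_loc(i))


def build_grid(gmap: GeneticMap, step: float = 5.0) -> EvaluationGrid:
    """Regular grid from each chromosome's first position, end point included."""
    if step <= 0:
        raise ValueError(f"grid step must be positive, got {step}")
    rows = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        start, end = float(pos[0]), float(pos[-1])
        n = int(np.floor((end - start) / step + 1e-9))
        pts = start + step * np.arange(n + 1)
        if end - pts[-1] > 1e-9:
            pts = np.append(pts, end)
        rows.append(pd.DataFrame({"chrom": chrom, "pos_cM": pts}))
    return EvaluationGrid(pd.concat(rows, ignore_index=True), step=float(step))


# ---------------------------------------------------------------------------
# Population design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Family:
    name: str
    parents: tuple[str, ...]  # two parents for biparental; all founders for MAGIC


@dataclass(frozen=True)
class PopulationDesign:
    """Parents and family structure of a multi-parent population.

    ``magic=True`` marks a single funnel family over all parents (C = 1);
    otherwise families are ordered biparental crosses.  ``offspring`` is
    ``"dh"`` or ``"ril"``; ``selfing_generations`` applies to RILs.
    """

    parents: tuple[str, ...]
    families: tuple[Family, ...]
    offspring: str = "dh"
    selfing_generations: int = 6
    magic: bool = False

    def __post_init__(self):
        if len(self.parents) < 2:
            raise ValueError("a population design needs at least 2 parents")
        if len(self.families) < 1:
            raise ValueError("a population design needs at least 1 family")
        if self.magic and len(self.families) != 1:
            raise ValueError("a MAGIC design has exactly one (funnel) family")
        pset = set(self.parents)
        for fam in self.families:
            unknown = set(fam.parents) - pset
            if unknown:
                raise ValueError(f"family {fam.name}: unknown parents {sorted(unknown)}")
            if not self.magic and len(fam.parents) != 2:
                raise ValueError(f"family {fam.name}: biparental families need 2 parents")
        if self.offspring not in ("dh", "ril"):
            raise ValueError("offspring must be 'dh' or 'ril'")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_parents(self, name: str) -> tuple[str, ...]:
        for fam in self.families:
            if fam.name == name:
                return fam.parents
        raise KeyError(name)

    @classmethod
    def diallel(cls, parents: Sequence[str], crosses: Sequence[tuple[str, str]],
                offspring: str = "dh", selfing_generations: int = 6) -> "PopulationDesign":
        fams = tuple(Family(f"{a}x{b}", (a, b)) for a, b in crosses)
        return cls(tuple(parents), fams, offspring, selfing_generations, magic=False)

    @classmethod
    def nam(cls, central: str, peripheral: Sequence[str],
            offspring: str = "dh", selfing_generations: int = 6) -> "PopulationDesign":
        fams = tuple(Family(f"{central}x{p}", (central, p)) for p in peripheral)
        return cls((central, *peripheral), fams, offspring, selfing_generations, magic=False)

    @classmethod
    def magic_funnel(cls, founders: Sequence[str], selfing_generations: int = 6,
                     name: str = "MAGIC") -> "PopulationDesign":
        fam = Family(name, tuple(founders))
        return cls(tuple(founders), (fam,), "ril", selfing_generations, magic=True)


# ---------------------------------------------------------------------------
# IBD probabilities
# ---------------------------------------------------------------------------

@dataclass
class IBDSet:
    """Expected parental allele-copy counts per genotype and grid position.

    ``pi`` has shape (G, n_positions, P); every (genotype, position) row sums
    to 2 (fully inbred diploid lines) and is non-negative.
    """

    genotypes: list[str]
    parents: list[str]
    grid: EvaluationGrid
    pi: np.ndarray
    family_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        G, M, P = self.pi.shape
        if G != len(self.genotypes) or M != self.grid.n_positions or P != len(self.parents):
            raise ValueError("pi tensor shape does not match labels/grid")
        self.validate()

    def validate(self, atol: float = 1e-8) -> None:
        if np.any(self.pi < -atol):
            raise DataFormatError("negative IBD allele-copy expectation")
        sums = self.pi.sum(axis=2)
        if np.any(np.abs(sums - 2.0) > atol):
            g, m = np.unravel_index(np.argmax(np.abs(sums - 2.0)), sums.shape)
            raise DataFormatError(
                f"IBD row for genotype {self.genotypes[g]} at grid index {m} "
                f"sums to {sums[g, m]:.6f}, expected 2"
            )

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    def genotype_index(self, labels: Sequence[str]) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.genotypes)}
        return np.array([lut[g] for g in labels], dtype=np.intp)


def _interp_ibd(values: pd.DataFrame, grid_pos: np.ndarray, parent_cols: list[str]) -> np.ndarray:
    """Linear interpolation of per-parent columns onto grid positions."""
    src = values["pos_cM"].to_numpy()
    out = np.empty((len(grid_pos), len(parent_cols)))
    for k, col in enumerate(parent_cols):
        out[:, k] = np.interp(grid_pos, src, values[col].to_numpy())
    # renormalize rows to sum exactly 2
    out = np.clip(out, 0.0, None)
    out *= 2.0 / out.sum(axis=1, keepdims=True)
    return out


def read_ibd(path, grid: EvaluationGrid) -> IBDSet:
    """Read long-format IBD values and place them on the evaluation grid.

    Columns: genotype, chrom, pos_cM, then one column per parent.  Rows may
    be probabilities (sum 1, rescaled x2) or allele copies (sum 2); the file
    convention is auto-detected from the median row sum.  Rows at off-grid
    positions are linearly interpolated between flanking supplied positions
    per parent and renormalized to sum 2.
    """
    df = _read_delimited(path)
    required = {"genotype", "chrom", "pos_cM"}
    if not required.issubset(df.columns):
        raise DataFormatError(f"{path}: IBD file needs columns {sorted(required)}")
    parent_cols = [c for c in df.columns if c not in required]
    if not parent_cols:
        raise DataFormatError(f"{path}: no parent columns found")
    vals = df[parent_cols].to_numpy(dtype=float)
    if np.any(vals < -1e-12):
        raise DataFormatError(f"{path}: negative IBD entries")
    row_sums = vals.sum(axis=1)
    target = float(np.median(row_sums))
    if abs(target - 1.0) < 0.25:
        scale, mode = 2.0, "probabilities"
    elif abs(target - 2.0) < 0.5:
        scale, mode = 1.0, "allele copies"
    else:
        raise DataFormatError(
            f"{path}: median IBD row sum {target:.4f} is neither ~1 nor ~2"
        )
    logger.info("read_ibd: interpreting %s as %s (median row sum %.4f)", path, mode, target)
    if np.any(np.abs(row_sums * scale - 2.0) > 1e-6):
        bad = int(np.argmax(np.abs(row_sums * scale - 2.0)))
        raise DataFormatError(
            f"{path}: row {bad} sums to {row_sums[bad]:.6f} after normalization"
        )
    df[parent_cols] = vals * scale
    df["chrom"] = df["chrom"].astype(str)

    genotypes = list(dict.fromkeys(df["genotype"]))
    pi = np.empty((len(genotypes), grid.n_positions, len(parent_cols)))
    grid_chroms = grid.chromosomes
    offsets = {}
    off = 0
    for chrom in grid_chroms:
        offsets[chrom] = off
        off += len(grid.positions(chrom))
    for gi, (geno, sub) in enumerate(df.groupby("genotype", sort=False)):
        for chrom in grid_chroms:
            ssub = sub[sub["chrom"] == chrom].sort_values("pos_cM")
            if ssub.empty:
                raise DataFormatError(
                    f"{path}: genotype {geno} has no IBD rows on chromosome {chrom}"
                )
            gp = grid.positions(chrom)
            o = offsets[chrom]
            pi[gi, o:o + len(gp), :] = _interp_ibd(ssub, gp, parent_cols)
    return IBDSet(genotypes, parent_cols, grid, pi)


def write_ibd(ibd: IBDSet, path) -> None:
    recs = []
    tab = ibd.grid.table
    for gi, geno in enumerate(ibd.genotypes):
        block = pd.DataFrame(ibd.pi[gi], columns=ibd.parents)
        block.insert(0, "pos_cM", tab["pos_cM"].to_numpy())
        block.insert(0, "chrom", tab["chrom"].to_numpy())
        block.insert(0, "genotype", geno)
        recs.append(block)
    pd.concat(recs, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Stacked genotypic means (BLUEs) with genotype/family/environment labels."""

    table: pd.DataFrame  # genotype, family, env, trait, value [, se]

    def __post_init__(self):
        t = self.table
        required = ["genotype", "family", "env", "trait", "value"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise DataFormatError(f"phenotype table missing columns {missing}")
        dup = t.duplicated(subset=["genotype", "env", "trait"])
        if dup.any():
            row = t[dup].iloc[0]
            raise DataFormatError(
                f"duplicated record for genotype {row['genotype']} in "
                f"environment {row['env']} trait {row['trait']}"
            )
        fam_count = t.groupby("genotype")["family"].nunique()
        if (fam_count > 1).any():
            g = fam_count[fam_count > 1].index[0]
            raise DataFormatError(f"genotype {g} assigned to multiple families")
        if "se" in t.columns and (t["se"].dropna() <= 0).any():
            raise DataFormatError("standard errors must be positive")

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.table["trait"]))

    @property
    def environments(self) -> list[str]:
        return sorted(self.table["env"].unique())

    @property
    def families(self) -> list[str]:
        return sorted(self.table["family"].unique())

    def n_records(self, trait: str | None = None) -> int:
        if trait is None:
            return len(self.table)
        return int((self.table["trait"] == trait).sum())

    def family_of(self) -> dict[str, str]:
        return dict(self.table.groupby("genotype", sort=False)["family"].first())

    def two_way(self, trait: str) -> pd.DataFrame:
        """Genotype x environment table of BLUEs for one trait."""
        sub = self.table[self.table["trait"] == trait]
        return sub.pivot(index="genotype", columns="env", values="value")


def read_phenotypes(path) -> PhenotypeTable:
    df = _read_delimited(path)
    for col in ("genotype", "family", "env", "trait"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    df["value"] = pd.to_numeric(df["value"])
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    cols = ["genotype", "family", "env", "trait", "value"]
    if "se" in pheno.table.columns:
        cols.append("se")
    pheno.table[cols].to_csv(path, index=False, float_format="%.12g")


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, index=False, float_format="%.12g")


def read_map(path) -> GeneticMap:
    df = _read_delimited(path)
    if not {"chrom", "pos_cM"}.issubset(df.columns):
        raise DataFormatError(f"{path}: map file needs columns chrom,pos_cM")
    try:
        df["pos_cM"] = pd.to_numeric(df["pos_cM"])
    except (ValueError, TypeError) as exc:
        raise DataFormatError(f"{path}: non-numeric map position ({exc})") from None
    df["chrom"] = df["chrom"].astype(str)
    dup = df.duplicated(subset=["chrom", "pos_cM"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DataFormatError(
            f"{path}: duplicated position chromosome {row['chrom']} at {row['pos_cM']} cM"
        )
    return GeneticMap.from_rows(list(df[["chrom", "pos_cM"]].itertuples(index=False)))


# ---------------------------------------------------------------------------
# Observation alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservationIndex:
    """Canonically ordered join of phenotype records with IBD genotypes.

    Rows are sorted by environment, then family, then genotype; this order is
    the row order of the response vector and of all design matrices.
    """

    table: pd.DataFrame          # genotype, family, env, value [, se]
    trait: str
    environments: list[str]      # ordered
    families: list[str]          # ordered
    geno_idx: np.ndarray         # per-observation index into IBDSet genotypes
    env_idx: np.ndarray          # per-observation index into environments
    fam_idx: np.ndarray          # per-observation index into families
    n_dropped: int

    @property
    def n_obs(self) -> int:
        return len(self.table)

    @property
    def y(self) -> np.ndarray:
        return self.table["value"].to_numpy(dtype=float)

    @property
    def n_env(self) -> int:
        return len(self.environments)

    @property
    def n_fam(self) -> int:
        return len(self.families)


def align(ibd: IBDSet, pheno: PhenotypeTable, trait: str | None = None,
          env_order: Sequence[str] | None = None) -> ObservationIndex:
    """Join phenotypes with IBD genotypes in the canonical observation order.

    Genotypes without IBD information are dropped (count logged).
    Environment order is lexicographic unless ``env_order`` is given.
    """
    if trait is None:
        traits = pheno.traits
        if len(traits) != 1:
            raise ValueError(f"trait must be named when table holds {traits}")
        trait = traits[0]
    sub = pheno.table[pheno.table["trait"] == trait].copy()
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    known = set(ibd.genotypes)
    keep = sub["genotype"].isin(known)
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise DataFormatError("no genotype overlap between IBD set and phenotypes")
    if n_dropped:
        logger.info("align: dropped %d phenotype records lacking IBD", n_dropped)
    sub = sub[keep]
    environments = list(env_order) if env_order is not None else sorted(sub["env"].unique())
    sub = sub[sub["env"].isin(environments)]
    families = sorted(sub["family"].unique())
    sub = sub.assign(
        _e=sub["env"].map({e: i for i, e in enumerate(environments)}),
        _f=sub["family"].map({f: i for i, f in enumerate(families)}),
    ).sort_values(["_e", "_f", "genotype"], kind="stable")
    geno_idx = ibd.genotype_index(sub["genotype"].tolist())
    env_idx = sub.pop("_e").to_numpy(dtype=np.intp)
    fam_idx = sub.pop("_f").to_numpy(dtype=np.intp)
    return ObservationIndex(
        table=sub.reset_index(drop=True),
        trait=trait,
        environments=environments,
        families=families,
        geno_idx=geno_idx,
        env_idx=env_idx,
        fam_idx=fam_idx,
        n_dropped=n_dropped,
    )
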