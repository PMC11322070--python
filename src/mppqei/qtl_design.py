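"""QTL design matrices from IBD allele-copy expectations.

Four random-effect structures express whether parental QTL effects are
consistent (C) or specific (S) across environments (E) and families (F):

* ``ecfc`` — one column per parent (N x P); entries are the expected
  parental allele copies pi for the observation's genotype.
* ``esfc`` — direct sum over environments of the ecfc matrix restricted to
  each environment's rows (N x PJ).
* ``ecfs`` — direct sum over families; each family contributes two columns
  holding pi for its own two parents on its own rows (N x 2C).
* ``esfs`` — direct sum over environment-by-family cells (N x 2CJ).

Rows follow the canonical observation order fixed by
:func:`mppqei.core_data.align`.  For MAGIC designs (one funnel family with
more than two founders) the family-specific structures are undefined and
rejected: effect consistency is considered only in relation to the
environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import IBDSet, ObservationIndex
from .simulate import EFFECT_TYPES, EFFECT_TYPE_NAMES

__all__ = ["QTLDesign", "build_design", "effect_index"]


@dataclass(frozen=True)
class QTLDesign:
    """A QTL design matrix with typed column labels."""

    matrix: np.ndarray                   # N x m, canonical row order
    effect_type: str
    chrom: str
    pos_cM: float
    parents: tuple[str, ...]             # column parent label per column
    environments: tuple[str | None, ...] # column environment (None = consistent)
    families: tuple[str | None, ...]     # column family (None = consistent)
    block: np.ndarray                    # per-column variance-component index

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_blocks(self) -> int:
        return int(self.block.max()) + 1

    def to_frame(self) -> pd.DataFrame:
        """Delimited-matrix form with typed column labels (debugging)."""
        cols = []
        for p, e, f in zip(self.parents, self.environments, self.families):
            cols.append("|".join(x for x in (p, e, f) if x))
        return pd.DataFrame(self.matrix, columns=cols)


def _family_parents(obs: ObservationIndex, ibd: IBDSet) -> dict[str, tuple[str, str]]:
    """Written cross order (P1c, P2c) per family, from the IBD family map."""
    fams = {}
    for fam in obs.families:
        members = [g for g, f in ibd.family_of.items() if f == fam]
        if not members:
            raise ValueError(f"family {fam} has no genotypes in the IBD set")
        # parents of a biparental family: founders with nonzero prior share
        share = ibd.pi[ibd.genotype_index(members)].sum(axis=(0, 1))
        order = [p for p in ibd.parents if share[ibd.parents.index(p)] > 1e-9]
        fams[fam] = tuple(order)
    return fams


def build_design(ibd: IBDSet, obs: ObservationIndex, *, grid_index: int | None = None,
                 chrom: str | None = None, pos_cM: float | None = None,
                 effect_type: str = "ecfc",
                 family_parents: dict[str, tuple[str, str]] | None = None) -> QTLDesign:
    """Build the design matrix of the requested effect type at one position.

    The position is given either as a ``grid_index`` or as ``chrom, pos_cM``
    (must lie on the grid).  ``family_parents`` overrides the inferred
    written cross order of each family's parents.
    """
    if effect_type not in EFFECT_TYPES:
        raise ValueError(f"unknown QTL effect type {effect_type!r}")
    if grid_index is None:
        if chrom is None or pos_cM is None:
            raise ValueError("give grid_index or (chrom, pos_cM)")
        grid_index = ibd.grid.index_of(chrom, pos_cM)
    row = ibd.grid.table.iloc[grid_index]
    chrom, pos_cM = str(row["chrom"]), float(row["pos_cM"])

    P = len(ibd.parents)
    J, C, N = obs.n_env, obs.n_fam, obs.n_obs
    pi_obs = ibd.pi[obs.geno_idx, grid_index, :]  # N x P

    if effect_type in ("ecfs", "esfs"):
        magic_like = C == 1 and P > 2
        if magic_like:
            raise ValueError(
                f"{EFFECT_TYPE_NAMES[effect_type]} is unsupported for a MAGIC "
                "design: with a single funnel family, effect consistency is "
                "considered only in relation to the environments"
            )
        if family_parents is None:
            family_parents = _family_parents(obs, ibd)
        for fam, ps in family_parents.items():
            if len(ps) != 2:
                raise ValueError(f"family {fam}: family-specific models need two parents")

    rows = np.arange(N)
    if effect_type == "ecfc":
        matrix = pi_obs
        parents = tuple(ibd.parents)
        envs = (None,) * P
        fams = (None,) * P
        block = np.zeros(P, dtype=np.intp)
    elif effect_type == "esfc":
        matrix = np.zeros((N, P * J))
        matrix[rows[:, None], obs.env_idx[:, None] * P + np.arange(P)[None, :]] = pi_obs
        parents = tuple(ibd.parents) * J
        envs = tuple(e for e in obs.environments for _ in range(P))
        fams = (None,) * (P * J)
        block = np.repeat(np.arange(J), P)
    elif effect_type == "ecfs":
        matrix = np.zeros((N, 2 * C))
        parents_l, envs_l, fams_l = [], [], []
        pidx = {p: k for k, p in enumerate(ibd.parents)}
        for c, fam in enumerate(obs.families):
            p1, p2 = family_parents[fam]
            sel = obs.fam_idx == c
            matrix[sel, 2 * c] = pi_obs[sel, pidx[p1]]
            matrix[sel, 2 * c + 1] = pi_obs[sel, pidx[p2]]
            parents_l += [p1, p2]
            envs_l += [None, None]
            fams_l += [fam, fam]
        parents, envs, fams = tuple(parents_l), tuple(envs_l), tuple(fams_l)
        block = np.repeat(np.arange(C), 2)
    else:  # esfs
        matrix = np.zeros((N, 2 * C * J))
        parents_l, envs_l, fams_l, block_l = [], [], [], []
        pidx = {p: k for k, p in enumerate(ibd.parents)}
        for j, env in enumerate(obs.environments):
            for c, fam in enumerate(obs.families):
                p1, p2 = family_parents[fam]
                col = 2 * (j * C + c)
                sel = (obs.env_idx == j) & (obs.fam_idx == c)
                matrix[sel, col] = pi_obs[sel, pidx[p1]]
                matrix[sel, col + 1] = pi_obs[sel, pidx[p2]]
                parents_l += [p1, p2]
                envs_l += [env, env]
                fams_l += [fam, fam]
                block_l += [j * C + c] * 2
        parents, envs, fams = tuple(parents_l), tuple(envs_l), tuple(fams_l)
        block = np.asarray(block_l, dtype=np.intp)

    return QTLDesign(matrix=matrix, effect_type=effect_type, chrom=chrom,
                     pos_cM=pos_cM, parents=parents, environments=envs,
                     families=fams, block=block)


def effect_index(design: QTLDesign) -> pd.DataFrame:
    """Column layout of the effect vector: parent / environment / family.

    One row per design column, in column order; used to label BLUPs as
    parental allele-effect profiles.
    """
    return pd.DataFrame({
        "column": np.arange(design.n_columns),
        "parent": design.parents,
        "env": [e if e is not None else "" for e in design.environments],
        "family": [f if f is not None else "" for f in design.families],
        "component": design.block,
    })
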