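"""GGE exploration of genotype-by-environment tables.

A rank-2 principal-component fit to the environment-centered genotype x
environment table of BLUEs: the first axis tracks genotypic main effects,
the second axis GEI.  Used to inspect genetic correlations between
environments before interpreting environment-specific QTLs.  Variant:
column (environment) centering, no scaling, symmetric singular-value
scaling of scores and loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GGEFit", "gge_fit", "env_correlations"]


@dataclass
class GGEFit:
    centered: pd.DataFrame
    singular_values: np.ndarray      # first two
    scores: pd.DataFrame             # genotypes x 2
    loadings: pd.DataFrame           # environments x 2
    explained: np.ndarray            # proportion of variation per axis

    def reconstruction(self) -> np.ndarray:
        """Rank-2 approximation of the centered table."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def _impute_rank2(M: np.ndarray, mask: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 500) -> np.ndarray:
    """EM-style iterative rank-2 imputation of missing cells."""
    X = M.copy()
    col_means = np.nanmean(M, axis=0)
    X[mask] = np.take(col_means, np.nonzero(mask)[1])
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        approx = (U[:, :2] * s[:2]) @ Vt[:2] + mu
        delta = np.max(np.abs(approx[mask] - X[mask])) if mask.any() else 0.0
        X[mask] = approx[mask]
        if delta < tol:
            break
    return X


def gge_fit(table: pd.DataFrame, max_missing: float = 0.2) -> GGEFit:
    """Rank-2 GGE decomposition of a genotype x environment table.

    Missing cells (at most ``max_missing`` of the table, no empty row or
    column) are imputed by iterative rank-2 EM for the decomposition only.
    Scores are U2*sqrt(S2), loadings V2*sqrt(S2); the first loading of each
    axis is made non-negative.
    """
    M = table.to_numpy(dtype=float)
    n_g, n_e = M.shape
    if n_g < 3 or n_e < 2:
        raise ValueError("rank-2 GGE needs >= 3 genotypes and >= 2 environments")
    mask = np.isnan(M)
    if mask.any():
        if mask.mean() > max_missing:
            raise ValueError(
                f"{mask.mean():.0%} missing cells exceed the {max_missing:.0%} limit")
        if mask.all(axis=1).any() or mask.all(axis=0).any():
            raise ValueError("empty genotype row or environment column")
        M = _impute_rank2(M, mask)
    centered = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    k = 2
    s2 = s[:k].copy()
    scores = U[:, :k] * np.sqrt(s2)
    loadings = Vt[:k].T * np.sqrt(s2)
    for ax in range(k):
        if loadings[0, ax] < 0:
            loadings[:, ax] *= -1
            scores[:, ax] *= -1
    total = float(np.sum(s ** 2))
    explained = (s2 ** 2) / total if total > 0 else np.zeros(k)
    axes = ["PC1", "PC2"]
    return GGEFit(
        centered=pd.DataFrame(centered, index=table.index, columns=table.columns),
        singular_values=s2,
        scores=pd.DataFrame(scores, index=table.index, columns=axes),
        loadings=pd.DataFrame(loadings, index=table.columns, columns=axes),
        explained=explained,
    )


def env_correlations(table: pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """Product-moment correlations between environment columns.

    Pairs with fewer than ``min_overlap`` shared genotypes get NaN with a
    warning.  Symmetric with unit diagonal.
    """
    envs = list(table.columns)
    J = len(envs)
    R = np.full((J, J), np.nan)
    np.fill_diagonal(R, 1.0)
    for i in range(J):
        for j in range(i + 1, J):
            sub = table[[envs[i], envs[j]]].dropna()
            if len(sub) < min_overlap:
                warnings.warn(
                    f"environments {envs[i]} and {envs[j]} share only "
                    f"{len(sub)} genotypes; correlation set to NaN",
                    RuntimeWarning, stacklevel=2)
                continue
            R[i, j] = R[j, i] = np.corrcoef(sub[envs[i]], sub[envs[j]])[0, 1]
    return pd.DataFrame(R, index=envs, columns=envs)
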