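"""Parametric covariance structures for random model terms.

Each structure maps a parameter vector theta to an m x m covariance matrix
``cov(theta)`` with analytic derivatives ``dcov(theta)``.  Variance
parameters carry a non-negativity bound; unstructured matrices use a
triangular-factor parameterization with log-scaled diagonal so that the
implied matrix stays positive definite throughout optimization.

Nine polygenic structures arise as Kronecker combinations
Sigma_MET (id | idh | us) x Sigma_MPP (id | idh | kin).  The MET factor
carries all scale; the MPP factor is normalized — identity for ``id``,
per-family weights with the first family fixed at 1 for ``idh``, and the
unit-scaled kinship matrix for ``kin`` — which removes the scale
confounding inherent to a Kronecker product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CovStructure", "IDScale", "DiagGroups", "WeightsFixedFirst",
    "FixedCov", "Unstructured", "met_structure", "mpp_structure",
]

_POS = (0.0, np.inf)
_FREE = (-np.inf, np.inf)


class CovStructure:
    """Base class; subclasses define dim, n_params, bounds, cov, dcov."""

    dim: int
    n_params: int
    param_names: list[str]
    bounds: list[tuple[float, float]]

    def cov(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dcov(self, theta: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def init(self, scale: float) -> np.ndarray:
        raise NotImplementedError


@dataclass
class IDScale(CovStructure):
    """sigma^2 * I_m — one homogeneous variance."""

    dim: int
    name: str = "var"

    def __post_init__(self):
        self.n_params = 1
        self.param_names = [self.name]
        self.bounds = [_POS]

    def cov(self, theta):
        return theta[0] * np.eye(self.dim)

    def dcov(self, theta):
        return [np.eye(self.dim)]

    def init(self, scale):
        return np.array([scale])


@dataclass
class DiagGroups(CovStructure):
    """diag(theta[group]) — one variance per level group.

    Covers heterogeneous (idh) structures and all four QTL variance
    structures: the QTL blocks (environment and/or family components) are
    the groups.
    """

    groups: np.ndarray
    group_names: list[str] | None = None

    def __post_init__(self):
        self.groups = np.asarray(self.groups, dtype=np.intp)
        self.dim = len(self.groups)
        self.n_params = int(self.groups.max()) + 1
        names = self.group_names or [f"g{i}" for i in range(self.n_params)]
        self.param_names = [f"var[{n}]" for n in names]
        self.bounds = [_POS] * self.n_params

    def cov(self, theta):
        return np.diag(theta[self.groups])

    def dcov(self, theta):
        out = []
        for i in range(self.n_params):
            d = np.zeros(self.dim)
            d[self.groups == i] = 1.0
            out.append(np.diag(d))
        return out

    def init(self, scale):
        return np.full(self.n_params, scale)


@dataclass
class WeightsFixedFirst(CovStructure):
    """diag(1, w_2, ..., w_m) — normalized heterogeneous weights."""

    dim: int
    level_names: list[str] | None = None

    def __post_init__(self):
        self.n_params = self.dim - 1
        names = self.level_names or [f"l{i + 1}" for i in range(self.dim)]
        self.param_names = [f"weight[{n}]" for n in names[1:]]
        self.bounds = [_POS] * self.n_params

    def cov(self, theta):
        return np.diag(np.concatenate(([1.0], theta)))

    def dcov(self, theta):
        out = []
        for i in range(self.n_params):
            d = np.zeros(self.dim)
            d[i + 1] = 1.0
            out.append(np.diag(d))
        return out

    def init(self, scale):
        return np.ones(self.n_params)


@dataclass
class FixedCov(CovStructure):
    """A fixed, parameter-free PSD matrix (identity or kinship)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.dim = self.matrix.shape[0]
        self.n_params = 0
        self.param_names = []
        self.bounds = []

    def cov(self, theta):
        return self.matrix

    def dcov(self, theta):
        return []

    def init(self, scale):
        return np.empty(0)


@dataclass
class Unstructured(CovStructure):
    """Full covariance via a lower-triangular factor with log diagonal.

    theta lists the factor row by row: [log l_11, l_21, log l_22, ...];
    cov = L L'.  d(d+1)/2 parameters for dimension d.
    """

    dim: int
    level_names: list[str] | None = None

    def __post_init__(self):
        d = self.dim
        self.n_params = d * (d + 1) // 2
        names = self.level_names or [f"l{i + 1}" for i in range(d)]
        pn = []
        self._rows, self._cols, self._isdiag = [], [], []
        for i in range(d):
            for j in range(i + 1):
                self._rows.append(i)
                self._cols.append(j)
                self._isdiag.append(i == j)
                pn.append(f"chol[{names[i]},{names[j]}]")
        self.param_names = pn
        self.bounds = [_FREE] * self.n_params

    def factor(self, theta):
        # saturate the log-diagonal so extreme trial steps stay finite
        L = np.zeros((self.dim, self.dim))
        for k, (i, j, d) in enumerate(zip(self._rows, self._cols, self._isdiag)):
            L[i, j] = np.exp(np.clip(theta[k], -50.0, 50.0)) if d else theta[k]
        return L

    def cov(self, theta):
        L = self.factor(theta)
        return L @ L.T

    def dcov(self, theta):
        L = self.factor(theta)
        out = []
        for k, (i, j, d) in enumerate(zip(self._rows, self._cols, self._isdiag)):
            dL = np.zeros_like(L)
            dL[i, j] = L[i, j] if d else 1.0
            out.append(dL @ L.T + L @ dL.T)
        return out

    def init(self, scale, corr: float = 0.3):
        """Factor of scale * ((1-corr) I + corr J)."""
        S = scale * ((1 - corr) * np.eye(self.dim) + corr * np.ones((self.dim, self.dim)))
        L = np.linalg.cholesky(S)
        theta = np.empty(self.n_params)
        for k, (i, j, d) in enumerate(zip(self._rows, self._cols, self._isdiag)):
            theta[k] = np.log(L[i, j]) if d else L[i, j]
        return theta

    def theta_from_cov(self, S):
        L = np.linalg.cholesky(S)
        theta = np.empty(self.n_params)
        for k, (i, j, d) in enumerate(zip(self._rows, self._cols, self._isdiag)):
            theta[k] = np.log(L[i, j]) if d else L[i, j]
        return theta


def met_structure(kind: str, J: int, env_names: list[str] | None = None) -> CovStructure:
    kind = kind.lower()
    if kind == "id":
        return IDScale(J, name="met_var")
    if kind == "idh":
        return DiagGroups(np.arange(J), group_names=env_names)
    if kind == "us":
        return Unstructured(J, level_names=env_names)
    raise ValueError(f"unknown MET structure {kind!r} (use id, idh or us)")


def mpp_structure(kind: str, C: int, fam_names: list[str] | None = None,
                  kinship: np.ndarray | None = None) -> CovStructure:
    """MPP factor over families (id/idh) or genotypes (kin); normalized."""
    kind = kind.lower()
    if kind == "id":
        return FixedCov(np.eye(C))
    if kind == "idh":
        return WeightsFixedFirst(C, level_names=fam_names)
    if kind == "kin":
        if kinship is None:
            raise ValueError("kin structure needs a kinship matrix")
        return FixedCov(kinship)
    raise ValueError(f"unknown MPP structure {kind!r} (use id, idh or kin)")
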