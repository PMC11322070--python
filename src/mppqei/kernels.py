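"""REML likelihood kernels: value, score and average-information matrix.

Two interchangeable evaluation paths:

* :class:`DenseKernel` assembles the full N x N observation covariance
  V = sum_t Z_t G_t Z_t' + R and works by Cholesky factorization — fully
  general.

* :class:`BlockedKernel` applies when the only random terms are a
  Kronecker polygenic effect with a diagonal (id/idh-by-family) MPP factor
  and a diagonal residual: V is then block-diagonal over genotypes with at
  most one J x J block *pattern* per (family, environment-set) group, and
  every quantity reduces to batched small-matrix algebra.  This is the
  blocked Kronecker exploitation that keeps genome scans and replicated
  simulations fast; it is numerically equivalent to the dense path.

Both return the restricted log-likelihood
ll = -1/2 [ log|V| + log|X'V^-1X| + y'Py ] - (N-p)/2 log(2*pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class EvalResult:
    loglik: float
    beta: np.ndarray
    Py: np.ndarray
    score: np.ndarray | None = None
    ai: np.ndarray | None = None
    ok: bool = True


class DenseKernel:
    """General dense-V REML evaluation for a VarianceModel."""

    def __init__(self, model, y: np.ndarray):
        self.model = model
        self.y = np.asarray(y, dtype=float)
        self.N, self.p = model.X.shape

    def _factor(self, theta):
        if not np.all(np.isfinite(theta)):
            return None
        V = self.model.build_V(theta)
        if not np.all(np.isfinite(V)):
            return None
        jitter = 0.0
        for attempt in range(4):
            try:
                L = np.linalg.cholesky(V if jitter == 0 else V + jitter * np.eye(self.N))
                return L
            except np.linalg.LinAlgError:
                scale = max(np.mean(np.diag(V)), 1e-12)
                jitter = scale * 10.0 ** (-8 + 2 * attempt)
        return None

    def evaluate(self, theta, derivs: bool = True) -> EvalResult:
        X, y = self.model.X, self.y
        L = self._factor(theta)
        if L is None:
            return EvalResult(-np.inf, np.zeros(self.p), np.zeros(self.N), ok=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        # V^-1 via the factor (needed for score/AI anyway)
        Li = solve_triangular(L, np.eye(self.N), lower=True)
        Vi = Li.T @ Li
        W = Vi @ X
        XtViX = X.T @ W
        try:
            cX = cho_factor(XtViX)
        except np.linalg.LinAlgError:
            return EvalResult(-np.inf, np.zeros(self.p), np.zeros(self.N), ok=False)
        logdetX = 2.0 * np.sum(np.log(np.diag(cX[0])))
        Viy = Vi @ y
        beta = cho_solve(cX, X.T @ Viy)
        Py = Viy - W @ beta
        yPy = float(y @ Py)
        ll = -0.5 * (logdetV + logdetX + yPy) - 0.5 * (self.N - self.p) * _LOG2PI
        if not derivs:
            return EvalResult(ll, beta, Py)
        Pmat = Vi - W @ cho_solve(cX, W.T)
        q = self.model.n_params
        score = np.empty(q)
        U = np.empty((self.N, q))
        for i, dV in enumerate(self.model.iter_dV(theta)):
            u = dV @ Py
            t1 = float(np.sum(Pmat * dV))
            score[i] = -0.5 * (t1 - float(Py @ u))
            U[:, i] = u
        ai = 0.5 * (U.T @ (Pmat @ U))
        return EvalResult(ll, beta, Py, score, ai)

    def whitener(self, theta):
        """Return a function M -> L^-1 M for the V at theta."""
        L = self._factor(theta)
        if L is None:
            raise np.linalg.LinAlgError("V not positive definite at theta")
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))

        def whiten(M):
            return solve_triangular(L, M, lower=True)

        return whiten, logdetV


class BlockedKernel:
    """Per-genotype blocked REML evaluation.

    Applicable iff the model is exactly [polygenic kron(met, id/idh-family),
    residual diag] with each genotype observed at most once per environment.
    """

    def __init__(self, model, y: np.ndarray):
        from .reml import PolygenicTerm, ResidualTerm  # local: avoid cycle

        self.model = model
        self.y = np.asarray(y, dtype=float)
        self.N, self.p = model.X.shape
        terms = model.terms
        if len(terms) != 2:
            raise ValueError("blocked kernel needs [polygenic, residual] terms")
        poly, resid = terms
        if not isinstance(poly, PolygenicTerm) or poly.mpp_kind not in ("id", "idh"):
            raise ValueError("blocked kernel needs a diagonal-MPP polygenic term")
        if not isinstance(resid, ResidualTerm):
            raise ValueError("blocked kernel needs a diagonal residual term")
        self.poly, self.resid = poly, resid
        self.J = poly.met.dim
        self.C = poly.n_fam

        # group genotypes by (family, environment pattern)
        geno_obs: dict[int, list[int]] = {}
        for o, g in enumerate(poly.geno_idx):
            geno_obs.setdefault(int(g), []).append(o)
        groups: dict[tuple, list[list[int]]] = {}
        for g, obs_list in geno_obs.items():
            envs = tuple(int(poly.env_idx[o]) for o in obs_list)
            if len(set(envs)) != len(envs):
                raise ValueError("genotype observed twice in one environment")
            key = (int(poly.fam_code[g]), envs)
            groups.setdefault(key, []).append(obs_list)
        self.groups = []
        X = model.X
        for (fam, envs), rows in groups.items():
            idx = np.asarray(rows, dtype=np.intp)      # n_g x Jg obs indices
            e = np.asarray(envs, dtype=np.intp)
            self.groups.append({
                "fam": fam, "envs": e, "idx": idx,
                "ys": self.y[idx],                      # n_g x Jg
                "Xs": X[idx, :],                        # n_g x Jg x p
            })

    def _blocks(self, theta):
        poly, resid = self.poly, self.resid
        th_p = theta[:poly.n_params]
        th_r = theta[poly.n_params:]
        A = poly.met.cov(th_p[:poly.met.n_params])
        w = poly.family_weights(th_p)
        r = resid.variances(th_r)
        return A, w, r, th_p

    def evaluate(self, theta, derivs: bool = True) -> EvalResult:
        if not np.all(np.isfinite(theta)):
            return EvalResult(-np.inf, np.zeros(self.p), np.zeros(self.N), ok=False)
        A, w, r, th_p = self._blocks(theta)
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(w)) and np.all(np.isfinite(r))):
            return EvalResult(-np.inf, np.zeros(self.p), np.zeros(self.N), ok=False)
        p = self.p
        logdetV = 0.0
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        yViy = 0.0
        cache = []
        for grp in self.groups:
            e = grp["envs"]
            S = w[grp["fam"]] * A[np.ix_(e, e)] + np.diag(r[e])
            try:
                Lb = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                return EvalResult(-np.inf, np.zeros(p), np.zeros(self.N), ok=False)
            if not np.all(np.isfinite(Lb)):
                return EvalResult(-np.inf, np.zeros(p), np.zeros(self.N), ok=False)
            Sinv = cho_solve((Lb, True), np.eye(len(e)))
            n_g = grp["idx"].shape[0]
            logdetV += n_g * 2.0 * np.sum(np.log(np.diag(Lb)))
            SiX = np.einsum("jk,gkp->gjp", Sinv, grp["Xs"])
            XtViX += np.einsum("gjp,gjq->pq", grp["Xs"], SiX)
            XtViy += np.einsum("gjp,gj->p", SiX, grp["ys"])
            yViy += float(np.einsum("jk,gj,gk->", Sinv, grp["ys"], grp["ys"]))
            cache.append((S, Sinv, SiX, Lb))
        try:
            cX = cho_factor(XtViX)
        except np.linalg.LinAlgError:
            return EvalResult(-np.inf, np.zeros(p), np.zeros(self.N), ok=False)
        logdetX = 2.0 * np.sum(np.log(np.diag(cX[0])))
        beta = cho_solve(cX, XtViy)
        yPy = yViy - float(XtViy @ beta)
        ll = -0.5 * (logdetV + logdetX + yPy) - 0.5 * (self.N - p) * _LOG2PI
        Py = np.zeros(self.N)
        Pys_list = []
        for grp, (S, Sinv, SiX, Lb) in zip(self.groups, cache):
            resid_g = grp["ys"] - np.einsum("gjp,p->gj", grp["Xs"], beta)
            Pyg = np.einsum("jk,gk->gj", Sinv, resid_g)
            Py[grp["idx"]] = Pyg
            Pys_list.append(Pyg)
        if not derivs:
            return EvalResult(ll, beta, Py)

        poly, resid = self.poly, self.resid
        q = self.model.n_params
        B = cho_solve(cX, np.eye(p))
        dA = poly.met.dcov(th_p[:poly.met.n_params])
        n_met = poly.met.n_params
        n_w = poly.n_params - n_met
        t1 = np.zeros(q)
        t2 = np.zeros(q)
        ai_tr = np.zeros((q, q))
        c_vec = np.zeros((q, p))
        for grp, (S, Sinv, SiX, Lb), Pyg in zip(self.groups, cache, Pys_list):
            e = grp["envs"]
            n_g = grp["idx"].shape[0]
            fam = grp["fam"]
            Q = np.einsum("gj,gk->jk", Pyg, Pyg)
            Msum = np.einsum("gjp,pq,gkq->jk", SiX, B, SiX)
            Amat = n_g * Sinv - Msum
            dS = []
            for i in range(n_met):
                dS.append(w[fam] * dA[i][np.ix_(e, e)])
            for i in range(n_w):
                fam_i = i + 1  # weight parameters start at family 2
                dS.append(A[np.ix_(e, e)] if fam == fam_i else np.zeros((len(e), len(e))))
            for jv in range(resid.n_params):
                dS.append(np.diag((resid.groups_of(e) == jv).astype(float)))
            SdS = [Sinv @ d for d in dS]
            for i in range(q):
                t1[i] += float(np.sum(Amat * dS[i]))
                t2[i] += float(np.sum(Q * dS[i]))
                c_vec[i] += np.einsum("gj,jk,gkp->p", Pyg, dS[i] @ Sinv, grp["Xs"])
            for i in range(q):
                for jq in range(i, q):
                    ai_tr[i, jq] += float(np.sum((dS[i] @ SdS[jq]) * Q))
        ai_tr = ai_tr + np.triu(ai_tr, 1).T
        score = -0.5 * (t1 - t2)
        ai = 0.5 * (ai_tr - c_vec @ B @ c_vec.T)
        return EvalResult(ll, beta, Py, score, ai)

    def whitener(self, theta):
        A, w, r, _ = self._blocks(theta)
        logdetV = 0.0
        plans = []
        for grp in self.groups:
            e = grp["envs"]
            S = w[grp["fam"]] * A[np.ix_(e, e)] + np.diag(r[e])
            Lb = np.linalg.cholesky(S)
            n_g = grp["idx"].shape[0]
            logdetV += n_g * 2.0 * np.sum(np.log(np.diag(Lb)))
            Linv = solve_triangular(Lb, np.eye(len(e)), lower=True)
            plans.append((grp["idx"], Linv))

        def whiten(M):
            M = np.asarray(M, dtype=float)
            vec = M.ndim == 1
            if vec:
                M = M[:, None]
            out = np.empty_like(M)
            for idx, Linv in plans:
                out[idx] = np.einsum("jk,gkm->gjm", Linv, M[idx])
            return out[:, 0] if vec else out

        return whiten, logdetV
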