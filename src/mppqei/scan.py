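"""Genome-wide QEI scans with forward cofactor selection and AIC-based
resolution of each locus's effect type.

Protocol: for each QTL effect type, repeated genome scans are run; each
round tests every unmasked grid position with a likelihood-ratio test of
the position's QTL variance component(s) (0/1-df chi-square mixture),
adds the most significant position above a Bonferroni genome-wide
threshold as a cofactor, masks an exclusion window around it, and repeats
until no position exceeds the threshold.  The per-type multi-QTL models
are then combined: loci coinciding across types are merged and each
locus's effect type is chosen by AIC over candidate formulations.

By default the polygenic and residual (and cofactor) parameters are
estimated once per round under the no-QTL model and held fixed while each
position's QTL variance is profiled on the whitened data via low-rank
(Woodbury) identities; ``full_reml=True`` refits everything jointly at
every position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_solve, solve_triangular

from .core_data import IBDSet, ObservationIndex
from .qtl_design import build_design
from .reml import (FitResult, aic, background_model, blup_effects,
                   build_qtl_term, lrt_mixture_pvalue, reml_fit, _make_kernel)
from .simulate import EFFECT_TYPES, EFFECT_TYPE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig", "ScanProfile", "QTLRecord", "ScanData",
    "bonferroni_threshold", "genome_scan", "forward_select",
    "joint_position_test", "assemble_final_model", "report",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ScanConfig:
    alpha: float = 0.05
    window_cM: float = 20.0          # exclusion window width around a cofactor
    max_rounds: int = 10
    coincidence_cM: float = 10.0     # cross-type merge distance
    polygenic: tuple[str, str] = ("us", "idh")
    residual: str = "idh"
    full_reml: bool = False
    mixture: str = "0_1"             # or 'half_df' for joint multi-df tests

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if min(self.window_cM, self.max_rounds, self.coincidence_cM) <= 0:
            raise ValueError("window, rounds and coincidence distance must be positive")


@dataclass
class ScanData:
    """Aligned inputs shared by all scans of one trait."""

    ibd: IBDSet
    obs: ObservationIndex
    kinship: np.ndarray | None = None

    @property
    def grid(self):
        return self.ibd.grid


@dataclass
class ScanProfile:
    effect_type: str
    table: pd.DataFrame      # chrom, pos_cM, stat, p, neglog10p, masked, converged
    cofactors: list[int]     # grid indices used while scanning
    threshold: float

    def peak(self) -> tuple[int | None, float]:
        """(grid index, -log10 p) of the best unmasked converged position."""
        t = self.table
        ok = (~t["masked"]) & t["converged"]
        if not ok.any():
            return None, np.nan
        vals = t.loc[ok, "neglog10p"]
        best = vals.max()
        # tie-break: first in genomic order
        idx = vals.index[vals >= best - 1e-12][0]
        return int(idx), float(best)


@dataclass
class QTLRecord:
    chrom: str
    pos_cM: float
    effect_type: str
    peak_neglog10p: float
    effects: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """-log10 of the Bonferroni-corrected per-test significance level."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-np.log10(alpha / n_tests))


def _mask_windows(grid_tab: pd.DataFrame, cofactors: list[int], half: float) -> np.ndarray:
    masked = np.zeros(len(grid_tab), dtype=bool)
    for ci in cofactors:
        chrom = grid_tab.iloc[ci]["chrom"]
        pos = grid_tab.iloc[ci]["pos_cM"]
        masked |= ((grid_tab["chrom"] == chrom)
                   & ((grid_tab["pos_cM"] - pos).abs() <= half)).to_numpy()
    return masked


class _ProfiledScanner:
    """Profile a position's QTL variance(s) against a fixed background.

    Background covariance V0 comes from the round's no-QTL fit.  On the
    whitened scale V = I + U G(sigma) U', with U = L0^-1 Z_q of low rank,
    the REML log-likelihood is evaluated through small-matrix identities.
    """

    def __init__(self, whiten, logdetV0: float, X: np.ndarray, y: np.ndarray):
        self.whiten, self.logdetV0 = whiten, logdetV0
        self.N, self.p = X.shape
        self.Xw = self.whiten(X)
        self.yw = self.whiten(y)
        self.XtX = self.Xw.T @ self.Xw
        self.Xty = self.Xw.T @ self.yw
        self.yty = float(self.yw @ self.yw)
        self.const = -0.5 * (self.N - self.p) * _LOG2PI
        self.var_scale = float(np.var(y))

    @classmethod
    def from_fit(cls, null_fit: FitResult, y: np.ndarray) -> "_ProfiledScanner":
        kernel, _ = _make_kernel(null_fit.model, y)
        whiten, logdetV0 = kernel.whitener(null_fit.theta)
        return cls(whiten, logdetV0, null_fit.model.X, y)

    def _loglik(self, UtU, UtX, Uty, g_diag):
        """REML ll with V = I + U diag(g) U' on the whitened scale."""
        m = len(g_diag)
        s = np.sqrt(g_diag)
        Cm = np.eye(m) + (s[:, None] * UtU * s[None, :])
        try:
            Lc = np.linalg.cholesky(Cm)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = self.logdetV0 + 2.0 * np.sum(np.log(np.diag(Lc)))
        # (I + UGU')^-1 = I - U S C^-1 S U'
        SX = s[:, None] * UtX
        Sy = s * Uty
        a = np.linalg.solve(Lc, SX)
        b = np.linalg.solve(Lc, Sy)
        XtViX = self.XtX - a.T @ a
        XtViy = self.Xty - a.T @ b
        ytViy = self.yty - float(b @ b)
        try:
            LX = np.linalg.cholesky(XtViX)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetX = 2.0 * np.sum(np.log(np.diag(LX)))
        beta = np.linalg.solve(LX.T, np.linalg.solve(LX, XtViy))
        yPy = ytViy - float(XtViy @ beta)
        return -0.5 * (logdet + logdetX + yPy) + self.const

    def test_position(self, Z: np.ndarray, block: np.ndarray,
                      mixture: str = "0_1", quick: bool = False):
        """Maximize over the per-block variances; return (T, p, sigmas)."""
        U = self.whiten(Z)
        UtU = U.T @ U
        UtX = U.T @ self.Xw
        Uty = U.T @ self.yw
        n_comp = int(block.max()) + 1

        def ll_of(sig):
            return self._loglik(UtU, UtX, Uty, np.asarray(sig)[block])

        ll0 = self._loglik(UtU, UtX, Uty, np.zeros(n_comp)[block])
        # coarse log-grid per component, then joint polish; a variance of
        # s_ref would carry roughly the whole whitened variance
        s_ref = self.N / max(np.mean(np.diag(UtU)), 1e-12)
        n_grid = 14 if quick else 24
        grid = np.concatenate(([0.0], np.geomspace(1e-6, 4.0, n_grid) * s_ref))
        sig = np.zeros(n_comp)
        for c in range(n_comp):
            best_ll, best_s = -np.inf, 0.0
            for s_try in grid:
                trial = sig.copy()
                trial[c] = s_try
                llv = ll_of(trial)
                if llv > best_ll:
                    best_ll, best_s = llv, s_try
            sig[c] = best_s
        if n_comp == 1:
            ub = max(sig[0] * 8.0, grid[-1])
            res = optimize.minimize_scalar(lambda s: -ll_of([s]),
                                           bounds=(0.0, ub), method="bounded",
                                           options={"xatol": 1e-8 if quick else 1e-10})
            if -res.fun >= ll_of(sig):
                sig = np.array([max(res.x, 0.0)])
        else:
            res = optimize.minimize(lambda s: -ll_of(s), sig, method="L-BFGS-B",
                                    bounds=[(0.0, None)] * n_comp)
            if -res.fun >= ll_of(sig):
                sig = np.maximum(res.x, 0.0)
        ll1 = ll_of(sig)
        T, pval = lrt_mixture_pvalue(ll1, ll0, df=n_comp, mixture=mixture)
        return T, pval, sig, ll1, ll0


class _JointLocusObjective:
    """Profiled joint REML objective for one locus over background params.

    Restricted to blocked-compatible null models (Kronecker polygenic with
    diagonal MPP factor + diagonal residual).  For background parameters
    theta and inner-profiled QTL variances sigma(theta), computes the REML
    log-likelihood and its analytic gradient with respect to theta via the
    envelope theorem (the partial derivative at the inner optimum), using
    block + low-rank identities throughout.
    """

    def __init__(self, kernel, X, y, Z, block):
        from .kernels import BlockedKernel
        if not isinstance(kernel, BlockedKernel):
            raise TypeError("joint locus objective needs a blocked kernel")
        self.k = kernel
        self.X, self.y, self.Z = X, y, Z
        self.block = np.asarray(block)
        self.n_comp = int(self.block.max()) + 1
        self.N, self.p = X.shape
        self.m = Z.shape[1]

    def value_and_grad(self, theta):
        k = self.k
        poly, resid = k.poly, k.resid
        A, w, r, th_p = k._blocks(theta)
        n_met = poly.met.n_params
        dA = poly.met.dcov(th_p[:n_met])
        n_w = poly.n_params - n_met
        q = k.model.n_params
        # per-group factorizations and whitened gathers
        plans = []
        logdetV0 = 0.0
        for grp in k.groups:
            e = grp["envs"]
            S = w[grp["fam"]] * A[np.ix_(e, e)] + np.diag(r[e])
            Lb = np.linalg.cholesky(S)
            logdetV0 += grp["idx"].shape[0] * 2.0 * np.sum(np.log(np.diag(Lb)))
            Linv = solve_triangular(Lb, np.eye(len(e)), lower=True)
            plans.append((grp, S, Linv))

        def whiten(M):
            vec = M.ndim == 1
            Mm = M[:, None] if vec else M
            out = np.empty_like(Mm, dtype=float)
            for grp, S, Linv in plans:
                out[grp["idx"]] = np.einsum("jk,gkm->gjm", Linv, Mm[grp["idx"]])
            return out[:, 0] if vec else out

        sc = _ProfiledScanner(whiten, logdetV0, self.X, self.y)
        _, _, sig, ll1, _ = sc.test_position(self.Z, self.block, quick=True)
        # gradient at (theta, sig): whitened M = I + U G U'
        U = whiten(self.Z)
        s = np.sqrt(sig[self.block])
        Ut = U * s[None, :]
        C = np.eye(self.m) + Ut.T @ Ut
        Lc = np.linalg.cholesky(C)
        # M^-1 a = a - Ut C^-1 Ut' a
        def Minv(Aw):
            return Aw - Ut @ cho_solve((Lc, True), Ut.T @ Aw)

        Xw, yw = sc.Xw, sc.yw
        MiX = Minv(Xw)
        Miy = Minv(yw)
        XtViX = Xw.T @ MiX
        beta = np.linalg.solve(XtViX, Xw.T @ Miy)
        Binv = np.linalg.inv(XtViX)
        Pyw = Minv(yw - Xw @ beta)
        # back-transform by L0^-T per group
        Py = np.empty(self.N)
        Vx = np.empty((self.N, self.p))
        W2 = Ut @ solve_triangular(Lc, np.eye(self.m), lower=True).T  # whitened
        W2b = np.empty((self.N, self.m))
        for grp, S, Linv in plans:
            idx = grp["idx"]
            Py[idx] = np.einsum("kj,gkm->gjm", Linv, Pyw[idx][:, :, None])[:, :, 0]
            Vx[idx] = np.einsum("kj,gkm->gjm", Linv, MiX[idx])
            W2b[idx] = np.einsum("kj,gkm->gjm", Linv, W2[idx])
        grad = np.empty(q)
        for i_par in range(q):
            t1 = 0.0
            t2 = 0.0
            for grp, S, Linv in plans:
                e = grp["envs"]
                fam = grp["fam"]
                idx = grp["idx"]
                n_g = idx.shape[0]
                if i_par < n_met:
                    dS = w[fam] * dA[i_par][np.ix_(e, e)]
                elif i_par < n_met + n_w:
                    fam_i = i_par - n_met + 1
                    if fam != fam_i:
                        continue
                    dS = A[np.ix_(e, e)]
                else:
                    jv = i_par - n_met - n_w
                    diag = (resid.groups_of(e) == jv).astype(float)
                    if not diag.any():
                        continue
                    dS = np.diag(diag)
                Sinv = Linv.T @ Linv
                # tr(V^-1 dV0) = tr(V0^-1 dV0) - tr(W2' dV0 W2)
                t1 += n_g * float(np.sum(Sinv * dS))
                t1 -= float(np.einsum("gjm,jk,gkm->", W2b[idx], dS, W2b[idx]))
                # X-projection part of tr(P dV0)
                t1 -= float(np.einsum("pq,gjq,jk,gkp->", Binv, Vx[idx], dS,
                                      Vx[idx]))
                t2 += float(np.einsum("gj,jk,gk->", Py[idx], dS, Py[idx]))
            grad[i_par] = -0.5 * (t1 - t2)
        return ll1, grad, sig


def joint_position_test(null_fit: FitResult, y: np.ndarray, design,
                        mixture: str = "0_1", maxfev: int = 4000):
    """Exact joint REML LRT for one position's QTL variance component(s).

    Unlike the fixed-background profile, the background parameters are
    re-maximized together with the QTL variance: the inner profile over
    the QTL variance(s) is nested inside an outer quasi-Newton search over
    the background parameters, with the outer gradient computed
    analytically at the inner optimum (envelope theorem) through block +
    low-rank identities.  This is the statistic whose null distribution
    the 0/1-df chi-square mixture approximates; the fixed-background
    shortcut underestimates it slightly because the null-fitted background
    absorbs locus-aligned variance.  Falls back to a derivative-free outer
    search when the null model is not blocked-compatible.

    Returns (T, p, sigma_hat, ll_full, ll_null).
    """
    from .kernels import BlockedKernel

    model = null_fit.model
    kernel, _ = _make_kernel(model, y)
    lb = np.array([b[0] for b in model.bounds])
    Z, block = design.matrix, design.block
    best = {"ll": -np.inf, "sig": None}
    bnds = [(lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None)
            for lo, hi in model.bounds]

    if isinstance(kernel, BlockedKernel):
        obj = _JointLocusObjective(kernel, model.X, y, Z, block)

        def negfg(th):
            th = np.maximum(np.asarray(th, dtype=float), lb)
            try:
                ll, grad, sig = obj.value_and_grad(th)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros_like(th)
            if ll > best["ll"]:
                best["ll"], best["sig"] = ll, sig
            return -ll, -grad

        negfg(null_fit.theta)
        optimize.minimize(negfg, null_fit.theta, jac=True, method="L-BFGS-B",
                          bounds=bnds,
                          options={"maxiter": 120, "ftol": 1e-11, "gtol": 1e-5})
    else:
        def neg_profiled(th):
            th = np.maximum(np.asarray(th, dtype=float), lb)
            try:
                whiten, logdet = kernel.whitener(th)
                sc = _ProfiledScanner(whiten, logdet, model.X, y)
                _, _, sig, ll1, _ = sc.test_position(Z, block, mixture=mixture)
            except np.linalg.LinAlgError:
                return 1e12
            if ll1 > best["ll"]:
                best["ll"], best["sig"] = ll1, sig
            return -ll1

        neg_profiled(null_fit.theta)
        optimize.minimize(neg_profiled, null_fit.theta, method="L-BFGS-B",
                          bounds=bnds,
                          options={"maxfun": maxfev, "ftol": 1e-12, "gtol": 1e-7})

    ll_full = best["ll"]
    if best["sig"] is not None and np.all(best["sig"] == 0.0):
        ll_full = null_fit.loglik  # boundary optimum: the models coincide
    T, p = lrt_mixture_pvalue(ll_full, null_fit.loglik,
                              df=int(block.max()) + 1, mixture=mixture)
    return T, p, best["sig"], ll_full, null_fit.loglik


def _round_null_fit(data: ScanData, config: ScanConfig, effect_type: str,
                    cofactors: list[int], theta0=None) -> FitResult:
    qtl_terms = [build_qtl_term(build_design(data.ibd, data.obs, grid_index=ci,
                                             effect_type=effect_type),
                                name=f"cof{ci}")
                 for ci in cofactors]
    model = background_model(data.obs, data.ibd, polygenic=config.polygenic,
                             residual=config.residual, qtl_terms=qtl_terms,
                             kinship=data.kinship)
    return reml_fit(model, data.obs.y, theta0=theta0)


def genome_scan(data: ScanData, effect_type: str, cofactors: list[int],
                config: ScanConfig, null_fit: FitResult | None = None) -> ScanProfile:
    """One full-genome scan of the given effect type with fixed cofactors."""
    if effect_type not in EFFECT_TYPES:
        raise ValueError(f"unknown effect type {effect_type!r}")
    grid_tab = data.grid.table
    n_pos = len(grid_tab)
    masked = _mask_windows(grid_tab, cofactors, config.window_cM / 2.0)
    threshold = bonferroni_threshold(n_pos, config.alpha)
    if null_fit is None:
        null_fit = _round_null_fit(data, config, effect_type, cofactors)
    stat = np.full(n_pos, np.nan)
    pval = np.full(n_pos, np.nan)
    conv = np.zeros(n_pos, dtype=bool)
    if config.full_reml:
        for i in range(n_pos):
            if masked[i]:
                continue
            dz = build_design(data.ibd, data.obs, grid_index=i, effect_type=effect_type)
            terms = [build_qtl_term(dz, name="qtl_test")] + [
                build_qtl_term(build_design(data.ibd, data.obs, grid_index=ci,
                                            effect_type=effect_type), name=f"cof{ci}")
                for ci in cofactors]
            model = background_model(data.obs, data.ibd, polygenic=config.polygenic,
                                     residual=config.residual, qtl_terms=terms,
                                     kinship=data.kinship)
            fit = reml_fit(model, data.obs.y)
            if not fit.converged:
                continue
            T, p = lrt_mixture_pvalue(fit.loglik, null_fit.loglik,
                                      df=dz.n_blocks, mixture=config.mixture)
            stat[i], pval[i], conv[i] = T, p, True
    else:
        scanner = _ProfiledScanner.from_fit(null_fit, data.obs.y)
        for i in range(n_pos):
            if masked[i]:
                continue
            dz = build_design(data.ibd, data.obs, grid_index=i, effect_type=effect_type)
            T, p, _, _, _ = scanner.test_position(dz.matrix, dz.block,
                                                  mixture=config.mixture)
            stat[i], pval[i], conv[i] = T, p, True
    neglog = np.where(conv & ~masked, -np.log10(np.clip(pval, 1e-300, 1.0)), np.nan)
    table = pd.DataFrame({
        "chrom": grid_tab["chrom"].to_numpy(),
        "pos_cM": grid_tab["pos_cM"].to_numpy(),
        "stat": stat, "p": pval, "neglog10p": neglog,
        "masked": masked, "converged": conv,
    })
    return ScanProfile(effect_type, table, list(cofactors), threshold)


def forward_select(data: ScanData, effect_type: str, config: ScanConfig
                   ) -> tuple[list[int], ScanProfile, list[float]]:
    """Forward cofactor selection for one effect type.

    Returns (cofactor grid indices, final profile, peak -log10 p at each
    cofactor's selection round).
    """
    cofactors: list[int] = []
    peak_stats: list[float] = []
    profile = None
    prev_fit = None
    for rnd in range(1, config.max_rounds + 1):
        theta0 = None
        if prev_fit is not None:
            # warm start: previous cofactor variances + a modest starting
            # value for the newly added term + previous background
            n_bg = prev_fit.model.terms[-2].n_params + prev_fit.model.terms[-1].n_params
            prev_qtl = prev_fit.theta[:-n_bg] if n_bg < len(prev_fit.theta) else np.empty(0)
            new_dz = build_design(data.ibd, data.obs, grid_index=cofactors[-1],
                                  effect_type=effect_type)
            new_init = np.full(new_dz.n_blocks, 0.1 * np.var(data.obs.y))
            theta0 = np.concatenate([prev_qtl, new_init, prev_fit.theta[-n_bg:]])
        null_fit = _round_null_fit(data, config, effect_type, cofactors,
                                   theta0=theta0)
        prev_fit = null_fit
        profile = genome_scan(data, effect_type, cofactors, config,
                              null_fit=null_fit)
        idx, peak = profile.peak()
        if idx is None or not np.isfinite(peak) or peak <= profile.threshold:
            logger.info("scan[%s] round %d: no position above threshold %.3f",
                        effect_type, rnd, profile.threshold)
            break
        cofactors.append(idx)
        peak_stats.append(peak)
        logger.info("scan[%s] round %d: cofactor at %s:%g cM (-log10p=%.2f)",
                    effect_type, rnd,
                    data.grid.table.iloc[idx]["chrom"],
                    data.grid.table.iloc[idx]["pos_cM"], peak)
    return cofactors, profile, peak_stats


def _candidate_types(data: ScanData) -> list[str]:
    C = data.obs.n_fam
    P = len(data.ibd.parents)
    if C == 1 and P > 2:   # MAGIC: environment dimension only
        return ["ecfc", "esfc"]
    return list(EFFECT_TYPES)


def _joint_fit(data: ScanData, config: ScanConfig,
               loci: list[tuple[int, str]],
               bg_theta: np.ndarray | None = None) -> FitResult:
    terms = [build_qtl_term(build_design(data.ibd, data.obs, grid_index=gi,
                                         effect_type=et),
                            name=f"locus{k}")
             for k, (gi, et) in enumerate(loci)]
    model = background_model(data.obs, data.ibd, polygenic=config.polygenic,
                             residual=config.residual, qtl_terms=terms,
                             kinship=data.kinship)
    theta0 = None
    if bg_theta is not None:
        n_qtl = sum(t.n_params for t in terms)
        theta0 = np.concatenate([
            np.full(n_qtl, 0.1 * np.var(data.obs.y)), bg_theta])
    return reml_fit(model, data.obs.y, theta0=theta0)


def _bg_theta(fit: FitResult) -> np.ndarray:
    n_bg = fit.model.terms[-2].n_params + fit.model.terms[-1].n_params
    return fit.theta[-n_bg:]


def assemble_final_model(per_type: dict[str, tuple[list[int], ScanProfile, list[float]]],
                         data: ScanData, config: ScanConfig
                         ) -> tuple[list[QTLRecord], FitResult | None]:
    """Merge per-type cofactors into loci and resolve each type by AIC."""
    grid_tab = data.grid.table
    found = []  # (grid index, type, peak stat)
    for et, (cofs, _prof, peaks) in per_type.items():
        for gi, pk in zip(cofs, peaks):
            found.append((gi, et, pk))
    if not found:
        return [], None
    found.sort(key=lambda t: -t[2])
    clusters: list[dict] = []
    for gi, et, pk in found:
        chrom = grid_tab.iloc[gi]["chrom"]
        pos = grid_tab.iloc[gi]["pos_cM"]
        home = None
        for cl in clusters:
            if cl["chrom"] == chrom and abs(cl["pos"] - pos) <= config.coincidence_cM:
                home = cl
                break
        if home is None:
            clusters.append({"chrom": chrom, "pos": pos, "grid_index": gi,
                             "best_stat": pk, "types": {et: pk}})
        else:
            home["types"][et] = max(home["types"].get(et, -np.inf), pk)
            if pk > home["best_stat"]:
                home["best_stat"] = pk  # position stays at the most significant hit

    candidates = _candidate_types(data)
    resolved = [max(cl["types"], key=cl["types"].get) for cl in clusters]
    # shared warm start for all candidate fits: one background-only fit,
    # so no candidate is advantaged by the order of evaluation
    null_model = background_model(data.obs, data.ibd, polygenic=config.polygenic,
                                  residual=config.residual, kinship=data.kinship)
    bg = _bg_theta(reml_fit(null_model, data.obs.y))
    # one pass of locus-wise AIC resolution, most significant first
    order = sorted(range(len(clusters)), key=lambda k: -clusters[k]["best_stat"])
    fit_cache: dict[tuple, FitResult] = {}

    def cached_fit(loci):
        key = tuple(loci)
        if key not in fit_cache:
            fit_cache[key] = _joint_fit(data, config, loci, bg_theta=bg)
        return fit_cache[key]

    for k in order:
        best_type, best_aic = resolved[k], np.inf
        for cand in candidates:
            loci = [(clusters[m]["grid_index"], cand if m == k else resolved[m])
                    for m in range(len(clusters))]
            fit = cached_fit(loci)
            if not fit.converged:
                continue
            a = aic(fit)
            if a < best_aic - 1e-9:
                best_aic, best_type = a, cand
        if np.isfinite(best_aic):
            resolved[k] = best_type
        else:
            logger.warning("locus %s:%g: combined model did not converge for any "
                           "type; keeping scan type %s",
                           clusters[k]["chrom"], clusters[k]["pos"], resolved[k])
    loci = [(cl["grid_index"], et) for cl, et in zip(clusters, resolved)]
    final_fit = cached_fit(loci)
    records = []
    for k, (cl, et) in enumerate(zip(clusters, resolved)):
        eff = None
        if final_fit.converged:
            eff = blup_effects(final_fit, f"locus{k}")
        records.append(QTLRecord(
            chrom=str(cl["chrom"]), pos_cM=float(cl["pos"]),
            effect_type=et, peak_neglog10p=float(cl["best_stat"]),
            effects=eff, provenance={"found_by": dict(cl["types"])}))
    records.sort(key=lambda r: (r.chrom, r.pos_cM))
    return records, final_fit


def report(records: list[QTLRecord], profiles: dict[str, ScanProfile],
           outdir, plots: bool = False,
           final_fit: FitResult | None = None) -> dict[str, str]:
    """Write scan profiles, QTL records, an allele-effect heat table and,
    when the final joint fit is supplied, its variance components and
    labeled BLUPs."""
    import os
    os.makedirs(outdir, exist_ok=True)
    written = {}
    if final_fit is not None and final_fit.converged:
        vc_path = os.path.join(outdir, "varcomp.csv")
        final_fit.varcomp_table().to_csv(vc_path, index=False,
                                         float_format="%.12g")
        written["varcomp"] = vc_path
        eff_rows = []
        for r in records:
            if r.effects is None:
                continue
            e = r.effects.copy()
            e.insert(0, "locus", f"{r.chrom}@{r.pos_cM:g}")
            eff_rows.append(e)
        if eff_rows:
            eff_path = os.path.join(outdir, "effects.csv")
            pd.concat(eff_rows, ignore_index=True)[
                ["locus", "parent", "env", "family", "blup"]
            ].to_csv(eff_path, index=False, float_format="%.12g")
            written["effects"] = eff_path
    for et, prof in profiles.items():
        path = os.path.join(outdir, f"profile_{et}.csv")
        prof.table.to_csv(path, index=False, float_format="%.12g")
        written[f"profile_{et}"] = path
    rec_rows = []
    for r in records:
        rec_rows.append({
            "chrom": r.chrom, "pos_cM": r.pos_cM,
            "effect_type": EFFECT_TYPE_NAMES[r.effect_type],
            "peak_neglog10p": r.peak_neglog10p,
            "found_by": ";".join(f"{EFFECT_TYPE_NAMES[t]}={v:.2f}"
                                 for t, v in r.provenance.get("found_by", {}).items()),
        })
    rec_path = os.path.join(outdir, "qtl_records.csv")
    pd.DataFrame(rec_rows, columns=["chrom", "pos_cM", "effect_type",
                                    "peak_neglog10p", "found_by"]
                 ).to_csv(rec_path, index=False, float_format="%.12g")
    written["qtl_records"] = rec_path
    heat_rows = []
    for r in records:
        if r.effects is None:
            continue
        for _, row in r.effects.iterrows():
            label = row["parent"] if not row["family"] else f"{row['family']}:{row['parent']}"
            col = f"{r.chrom}@{r.pos_cM:g}" + (f"|{row['env']}" if row["env"] else "")
            heat_rows.append({"parent": label, "column": col, "blup": row["blup"]})
    heat_path = os.path.join(outdir, "effects_heat.csv")
    if heat_rows:
        heat = pd.DataFrame(heat_rows).pivot_table(index="parent", columns="column",
                                                   values="blup", aggfunc="first")
        heat.to_csv(heat_path, float_format="%.12g")
    else:
        pd.DataFrame(columns=["parent"]).to_csv(heat_path, index=False)
    written["effects_heat"] = heat_path
    if plots:
        _plot_profiles(profiles, outdir, written)
    return written


def _plot_profiles(profiles, outdir, written):
    import os
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(9, 3.2))
    for et, prof in profiles.items():
        t = prof.table
        x = np.arange(len(t))
        ax.plot(x, t["neglog10p"], label=EFFECT_TYPE_NAMES[et], lw=1)
        ax.axhline(prof.threshold, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("grid position")
    ax.set_ylabel("-log10(p)")
    ax.legend(fontsize=7)
    path = os.path.join(outdir, "profiles.svg")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    written["plot"] = path
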