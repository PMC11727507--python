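"""Repeatability animal models with an inbreeding-load effect, fitted by REML.

Two nested models for repeated records y of phenotyped females:

    reduced (RM):  y = X beta + f b + Z_u u + Z_p p + e
    full    (FM):  y = X beta + f b + Z_u u + Z_u K i + Z_p p + e

where f is the total inbreeding coefficient (b the overall inbreeding
depression per fully inbred descendant), u the additive genetic effect,
i the inbreeding load effect of ancestors, p a permanent environmental
effect and K the load design matrix.  (u, i) are jointly distributed
N(0, G kron A) with G the 2x2 (co)variance matrix and A the pedigree
relationship matrix, p ~ N(0, I sigma_p^2), e ~ N(0, I sigma_e^2).

Variance components are estimated by maximizing the restricted likelihood
with Newton steps preconditioned by the average-information matrix;
the score vector is obtained by central finite differences of -2logL,
which is evaluated through one sparse factorization of the mixed-model
equations per trial point.  Full and reduced fits share the likelihood
constant, so their difference is the likelihood-ratio statistic, referred
to the boundary mixture 1/2 chi2(0) + 1/2 chi2(1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.stats import chi2


def _factor(C):
    """Sparse LDL-style factorization tuned for SPD mixed-model equations."""
    return splu(
        C,
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.0,
        options=dict(SymmetricMode=True),
    )

from .design import LoadDesign
from .pedigree import Pedigree, mendelian_sampling_variance_from_parents

logger = logging.getLogger("pedload")

LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Relationship-matrix inverse
# ---------------------------------------------------------------------------

@dataclass
class AInverse:
    """Sparse inverse of the additive relationship matrix with its log-det."""

    matrix: sp.csr_matrix
    logdet_A: float
    mendelian_variance: np.ndarray


def build_A_inverse(ped: Pedigree, F) -> AInverse:
    """Henderson-rule sparse A-inverse accounting for inbreeding.

    Each animal contributes the outer product of (1, -1/2, -1/2) on
    (itself, sire, dam), divided by its Mendelian-sampling variance
    m_j = 1/2 - 1/4 (F_s + F_d), adapted to the number of known parents.
    log|A| is the sum of log m_j.
    """
    Farr = ped.aligned(F)
    if np.any((Farr < 0) | (Farr >= 1)):
        raise ValueError("inbreeding coefficients must lie in [0, 1)")
    n = ped.n
    rows, cols, vals = [], [], []
    m = np.empty(n)
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        m[j] = mendelian_sampling_variance_from_parents(
            Farr[s] if s >= 0 else None, Farr[d] if d >= 0 else None
        )
        entries = [(j, 1.0)]
        if s >= 0:
            entries.append((s, -0.5))
        if d >= 0:
            entries.append((d, -0.5))
        w = 1.0 / m[j]
        for a, ca in entries:
            for b, cb in entries:
                rows.append(a)
                cols.append(b)
                vals.append(ca * cb * w)
    Ainv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    Ainv.sum_duplicates()
    return AInverse(matrix=Ainv, logdet_A=float(np.log(m).sum()), mendelian_variance=m)


# ---------------------------------------------------------------------------
# Variance components and results
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """(Co)variance components on the observed scale (trait units squared).

    ``sigma_i2``/``sigma_ui`` are None under the reduced model;
    ``sigma_p2`` is None when no permanent-environment effect is fitted.
    """

    sigma_u2: float
    sigma_e2: float
    sigma_p2: float | None = None
    sigma_i2: float | None = None
    sigma_ui: float | None = None

    @property
    def G(self) -> np.ndarray:
        if self.sigma_i2 is None:
            return np.array([[self.sigma_u2]])
        return np.array(
            [
                [self.sigma_u2, self.sigma_ui or 0.0],
                [self.sigma_ui or 0.0, self.sigma_i2],
            ]
        )


@dataclass
class FitResult:
    model: str
    components: VarianceComponents
    se: dict
    b_hat: float | None
    b_se: float | None
    beta_hat: pd.Series
    u_hat: pd.Series
    i_hat: pd.Series | None
    p_hat: pd.Series | None
    minus2logl: float
    converged: bool
    iterations: int
    history: list = field(default_factory=list)
    n_records: int = 0


@dataclass
class LRTResult:
    statistic: float
    p_value: float


@dataclass
class REMLOptions:
    maxiter: int = 60
    tol_logl: float = 1e-8
    tol_param: float = 1e-6
    max_halvings: int = 12
    verbose: int = 0


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

def _build_fixed(data: pd.DataFrame, factors, f: np.ndarray | None):
    """Full-rank fixed-effect matrix: intercept, drop-last dummies, f covariate."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    for fac in factors:
        levels = pd.unique(data[fac])
        for lv in levels[:-1]:  # last level dropped for identifiability
            cols.append((data[fac] == lv).to_numpy(dtype=float))
            names.append(f"{fac}={lv}")
    b_col = None
    if f is not None:
        if np.ptp(f) == 0.0:
            logger.warning("inbreeding covariate is constant; b dropped from model")
        else:
            b_col = len(cols)
            cols.append(f)
            names.append("f")
    X = np.column_stack(cols)
    if len(data) <= X.shape[1]:
        raise ValueError("more fixed-effect columns than records")
    return X, names, b_col


class _Problem:
    """Precomputed quantities for one model structure (FM or RM)."""

    def __init__(
        self,
        ped: Pedigree,
        ainv: AInverse,
        data: pd.DataFrame,
        model: str,
        design: LoadDesign | None,
        factors,
        value_col: str,
        animal_col: str,
        f: np.ndarray | None,
        include_pe: bool,
    ):
        self.model = model
        self.include_pe = include_pe
        n_rec = len(data)
        n_a = ped.n
        self.n_a = n_a
        self.y = data[value_col].to_numpy(dtype=float)
        rec_idx = np.array([ped.index_of(a) for a in data[animal_col]])

        X, self.fixed_names, self.b_col = _build_fixed(data, factors, f)
        self.p_fixed = X.shape[1]
        Zu = sp.csr_matrix(
            (np.ones(n_rec), (np.arange(n_rec), rec_idx)), shape=(n_rec, n_a)
        )
        blocks = [sp.csr_matrix(X), Zu]
        self.slices = {"fixed": slice(0, self.p_fixed)}
        off = self.p_fixed
        self.slices["u"] = slice(off, off + n_a)
        off += n_a
        if model == "FM":
            Zi = (Zu @ design.K).tocsr()
            blocks.append(Zi)
            self.slices["i"] = slice(off, off + n_a)
            off += n_a
            self.Zi = Zi
        else:
            self.Zi = None
        if include_pe:
            pe_animals = np.unique(rec_idx)
            self.pe_ids = ped.ids[pe_animals]
            pe_map = {int(a): i for i, a in enumerate(pe_animals)}
            Zp = sp.csr_matrix(
                (
                    np.ones(n_rec),
                    (np.arange(n_rec), [pe_map[int(a)] for a in rec_idx]),
                ),
                shape=(n_rec, len(pe_animals)),
            )
            blocks.append(Zp)
            self.n_pe = len(pe_animals)
            self.slices["pe"] = slice(off, off + self.n_pe)
            off += self.n_pe
            self.Zp = Zp
        else:
            self.n_pe = 0
            self.Zp = None
        self.dim = off
        self.Zu = Zu
        self.W = sp.hstack(blocks).tocsr()
        self.WtW = (self.W.T @ self.W).tocsr()
        self.Wty = self.W.T @ self.y
        self.yty = float(self.y @ self.y)
        self.n_rec = n_rec
        self.ainv = ainv
        self._asolve = None
        self._zeros_pp = sp.csr_matrix((self.p_fixed, self.p_fixed))

    @property
    def asolve(self):
        if self._asolve is None:
            self._asolve = splu(self.ainv.matrix.tocsc())
        return self._asolve

    # -- parameter vector layout -------------------------------------------
    def param_names(self) -> list[str]:
        names = ["sigma_u2"]
        if self.model == "FM":
            names += ["sigma_i2", "sigma_ui"]
        if self.include_pe:
            names.append("sigma_p2")
        names.append("sigma_e2")
        return names

    def pack(self, vc: VarianceComponents) -> np.ndarray:
        vals = [vc.sigma_u2]
        if self.model == "FM":
            vals += [vc.sigma_i2, vc.sigma_ui]
        if self.include_pe:
            vals.append(vc.sigma_p2)
        vals.append(vc.sigma_e2)
        return np.asarray(vals, dtype=float)

    def unpack(self, theta: np.ndarray) -> VarianceComponents:
        it = iter(theta)
        su = next(it)
        si = sui = sp_ = None
        if self.model == "FM":
            si = next(it)
            sui = next(it)
        if self.include_pe:
            sp_ = next(it)
        se = next(it)
        return VarianceComponents(
            sigma_u2=su, sigma_e2=se, sigma_p2=sp_, sigma_i2=si, sigma_ui=sui
        )

    # -- mixed-model equations ---------------------------------------------
    def coefficient_matrix(self, vc: VarianceComponents):
        """(C, rhs) of the MME at the given components.

        At ``sigma_i2 = 0`` the load effect is absent and the FM structure
        degenerates exactly to the reduced model; callers handle that case
        via a reduced problem.
        """
        inv_e = 1.0 / vc.sigma_e2
        Ainv = self.ainv.matrix
        if self.model == "FM":
            G = vc.G
            Ginv = np.linalg.inv(G)
            Sinv = sp.bmat(
                [
                    [Ginv[0, 0] * Ainv, Ginv[0, 1] * Ainv],
                    [Ginv[1, 0] * Ainv, Ginv[1, 1] * Ainv],
                ]
            )
        else:
            Sinv = Ainv * (1.0 / vc.sigma_u2)
        diag_blocks = [self._zeros_pp, Sinv]
        if self.include_pe:
            diag_blocks.append(sp.identity(self.n_pe) * (1.0 / vc.sigma_p2))
        C = (self.WtW * inv_e + sp.block_diag(diag_blocks)).tocsc()
        rhs = self.Wty * inv_e
        return C, rhs

    def logdet_sigma(self, vc: VarianceComponents) -> float:
        if self.model == "FM":
            sign, logdetG = np.linalg.slogdet(vc.G)
            if sign <= 0:
                return np.inf
            out = self.n_a * logdetG + 2.0 * self.ainv.logdet_A
        else:
            if vc.sigma_u2 <= 0:
                return np.inf
            out = self.n_a * np.log(vc.sigma_u2) + self.ainv.logdet_A
        if self.include_pe:
            if vc.sigma_p2 <= 0:
                return np.inf
            out += self.n_pe * np.log(vc.sigma_p2)
        return out

    def minus2logl(self, vc: VarianceComponents, want_solution: bool = False):
        """REML -2 log-likelihood, with constant (n-p) log 2 pi included."""
        lds = self.logdet_sigma(vc)
        if not np.isfinite(lds) or vc.sigma_e2 <= 0:
            return (np.inf, None, None) if want_solution else np.inf
        C, rhs = self.coefficient_matrix(vc)
        try:
            lu = _factor(C)
        except RuntimeError:
            return (np.inf, None, None) if want_solution else np.inf
        sol = lu.solve(rhs)
        logdetC = float(np.log(np.abs(lu.U.diagonal())).sum())
        ypy = (self.yty - float(sol @ self.Wty)) / vc.sigma_e2
        val = (
            (self.n_rec - self.p_fixed) * LOG2PI
            + self.n_rec * np.log(vc.sigma_e2)
            + lds
            + logdetC
            + ypy
        )
        if want_solution:
            return val, sol, lu
        return val

    # -- average information ------------------------------------------------
    def _A_times(self, v: np.ndarray) -> np.ndarray:
        return self.asolve.solve(v)

    def _P_times(self, v: np.ndarray, lu, sigma_e2: float) -> np.ndarray:
        sol = lu.solve(self.W.T @ v / sigma_e2)
        return (v - self.W @ sol) / sigma_e2

    def _ai_from(self, Py: np.ndarray, solver, sigma_e2: float) -> np.ndarray:
        """AI matrix 0.5 f_j' P f_k with f_j = dV/dtheta_j P y."""
        fs = []
        AZuPy = self._A_times(self.Zu.T @ Py)
        fs.append(self.Zu @ AZuPy)  # sigma_u2
        if self.model == "FM":
            AZiPy = self._A_times(self.Zi.T @ Py)
            fs.append(self.Zi @ AZiPy)  # sigma_i2
            fs.append(self.Zu @ AZiPy + self.Zi @ AZuPy)  # sigma_ui
        if self.include_pe:
            fs.append(self.Zp @ (self.Zp.T @ Py))
        fs.append(Py)  # sigma_e2
        Pf = [solver(f, sigma_e2) for f in fs]
        k = len(fs)
        ai = np.empty((k, k))
        for a in range(k):
            for b in range(a, k):
                ai[a, b] = ai[b, a] = 0.5 * float(fs[a] @ Pf[b])
        return ai

    def average_information(self, vc: VarianceComponents, sol, lu) -> np.ndarray:
        Py = (self.y - self.W @ sol) / vc.sigma_e2
        return self._ai_from(
            Py, lambda f, se2: self._P_times(f, lu, se2), vc.sigma_e2
        )

    def boundary_information(
        self, red: "_Problem", vc_red: VarianceComponents, sol_r, lu_r
    ) -> np.ndarray:
        """Full-parameter AI at the sigma_i2 = 0 boundary.

        V and hence the projection P are those of the reduced model, but
        the derivative directions dV/dsigma_i2 and dV/dsigma_ui still
        exist, so the information on the load components is finite.
        """
        Py = (red.y - red.W @ sol_r) / vc_red.sigma_e2
        return self._ai_from(
            Py, lambda f, se2: red._P_times(f, lu_r, se2), vc_red.sigma_e2
        )


# ---------------------------------------------------------------------------
# REML driver
# ---------------------------------------------------------------------------

def _project(theta: np.ndarray, names: list[str], scale: float) -> np.ndarray:
    """Pull a trial point back into the admissible parameter space."""
    theta = theta.copy()
    idx = {n: i for i, n in enumerate(names)}
    floor = 1e-8 * scale
    theta[idx["sigma_e2"]] = max(theta[idx["sigma_e2"]], floor)
    theta[idx["sigma_u2"]] = max(theta[idx["sigma_u2"]], floor)
    if "sigma_p2" in idx:
        theta[idx["sigma_p2"]] = max(theta[idx["sigma_p2"]], floor)
    if "sigma_i2" in idx:
        si = max(theta[idx["sigma_i2"]], 0.0)
        sui = theta[idx["sigma_ui"]]
        su = theta[idx["sigma_u2"]]
        if si == 0.0:
            sui = 0.0
        else:
            G = np.array([[su, sui], [sui, si]])
            evals, evecs = np.linalg.eigh(G)
            lo = 1e-8 * max(G.trace(), floor)
            if evals[0] < lo:
                logger.debug("G bent back to the PSD cone at a trial point")
                evals = np.maximum(evals, lo)
                G = evecs @ np.diag(evals) @ evecs.T
                su, sui, si = G[0, 0], G[0, 1], G[1, 1]
        theta[idx["sigma_u2"]] = su
        theta[idx["sigma_i2"]] = si
        theta[idx["sigma_ui"]] = sui
    return theta


def _fd_gradient(fun, theta, names, scale, f0):
    """Forward-difference gradient of -2logL around the current point."""
    g = np.zeros_like(theta)
    for j in range(len(theta)):
        h = 1e-5 * (abs(theta[j]) + 1e-4 * scale)
        tp = theta.copy()
        tp[j] += h
        fp = fun(tp)
        if not np.isfinite(fp):
            tp[j] = theta[j] - h
            fp = fun(tp)
            h = -h
        g[j] = (fp - f0) / h
    return g


def reml_fit(
    ped: Pedigree,
    F,
    design: LoadDesign | None,
    data: pd.DataFrame,
    model: str = "FM",
    *,
    factors=(),
    value_col: str = "y",
    animal_col: str = "animal",
    f_col: str | None = "from_pedigree",
    include_pe: bool = True,
    start: VarianceComponents | None = None,
    rm_components: VarianceComponents | None = None,
    opts: REMLOptions | None = None,
) -> FitResult:
    """Fit the full or reduced repeatability animal model by REML.

    Parameters
    ----------
    ped, F : pedigree and its inbreeding coefficients.
    design : LoadDesign, required for the full model (ignored under RM).
    data : phenotype table (one row per record).
    model : "FM" (with inbreeding load) or "RM".
    factors : fixed-effect factor column names.
    f_col : column holding the inbreeding covariate, or "from_pedigree" to
        use the pedigree F of the recorded animal, or None to omit b.
    include_pe : fit a permanent environmental effect (repeated records).
    start : starting components; a variance-scaled default otherwise.
    rm_components : components of an already-fitted reduced model, used to
        seed the boundary (sigma_i2 = 0) comparison of a full-model fit so
        that nesting holds against that fit numerically.
    """
    opts = opts or REMLOptions()
    model = model.upper()
    if model not in ("FM", "RM"):
        raise ValueError("model must be 'FM' or 'RM'")
    if model == "FM" and (design is None or design.K.nnz == 0):
        warnings.warn("empty K matrix: full model degenerates to the reduced model")
        model = "RM"

    ainv = build_A_inverse(ped, F)
    Farr = ped.aligned(F)
    if f_col == "from_pedigree":
        f = np.array([Farr[ped.index_of(a)] for a in data[animal_col]])
    elif f_col is None:
        f = None
    else:
        f = data[f_col].to_numpy(dtype=float)
    if f is not None and np.ptp(f) == 0.0:
        f = None  # constant covariate: b not estimable

    kw = dict(
        data=data,
        design=design,
        factors=factors,
        value_col=value_col,
        animal_col=animal_col,
        f=f,
        include_pe=include_pe,
    )
    prob = _Problem(ped, ainv, model=model, **kw)
    red = _Problem(ped, ainv, model="RM", **kw) if model == "FM" else prob

    vary = float(np.var(prob.y)) if len(prob.y) > 1 else 1.0
    scale = max(vary, 1e-12)
    if start is None:
        start = VarianceComponents(
            sigma_u2=0.25 * vary,
            sigma_e2=0.5 * vary,
            sigma_p2=0.25 * vary if include_pe else None,
            sigma_i2=vary if model == "FM" else None,
            sigma_ui=0.0 if model == "FM" else None,
        )
    def newton(use_prob, theta0):
        """AI-preconditioned Newton descent on -2logL for one structure."""
        names_u = use_prob.param_names()

        def evaluate(th, want_solution=False):
            vc = use_prob.unpack(th)
            if use_prob.model == "FM" and vc.sigma_i2 <= 0.0:
                vc_red = replace(vc, sigma_i2=None, sigma_ui=None)
                return red.minus2logl(vc_red, want_solution=want_solution)
            return use_prob.minus2logl(vc, want_solution=want_solution)

        theta = _project(theta0, names_u, scale)
        f0, sol, lu = evaluate(theta, want_solution=True)
        history = [(0, theta.copy(), f0)]
        converged = False
        it = 0
        small_dl_streak = 0
        slow_dl_streak = 0
        for it in range(1, opts.maxiter + 1):
            vc = use_prob.unpack(theta)
            if use_prob.model == "FM" and vc.sigma_i2 <= 0.0:
                vc_red = replace(vc, sigma_i2=None, sigma_ui=None)
                _, sol_r, lu_r = red.minus2logl(vc_red, want_solution=True)
                ai = use_prob.boundary_information(red, vc_red, sol_r, lu_r)
            else:
                ai = use_prob.average_information(vc, sol, lu)
            grad = _fd_gradient(evaluate, theta, names_u, scale, f0)
            score = -0.5 * grad
            # active set: a variance pinned at its floor whose score points
            # further out is held fixed, so it cannot poison the Newton step
            floor = 1e-8 * scale
            free = np.ones(len(names_u), dtype=bool)
            for j, nm in enumerate(names_u):
                at_floor = (
                    theta[j] <= 1.01 * floor
                    if nm != "sigma_i2"
                    else theta[j] <= 0.0
                )
                if nm != "sigma_ui" and at_floor and score[j] < 0:
                    free[j] = False
            if not free.any():
                free[:] = True
            ridge = 1e-8 * np.trace(ai) / len(names_u)
            delta = np.zeros(len(names_u))
            try:
                sub = ai[np.ix_(free, free)] + ridge * np.eye(int(free.sum()))
                delta[free] = np.linalg.solve(sub, score[free])
            except np.linalg.LinAlgError:
                delta = score * scale / max(np.abs(score).max(), 1e-30)

            step = 1.0
            accepted = False
            for _ in range(opts.max_halvings):
                cand = _project(theta + step * delta, names_u, scale)
                fc = evaluate(cand)
                if np.isfinite(fc) and fc <= f0 + 1e-12 * (1 + abs(f0)):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                # fall back to a small scaled-gradient step
                gnorm = np.abs(grad).max()
                if gnorm > 0:
                    cand = _project(
                        theta - (1e-3 * scale / gnorm) * grad, names_u, scale
                    )
                    fc = evaluate(cand)
                    accepted = np.isfinite(fc) and fc < f0
            if not accepted:
                converged = True  # no descent direction left at FD resolution
                break

            dtheta = np.abs(cand - theta) / np.maximum(np.abs(theta), 1e-8 * scale)
            dl = f0 - fc
            theta = cand
            f0, sol, lu = evaluate(theta, want_solution=True)
            history.append((it, theta.copy(), f0))
            logger.log(
                logging.INFO if opts.verbose else logging.DEBUG,
                "REML iter %d: -2logL=%.6f theta=%s", it, f0, theta,
            )
            if dl < opts.tol_logl * (1 + abs(f0)):
                small_dl_streak += 1
            else:
                small_dl_streak = 0
            slow_dl_streak = slow_dl_streak + 1 if dl < 100 * opts.tol_logl * (
                1 + abs(f0)
            ) else 0
            # stop when the likelihood is stationary; a flat ridge or a
            # degenerate edge of the PSD cone (parameters drifting at
            # negligible likelihood gain) counts as converged after a few
            # consecutive near-stationary steps
            if small_dl_streak and (
                dtheta.max() < opts.tol_param or small_dl_streak >= 2
            ):
                converged = True
                break
            if slow_dl_streak >= 3:
                converged = True
                logger.debug("stopped on a flat likelihood region (iter %d)", it)
                break
        return theta, f0, converged, it, history

    names = prob.param_names()
    theta, f0, converged, it, history = newton(prob, prob.pack(start))

    if model == "FM":
        # the reduced model sits on the boundary sigma_i2 = 0 of the full
        # parameter space; if the boundary optimum beats the interior search,
        # the constrained REML estimate is the boundary itself
        if rm_components is not None:
            red_start = red.pack(rm_components)
        else:
            red_start = np.array(
                [th for nm, th in zip(names, theta) if nm in red.param_names()]
            )
        theta_b, f_b, conv_b, it_b, _ = newton(red, red_start)
        if f_b < f0 - 1e-12 * (1 + abs(f0)):
            logger.debug(
                "boundary (reduced) optimum better by %.3g; taking sigma_i2=0",
                f0 - f_b,
            )
            theta = prob.pack(
                replace(
                    red.unpack(theta_b),
                    sigma_i2=0.0,
                    sigma_ui=0.0,
                )
            )
            f0, converged = f_b, conv_b
            it += it_b

    if not converged:
        logger.warning("REML did not converge in %d iterations", opts.maxiter)

    # final quantities at the optimum
    vc = prob.unpack(theta)
    boundary = prob.model == "FM" and vc.sigma_i2 <= 0.0
    use = red if boundary else prob
    vc_eval = replace(vc, sigma_i2=None, sigma_ui=None) if boundary else vc
    f0, sol, lu = use.minus2logl(vc_eval, want_solution=True)
    if boundary:
        ai_final = prob.boundary_information(red, vc_eval, sol, lu)
        se_names = prob.param_names()
    else:
        ai_final = use.average_information(vc_eval, sol, lu)
        se_names = use.param_names()
    try:
        cov = np.linalg.inv(ai_final)
        se_vals = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_vals = np.full(len(se_names), np.nan)
    se = dict(zip(se_names, se_vals))

    beta = sol[use.slices["fixed"]]
    b_hat = b_se = None
    if use.b_col is not None:
        b_hat = float(beta[use.b_col])
        eb = np.zeros(use.dim)
        eb[use.b_col] = 1.0
        b_se = float(np.sqrt(max(lu.solve(eb)[use.b_col], 0.0)))
    u_hat = ped.series(sol[use.slices["u"]], name="u_hat")
    if use.model == "FM":
        i_hat = ped.series(sol[use.slices["i"]], name="i_hat")
    elif model == "FM" and boundary:
        i_hat = ped.series(np.zeros(ped.n), name="i_hat")
    else:
        i_hat = None
    p_hat = (
        pd.Series(sol[use.slices["pe"]], index=use.pe_ids, name="p_hat")
        if include_pe
        else None
    )
    if boundary:
        vc = replace(vc, sigma_i2=0.0, sigma_ui=0.0)
    return FitResult(
        model=model,
        components=vc,
        se=se,
        b_hat=b_hat,
        b_se=b_se,
        beta_hat=pd.Series(beta, index=use.fixed_names),
        u_hat=u_hat,
        i_hat=i_hat,
        p_hat=p_hat,
        minus2logl=float(f0),
        converged=converged,
        iterations=it,
        history=history,
        n_records=use.n_rec,
    )


def restricted_minus2logl(
    ped: Pedigree,
    F,
    design: LoadDesign | None,
    data: pd.DataFrame,
    vc: VarianceComponents,
    model: str = "FM",
    **kwargs,
) -> float:
    """REML -2 log-likelihood at fixed variance components.

    Uses the same constant convention as :func:`reml_fit`, so differences
    between models evaluated on the same data are likelihood-ratio
    statistics.  Keyword arguments are as in :func:`reml_fit`.
    """
    model = model.upper()
    if model == "FM" and (vc.sigma_i2 is None or vc.sigma_i2 <= 0.0):
        model = "RM"
        vc = replace(vc, sigma_i2=None, sigma_ui=None)
    prob = _problem_from_kwargs(ped, F, design, data, model, **kwargs)
    return float(prob.minus2logl(vc))


def _problem_from_kwargs(ped, F, design, data, model, **kwargs):
    ainv = build_A_inverse(ped, F)
    f_col = kwargs.pop("f_col", "from_pedigree")
    animal_col = kwargs.get("animal_col", "animal")
    Farr = ped.aligned(F)
    if f_col == "from_pedigree":
        f = np.array([Farr[ped.index_of(a)] for a in data[animal_col]])
        if np.ptp(f) == 0.0:
            f = None
    elif f_col is None:
        f = None
    else:
        f = data[f_col].to_numpy(dtype=float)
    return _Problem(
        ped,
        ainv,
        data=data,
        model=model,
        design=design,
        factors=kwargs.get("factors", ()),
        value_col=kwargs.get("value_col", "y"),
        animal_col=animal_col,
        f=f,
        include_pe=kwargs.get("include_pe", True),
    )


def assemble_mme(
    ped: Pedigree,
    F,
    design: LoadDesign | None,
    data: pd.DataFrame,
    vc: VarianceComponents,
    model: str = "FM",
    **kwargs,
):
    """Mixed-model equations at fixed variance components.

    Returns ``(C, rhs, index_map)`` where ``index_map`` maps effect names
    ("fixed", "u", "i", "pe") to slices of the solution vector.
    """
    model = model.upper()
    if model == "FM" and (design is None or design.K.nnz == 0):
        warnings.warn("empty K matrix: assembling reduced-model equations")
        model = "RM"
        vc = replace(vc, sigma_i2=None, sigma_ui=None)
    prob = _problem_from_kwargs(ped, F, design, data, model, **kwargs)
    C, rhs = prob.coefficient_matrix(vc)
    return C, rhs, dict(prob.slices)


# ---------------------------------------------------------------------------
# Model comparison and summaries
# ---------------------------------------------------------------------------

def lrt_from_minus2logl(m2_rm: float, m2_fm: float) -> LRTResult:
    """Likelihood-ratio test of FM vs RM under the boundary mixture null.

    statistic = (-2logL_RM) - (-2logL_FM);
    p = 1/2 Pr(chi2_1 >= statistic) for a positive statistic, 1 at zero.
    """
    stat = m2_rm - m2_fm
    if stat < -1e-6:
        raise ValueError(
            f"reduced model fits better than full by {-stat}: nesting violated"
        )
    if stat < 0:
        warnings.warn("tiny negative LRT statistic clipped to 0")
        stat = 0.0
    p = 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    return LRTResult(statistic=float(stat), p_value=p)


def likelihood_ratio_test(fit_fm: FitResult, fit_rm: FitResult) -> LRTResult:
    if fit_fm.n_records != fit_rm.n_records:
        raise ValueError("fits are not on identical data")
    return lrt_from_minus2logl(fit_rm.minus2logl, fit_fm.minus2logl)


def rescaled_load_variance(sigma_i2: float, F_ref: float = 0.10) -> float:
    """Load variance rescaled from the per-100%-inbred scale to F = F_ref."""
    return sigma_i2 * F_ref**2


def genetic_correlation(sigma_ui: float, sigma_u2: float, sigma_i2: float) -> float:
    denom = np.sqrt(sigma_u2 * sigma_i2)
    if denom == 0:
        return np.nan
    return sigma_ui / denom


def depression_rate_percent(
    b: float, trait_mean: float, delta_F: float = 0.01
) -> float:
    """|b| * delta_F as a percentage of the trait mean."""
    return abs(b) * delta_F / trait_mean * 100.0


def depression_trait_units(b: float, delta_F: float = 0.10) -> float:
    """Trait-unit loss for an inbreeding increase of delta_F (positive=loss)."""
    return abs(b) * delta_F


def total_inbreeding_effect(i_hat, b: float):
    """Total effect on a fully inbred descendant: predicted load plus b."""
    return i_hat + b


def summarize_fit(
    fit: FitResult,
    trait_mean: float,
    F_ref: float = 0.10,
    delta_F: float = 0.01,
) -> dict:
    """Derived quantities of a converged full-model fit.

    Rescaled load variance at a reference inbreeding level, the genetic
    correlation r(u,i), the depression rate as % of the mean per delta_F of
    inbreeding, and the distribution of predicted loads with and without
    the overall depression b added.
    """
    vc = fit.components
    out = {
        "model": fit.model,
        "trait_mean": trait_mean,
        "F_ref": F_ref,
        "delta_F": delta_F,
    }
    if fit.b_hat is not None:
        out["b_hat"] = fit.b_hat
        out["depression_pct_per_deltaF"] = depression_rate_percent(
            fit.b_hat, trait_mean, delta_F
        )
    if vc.sigma_i2 is not None:
        if vc.sigma_i2 > 0:
            out["rescaled_sigma_i2"] = rescaled_load_variance(vc.sigma_i2, F_ref)
            out["r_ui"] = genetic_correlation(vc.sigma_ui, vc.sigma_u2, vc.sigma_i2)
        else:
            out["rescaled_sigma_i2"] = 0.0
            out["r_ui"] = None
            out["r_ui_undefined"] = True
    if fit.i_hat is not None:
        ih = fit.i_hat.to_numpy()
        out["mean_i_hat"] = float(ih.mean())
        out["sd_i_hat"] = float(ih.std(ddof=1)) if len(ih) > 1 else 0.0
        out["pct_positive_load"] = 100.0 * float((ih > 0).mean())
        if fit.b_hat is not None:
            tot = total_inbreeding_effect(ih, fit.b_hat)
            out["pct_positive_total_effect"] = 100.0 * float((tot > 0).mean())
    return out
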