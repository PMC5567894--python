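"""Gaussian linear mixed models with crossed random effects, fit by REML.

The solver follows the penalized-least-squares formulation used by modern
mixed-model software: the random-effect covariance is written as
sigma^2 * Lambda(theta) Lambda(theta)', with Lambda block-diagonal over
grouping-factor levels and a lower-triangular relative Cholesky factor
shared across the levels of each random term.  For a candidate theta the
fixed effects and the residual variance are profiled out analytically
through a blocked Cholesky factorization, leaving a low-dimensional
bounded quasi-Newton search over theta.  Crossed grouping factors (e.g.,
subject and item) are handled natively: Z simply concatenates the
indicator expansions of every random term.

Because the design is identical for every component score (only the
response changes), the expensive cross products Z'Z, Z'X, X'X are
precomputed once in :class:`LmerEngine` and reused across components and
permutations.

t-values are beta / SE with SE from the profiled information matrix; no
degrees-of-freedom correction is applied, since significance in this
pipeline comes from permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg.lapack import dpotrf, dtrtrs

from .formula import ModelFormula, _code_column

__all__ = ["LmerFit", "ComponentTValues", "LmerEngine", "fit_lmer", "fit_components"]

_BIG = 1e300


@dataclass
class LmerFit:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    fixed_names: list[str]
    sigma2: float
    vcomp: dict[str, np.ndarray]  # per random term: sigma^2 * lam lam'
    status: str  # converged | fallback_intercepts_only | fallback_ols
    reml_criterion: float


@dataclass
class ComponentTValues:
    T_s: np.ndarray  # k x n_terms (intercept excluded)
    term_names: list[str]
    statuses: list[str]


class _RandomTerm:
    """One (expressions | group) random term, expanded to indicators."""

    def __init__(self, exprs: tuple[str, ...], group: str, design: pd.DataFrame):
        if group not in design.columns:
            raise ValueError(f"grouping factor {group!r} not in design")
        labels = design[group].astype(str).to_numpy()
        self.group = group
        self.levels = np.unique(labels)
        if len(self.levels) < 2:
            raise ValueError(f"grouping factor {group!r} has fewer than 2 levels")
        self.codes = np.searchsorted(self.levels, labels)
        cols = [np.ones(len(design))]
        names = ["1"]
        for e in exprs:
            if e == "1":
                continue
            m, ns, _ = _code_column(design[e], e)
            cols.extend(m.T)
            names.extend(ns)
        self.W = np.stack(cols, axis=1)  # n x q_t
        self.expr_names = names
        self.q_t = self.W.shape[1]
        self.n_levels = len(self.levels)

    def z_block(self) -> np.ndarray:
        """n x (n_levels * q_t) indicator-times-expression design."""
        n = self.W.shape[0]
        Z = np.zeros((n, self.n_levels * self.q_t))
        cols = self.codes[:, None] * self.q_t + np.arange(self.q_t)[None, :]
        np.put_along_axis(Z, cols, self.W, axis=1)
        return Z


def _theta_slices(terms: list[_RandomTerm]) -> list[tuple[int, int]]:
    out, pos = [], 0
    for t in terms:
        n_par = t.q_t * (t.q_t + 1) // 2
        out.append((pos, pos + n_par))
        pos += n_par
    return out


def _build_lambdas(theta: np.ndarray, terms: list[_RandomTerm]) -> list[np.ndarray]:
    lams = []
    for (a, b), t in zip(_theta_slices(terms), terms):
        pars = theta[a:b]
        lam = np.zeros((t.q_t, t.q_t))
        idx = 0
        for j in range(t.q_t):  # column-major lower triangle, lme4 order
            for i in range(j, t.q_t):
                lam[i, j] = pars[idx]
                idx += 1
        lams.append(lam)
    return lams


class LmerEngine:
    """Precompiled model structure for repeated fits with different responses."""

    def __init__(self, formula: ModelFormula, design: pd.DataFrame):
        n = len(design)
        cols = [np.ones(n)]
        names = ["(Intercept)"]
        for term in formula.fixed:
            if term not in design.columns:
                raise ValueError(f"fixed term {term!r} not in design")
            m, ns, _ = _code_column(design[term], term)
            cols.extend(m.T)
            names.extend(ns)
        self.X = np.stack(cols, axis=1)
        self.fixed_names = names
        self.p = self.X.shape[1]
        self.n = n
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("singular fixed-effect design")
        self.terms = [_RandomTerm(exprs, g, design) for exprs, g in formula.random]
        self._intercept_terms = [
            _RandomTerm(("1",), g, design) for _, g in formula.random
        ]
        self.XtX = self.X.T @ self.X
        # cross products reused across responses (the design never changes)
        self._prep = {
            "full": self._cross_products(self.terms),
            "intercepts": self._cross_products(self._intercept_terms)
            if any(t.q_t > 1 for t in self.terms)
            else None,
        }

    def _cross_products(self, terms: list[_RandomTerm]):
        if not terms:
            return None
        Z = np.concatenate([t.z_block() for t in terms], axis=1)
        # index arrays for the vectorized block-diagonal Lambda fill:
        # Lam[rows, cols] = theta[tmap] writes every level's copy at once
        rows, cols, tmap = [], [], []
        pos = 0
        for (a, _), t in zip(_theta_slices(terms), terms):
            local_r, local_c, local_t = [], [], []
            idx = 0
            for j in range(t.q_t):  # column-major lower triangle
                for i in range(j, t.q_t):
                    local_r.append(i)
                    local_c.append(j)
                    local_t.append(a + idx)
                    idx += 1
            for lev in range(t.n_levels):
                off = pos + lev * t.q_t
                rows.extend(off + r for r in local_r)
                cols.extend(off + c for c in local_c)
                tmap.extend(local_t)
            pos += t.n_levels * t.q_t
        fill = (np.array(rows), np.array(cols), np.array(tmap))
        return Z, Z.T @ Z, Z.T @ self.X, fill

    # -- profiled REML ---------------------------------------------------

    def _profile(self, theta: np.ndarray, terms: list[_RandomTerm],
                 ZtZ: np.ndarray, rhs0: np.ndarray, ZtX: np.ndarray,
                 Xty: np.ndarray, yty: float, fill=None):
        """Blocked-Cholesky solve; returns (deviance, beta, RXX, pwrss)."""
        q = ZtZ.shape[0]
        Lam = np.zeros((q, q))
        if fill is None:
            lams = _build_lambdas(theta, terms)
            pos = 0
            for lam, t in zip(lams, terms):
                for _ in range(t.n_levels):
                    Lam[pos : pos + t.q_t, pos : pos + t.q_t] = lam
                    pos += t.q_t
        else:
            rows, cols, tmap = fill
            Lam[rows, cols] = theta[tmap]
        A = Lam.T @ ZtZ @ Lam
        A.flat[:: q + 1] += 1.0
        L, info = dpotrf(A, lower=1, clean=0, overwrite_a=1)
        if info != 0:
            raise np.linalg.LinAlgError("random-effect system not positive definite")
        # one triangular solve for [Z'y | Z'X] jointly
        sol, info = dtrtrs(L, Lam.T @ rhs0, lower=1, trans=0)
        if info != 0:
            raise np.linalg.LinAlgError("singular triangular factor")
        cu, RZX = sol[:, 0], sol[:, 1:]
        XtVX = self.XtX - RZX.T @ RZX
        RX, info = dpotrf(XtVX, lower=1, clean=0)
        if info != 0:
            raise np.linalg.LinAlgError("fixed-effect system not positive definite")
        c2, info = dtrtrs(RX, Xty - RZX.T @ cu, lower=1, trans=0)
        pwrss = yty - cu @ cu - c2 @ c2
        pwrss = max(pwrss, 1e-300)
        beta, info = dtrtrs(RX, c2, lower=1, trans=1)
        nmp = self.n - self.p
        dev = (
            2.0 * np.log(np.diag(L)).sum()
            + 2.0 * np.log(np.diag(RX)).sum()
            + nmp * (1.0 + np.log(2.0 * np.pi * pwrss / nmp))
        )
        return dev, beta, XtVX, pwrss

    def _fit_reml(
        self, y: np.ndarray, terms: list[_RandomTerm], status: str, prep,
        theta_start: np.ndarray | None = None, polish: bool = True,
    ) -> LmerFit:
        Z, ZtZ, ZtX, fill = prep
        Zty = Z.T @ y
        Xty = self.X.T @ y
        yty = float(y @ y)
        rhs0 = np.concatenate([Zty[:, None], ZtX], axis=1)

        n_par = _theta_slices(terms)[-1][1]
        theta0 = np.zeros(n_par)
        bounds: list[tuple[float | None, float | None]] = []
        for (a, b), t in zip(_theta_slices(terms), terms):
            idx = 0
            for j in range(t.q_t):
                for i in range(j, t.q_t):
                    diag = i == j
                    theta0[a + idx] = 1.0 if diag else 0.0
                    bounds.append((0.0, None) if diag else (None, None))
                    idx += 1

        if theta_start is not None and len(theta_start) == n_par:
            theta0 = theta_start

        def objective(th):
            try:
                return self._profile(th, terms, ZtZ, rhs0, ZtX, Xty, yty, fill)[0]
            except np.linalg.LinAlgError:
                return _BIG  # finite sentinel keeps finite differencing sane

        opts = (
            {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8}
            if polish
            else {"maxiter": 500, "ftol": 2e-9, "gtol": 1e-5}
        )
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options=opts,
        )
        if polish:
            # derivative-free search from the standard start: on flat or
            # multi-basin REML surfaces the quasi-Newton path can stall in
            # a sub-optimal basin, and variance components need ~1e-6
            # accuracy; keep whichever optimizer found the lower criterion
            refined = optimize.minimize(
                objective,
                theta0,
                method="Nelder-Mead",
                options={"maxiter": 3000, "xatol": 1e-9, "fatol": 1e-11},
            )
            if refined.fun <= res.fun:
                res = refined
        if not np.isfinite(res.fun) or res.fun >= _BIG:
            raise np.linalg.LinAlgError("REML optimization diverged")
        dev, beta, XtVX, pwrss = self._profile(
            res.x, terms, ZtZ, rhs0, ZtX, Xty, yty, fill
        )
        lams = _build_lambdas(res.x, terms)
        sigma2 = pwrss / (self.n - self.p)
        cov = sigma2 * np.linalg.inv(XtVX)
        se = np.sqrt(np.diag(cov))
        vcomp = {
            t.group: sigma2 * lam @ lam.T for t, lam in zip(terms, lams)
        }
        self._last_theta = res.x
        return LmerFit(
            beta=beta,
            se=se,
            t=beta / se,
            fixed_names=self.fixed_names,
            sigma2=sigma2,
            vcomp=vcomp,
            status=status,
            reml_criterion=dev,
        )

    def _fit_ols(self, y: np.ndarray) -> LmerFit:
        beta, *_ = np.linalg.lstsq(self.X, y, rcond=None)
        resid = y - self.X @ beta
        dof = self.n - self.p
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(self.XtX)
        se = np.sqrt(np.diag(cov))
        return LmerFit(
            beta=beta,
            se=se,
            t=beta / se,
            fixed_names=self.fixed_names,
            sigma2=sigma2,
            vcomp={},
            status="fallback_ols" if self.terms else "converged",
            reml_criterion=np.nan,
        )

    def fit(
        self,
        y: np.ndarray,
        theta_start: np.ndarray | None = None,
        polish: bool = True,
    ) -> LmerFit:
        """Fit one response, walking the fallback chain on failure.

        ``theta_start`` warm-starts the covariance search (used across the
        component columns of one pass; fits are sequential so results stay
        deterministic).  ``polish=False`` skips the derivative-free
        refinement of the covariance parameters; fixed-effect t-values are
        stable either way, so the permutation loop uses the fast path.
        """
        y = np.asarray(y, dtype=np.float64)
        if y.shape != (self.n,):
            raise ValueError("response length does not match design")
        if not self.terms:
            return self._fit_ols(y)
        try:
            return self._fit_reml(
                y, self.terms, "converged", self._prep["full"], theta_start, polish
            )
        except (np.linalg.LinAlgError, ValueError):
            pass
        if self._prep["intercepts"] is not None:
            try:
                return self._fit_reml(
                    y,
                    self._intercept_terms,
                    "fallback_intercepts_only",
                    self._prep["intercepts"],
                    None,
                    polish,
                )
            except (np.linalg.LinAlgError, ValueError):
                pass
        fit = self._fit_ols(y)
        fit.status = "fallback_ols"
        return fit


def fit_lmer(y: np.ndarray, design: pd.DataFrame, formula: ModelFormula) -> LmerFit:
    """One-shot REML fit of ``y`` against the formula's design structure."""
    return LmerEngine(formula, design).fit(y)


def fit_components(
    Y_w: np.ndarray,
    design: pd.DataFrame,
    formula: ModelFormula,
    engine: LmerEngine | None = None,
    polish: bool = False,
) -> ComponentTValues:
    """Fit one mixed model per component score column.

    Returns the k x n_terms matrix of fixed-effect t-values with the
    intercept excluded (only modeled terms enter inference).  Covariance
    refinement is off by default: component t-values change by less than
    ~1e-4 while the permutation loop runs several times faster.
    """
    if engine is None:
        engine = LmerEngine(formula, design)
    Y_w = np.atleast_2d(np.asarray(Y_w, dtype=np.float64))
    if not np.all(np.isfinite(Y_w)):
        raise ValueError("component scores contain non-finite values")
    rows, statuses = [], []
    for c in range(Y_w.shape[1]):
        # every column starts from the same reference point: identical
        # columns must produce identical fits
        fit = engine.fit(Y_w[:, c], polish=polish)
        rows.append(fit.t[1:])  # drop intercept
        statuses.append(fit.status)
    return ComponentTValues(
        T_s=np.array(rows).reshape(Y_w.shape[1], -1),
        term_names=engine.fixed_names[1:],
        statuses=statuses,
    )
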