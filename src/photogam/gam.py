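"""Penalized-spline additive models for locomotor trajectories.

The model is a Gaussian, identity-link additive model

    rsums_i = intercept + factor effects + sum_g f_g(time_i) + a(assay_i) + e_i

with one penalized smooth f_g of time per level of a "by" factor (separate
dark-light trajectory per genotype, say), and a ridge-penalized assay
indicator block acting as a Gaussian random intercept.  Smooths use a
cubic B-spline basis with a second-order difference penalty (P-splines), a
low-rank member of the same penalized-smoother family as thin-plate
regression splines; the basis dimension ``k`` caps each smooth's
flexibility and the smoothing parameters are chosen by REML (default) or
GCV.  Each smooth is centered (sum-to-zero over its observed rows) so the
parametric main effects stay estimable.

Fitting reduces to a generalized ridge problem: minimize
``||y - X b||^2 + sum_j lam_j b' S_j b`` over coefficient vector b, with
the restricted likelihood profiled over the residual variance.  Effective
degrees of freedom are the per-block traces of the influence matrix and
drive Wald tests, AIC, and the residual degrees of freedom used downstream
for the per-second contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .traces import FACTOR_DOMAINS


class GamError(ValueError):
    """Invalid model specification or design."""


class GamConvergenceError(RuntimeError):
    """Smoothing-parameter search failed to converge."""


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothTerm:
    """One penalized smooth of a continuous variable.

    ``by`` requests a separate smooth per level of that factor (which must
    also appear among the parametric factors).
    """

    var: str = "time_s"
    k: int = 10
    by: str | None = None

    def __post_init__(self) -> None:
        if self.k < 3:
            raise GamError(f"basis dimension k must be >= 3, got {self.k}")


@dataclass
class ModelSpec:
    """Formula-level description of the additive model."""

    response: str = "rsums"
    parametric_factors: list[str] = field(default_factory=list)
    smooth_terms: list[SmoothTerm] = field(default_factory=list)
    random_effect: str | None = "assay_id"
    selection: str = "REML"

    def __post_init__(self) -> None:
        if self.selection not in ("REML", "GCV"):
            raise GamError("selection must be 'REML' or 'GCV'")
        for s in self.smooth_terms:
            if s.by is not None and s.by not in self.parametric_factors:
                raise GamError(
                    f"by-factor {s.by!r} must also be a parametric factor"
                )

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "parametric_factors": list(self.parametric_factors),
            "smooth_terms": [
                {"var": s.var, "k": s.k, "by": s.by} for s in self.smooth_terms
            ],
            "random_effect": self.random_effect,
            "selection": self.selection,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["smooth_terms"] = [SmoothTerm(**s) for s in d.get("smooth_terms", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# B-spline basis with difference penalty
# ---------------------------------------------------------------------------

_DEGREE = 3  # cubic


def _pspline_knots(xmin: float, xmax: float, k: int) -> np.ndarray:
    """Equally spaced knot vector giving exactly k cubic B-splines."""
    if xmax <= xmin:
        raise GamError("degenerate covariate range for spline basis")
    n_seg = k - _DEGREE
    h = (xmax - xmin) / n_seg
    inner = xmin + h * np.arange(n_seg + 1)
    left = xmin - h * np.arange(_DEGREE, 0, -1)
    right = xmax + h * np.arange(1, _DEGREE + 1)
    return np.concatenate([left, inner, right])


def bspline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the cubic B-spline basis at x (dense n-by-k matrix)."""
    x = np.asarray(x, dtype=float)
    lo, hi = knots[_DEGREE], knots[-_DEGREE - 1]
    if np.any(x < lo) or np.any(x > hi):
        raise GamError(
            f"covariate values outside the spline domain [{lo}, {hi}]"
        )
    return BSpline.design_matrix(x, knots, _DEGREE, extrapolate=False).toarray()


def second_difference_penalty(k: int) -> np.ndarray:
    """k-by-k roughness penalty D2'D2 (rank k-2, null space = constant+linear)."""
    d2 = np.diff(np.eye(k), n=2, axis=0)
    return d2.T @ d2


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class Block:
    """Bookkeeping for one coefficient block of the design."""

    name: str
    kind: str  # "intercept" | "parametric" | "smooth" | "random"
    start: int
    stop: int
    S: np.ndarray | None = None  # block-local penalty (None = unpenalized)
    rank: int = 0
    null_dim: int = 0
    logdet_plus: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.stop - self.start

    @property
    def sl(self) -> slice:
        return slice(self.start, self.stop)


@dataclass
class Design:
    """Assembled design matrix, penalties and coding metadata."""

    X: np.ndarray
    y: np.ndarray
    blocks: list[Block]
    col_names: list[str]
    spec: ModelSpec
    factor_levels: dict[str, list[str]]
    re_levels: list[str]
    rows: pd.DataFrame  # per-row metadata (assay, factors, smooth vars)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def penalized_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.S is not None]

    @property
    def null_space_dim(self) -> int:
        """Total unpenalized dimensions (parametric + penalty null spaces)."""
        out = 0
        for b in self.blocks:
            out += b.null_dim if b.S is not None else b.size
        return out


def _levels_of(factor: str, values: pd.Series) -> list[str]:
    """Observed factor levels, ordered with the conventional reference first."""
    observed = [str(v) for v in pd.unique(values.astype(str))]
    domain = FACTOR_DOMAINS.get(factor)
    if domain is not None:
        ordered = [l for l in domain if l in observed]
        extra = sorted(set(observed) - set(ordered))
        if extra:
            raise GamError(f"levels {extra} of {factor!r} outside declared domain")
        return ordered
    return sorted(observed)


def build_design(spec: ModelSpec, data: pd.DataFrame) -> Design:
    """Build the model matrix and penalty blocks from tidy group-series data.

    Treatment coding with the first (reference) level absorbed by the
    intercept; one centered spline block per by-level with its difference
    penalty; one identity-penalized indicator block per random-effect term.
    """
    data = data.reset_index(drop=True)
    needed = [spec.response] + spec.parametric_factors + [s.var for s in spec.smooth_terms]
    if spec.random_effect:
        needed.append(spec.random_effect)
    for col in needed:
        if col not in data.columns:
            raise GamError(f"data lack required column {col!r}")

    n = len(data)
    y = data[spec.response].to_numpy(dtype=float)
    cols: list[np.ndarray] = []
    names: list[str] = []
    blocks: list[Block] = []

    def add_block(block_cols: list[np.ndarray], block_names: list[str], **kw) -> None:
        start = sum(c.shape[1] if c.ndim == 2 else 1 for c in cols)
        for c in block_cols:
            cols.append(c if c.ndim == 2 else c[:, None])
        names.extend(block_names)
        stop = start + sum(
            c.shape[1] if c.ndim == 2 else 1 for c in block_cols
        )
        blocks.append(Block(start=start, stop=stop, **kw))

    # intercept
    add_block([np.ones(n)], ["(Intercept)"], name="(Intercept)", kind="intercept")

    # parametric factors, treatment coding
    factor_levels: dict[str, list[str]] = {}
    for f in spec.parametric_factors:
        levels = _levels_of(f, data[f])
        factor_levels[f] = levels
        vals = data[f].astype(str).to_numpy()
        block_cols = [(vals == lev).astype(float) for lev in levels[1:]]
        if block_cols:
            add_block(
                block_cols,
                [f"{f}{lev}" for lev in levels[1:]],
                name=f,
                kind="parametric",
                meta={"factor": f, "levels": levels},
            )

    # smooth terms (one centered penalized block per by-level)
    for s in spec.smooth_terms:
        x = data[s.var].to_numpy(dtype=float)
        by_levels = factor_levels[s.by] if s.by else [None]
        for lev in by_levels:
            mask = (
                np.ones(n, dtype=bool)
                if lev is None
                else (data[s.by].astype(str) == lev).to_numpy()
            )
            if not mask.any():
                raise GamError(f"no data for by-level {lev!r} of smooth {s.var}")
            x_lev = x[mask]
            n_unique = np.unique(x_lev).size
            if n_unique < s.k:
                raise GamError(
                    f"smooth of {s.var} (k={s.k}) needs at least k distinct "
                    f"covariate values, found {n_unique}"
                )
            knots = _pspline_knots(float(x_lev.min()), float(x_lev.max()), s.k)
            B = np.zeros((n, s.k))
            B[mask] = bspline_basis(x_lev, knots)
            # sum-to-zero centering over the block's observed rows
            c = B.sum(axis=0)
            Q, _ = np.linalg.qr(c[:, None], mode="complete")
            Z = Q[:, 1:]
            Bc = B @ Z
            S = Z.T @ second_difference_penalty(s.k) @ Z
            S = 0.5 * (S + S.T)
            rank = s.k - 2
            eig = np.linalg.eigvalsh(S)
            logdet_plus = float(np.sum(np.log(eig[-rank:])))
            label = f"s({s.var})" + (f":{s.by}{lev}" if lev is not None else "")
            add_block(
                [Bc],
                [f"{label}.{j + 1}" for j in range(s.k - 1)],
                name=label,
                kind="smooth",
                S=S,
                rank=rank,
                null_dim=(s.k - 1) - rank,
                logdet_plus=logdet_plus,
                meta={"var": s.var, "k": s.k, "by": s.by, "level": lev,
                      "knots": knots, "Z": Z,
                      "xmin": float(x_lev.min()), "xmax": float(x_lev.max())},
            )

    # random-effect block: ridge-penalized assay indicators
    re_levels: list[str] = []
    if spec.random_effect:
        vals = data[spec.random_effect].astype(str).to_numpy()
        re_levels = sorted(pd.unique(vals))
        block_cols = [(vals == lev).astype(float) for lev in re_levels]
        m = len(re_levels)
        add_block(
            block_cols,
            [f"s({spec.random_effect}).{lev}" for lev in re_levels],
            name=f"s({spec.random_effect})",
            kind="random",
            S=np.eye(m),
            rank=m,
            null_dim=0,
            logdet_plus=0.0,
            meta={"factor": spec.random_effect, "levels": re_levels},
        )

    X = np.hstack(cols)
    row_cols = [c for c in needed if c != spec.response and c in data.columns]
    rows = data[sorted(set(row_cols))].copy()
    return Design(
        X=X,
        y=y,
        blocks=blocks,
        col_names=names,
        spec=spec,
        factor_levels=factor_levels,
        re_levels=re_levels,
        rows=rows,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class GamFit:
    """A fitted additive model."""

    design: Design
    beta: np.ndarray
    V_beta: np.ndarray
    lambdas: dict[str, float]
    edf_by_term: dict[str, float]
    sigma2: float
    fitted: np.ndarray
    deviance_explained: float
    reml_criterion: float | None
    gcv_score: float | None
    selection: str

    @property
    def n_obs(self) -> int:
        return self.design.n_obs

    @property
    def total_edf(self) -> float:
        return float(sum(self.edf_by_term.values()))

    @property
    def residual_df(self) -> float:
        return self.n_obs - self.total_edf

    @property
    def residuals(self) -> np.ndarray:
        return self.design.y - self.fitted

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    def loglik(self) -> float:
        """Gaussian log-likelihood at the ML residual-variance estimate."""
        n = self.n_obs
        s2 = self.rss / n
        return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)

    def aic(self) -> float:
        """AIC with model dimension = total edf + 1 (residual variance)."""
        return -2.0 * self.loglik() + 2.0 * (self.total_edf + 1.0)

    def summary_dict(self) -> dict:
        return {
            "n_obs": self.n_obs,
            "selection": self.selection,
            "lambdas": self.lambdas,
            "edf_by_term": self.edf_by_term,
            "total_edf": self.total_edf,
            "sigma2": self.sigma2,
            "deviance_explained": self.deviance_explained,
            "aic": self.aic(),
            "coefficients": dict(zip(self.design.col_names, self.beta.tolist())),
        }


def _assemble_penalty(design: Design, lam: np.ndarray) -> np.ndarray:
    p = design.n_coef
    S = np.zeros((p, p))
    for lam_j, b in zip(lam, design.penalized_blocks):
        S[b.sl, b.sl] += lam_j * b.S
    return S


def _chol_solve(H: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky solve with tiny-jitter fallback; returns (solution, chol)."""
    jitter = 0.0
    scale = float(np.mean(np.diag(H))) or 1.0
    for _ in range(4):
        try:
            L = sla.cholesky(H + jitter * np.eye(H.shape[0]), lower=True)
            return sla.cho_solve((L, True), rhs), L
        except np.linalg.LinAlgError:
            jitter = max(jitter * 100.0, 1e-10 * scale)
    raise GamError("design is rank deficient: normal equations not positive definite")


def _reml_neg2(
    lam: np.ndarray,
    design: Design,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
) -> float:
    """Negative twice the restricted log-likelihood, sigma^2 profiled out."""
    n, M = design.n_obs, design.null_space_dim
    H = XtX + _assemble_penalty(design, lam)
    beta, L = _chol_solve(H, Xty)
    rss = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
    pen = beta @ (H - XtX) @ beta
    # relative floor keeps the profile well defined for (near-)exact fits,
    # where float round-off would otherwise pull lambda to zero
    sig2 = max(rss + pen, 1e-10 * yty + 1e-300) / (n - M)
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(L))))
    logdet_S = sum(
        b.rank * np.log(l) + b.logdet_plus
        for l, b in zip(lam, design.penalized_blocks)
    )
    return (n - M) * (np.log(2.0 * np.pi * sig2) + 1.0) + logdet_H - logdet_S


def _gcv_score(
    lam: np.ndarray,
    design: Design,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
) -> float:
    n = design.n_obs
    H = XtX + _assemble_penalty(design, lam)
    beta, L = _chol_solve(H, Xty)
    rss = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
    tr_A = float(np.trace(sla.cho_solve((L, True), XtX)))
    denom = n - tr_A
    if denom <= 0:
        return np.inf
    return n * rss / denom**2


def fit_gam(
    design: Design,
    selection: str | None = None,
    lambdas: Sequence[float] | dict[str, float] | None = None,
    maxiter: int = 400,
) -> GamFit:
    """Fit the penalized model, selecting smoothing parameters if not given.

    With ``lambdas`` supplied the fit is a single generalized-ridge solve
    at those frozen values; otherwise each penalized block's lambda is
    chosen by minimizing the REML (default) or GCV criterion over log
    smoothing parameters with a derivative-free simplex search.
    """
    selection = selection or design.spec.selection
    n, p = design.X.shape
    if n <= design.null_space_dim:
        raise GamError(
            f"n_obs ({n}) must exceed the unpenalized dimension "
            f"({design.null_space_dim})"
        )
    XtX = design.X.T @ design.X
    Xty = design.X.T @ design.y
    yty = float(design.y @ design.y)
    pen_blocks = design.penalized_blocks

    reml_val: float | None = None
    gcv_val: float | None = None
    if lambdas is not None:
        if isinstance(lambdas, dict):
            lam = np.array([lambdas[b.name] for b in pen_blocks], dtype=float)
        else:
            lam = np.asarray(lambdas, dtype=float)
        if lam.size != len(pen_blocks):
            raise GamError(
                f"expected {len(pen_blocks)} smoothing parameters, got {lam.size}"
            )
        if np.any(lam < 0):
            raise GamError("smoothing parameters must be >= 0")
    elif not pen_blocks:
        lam = np.zeros(0)
    else:
        # scale-matched start, then simplex search over log-lambda
        lam0 = np.array(
            [
                (np.trace(XtX[b.sl, b.sl]) + 1e-8) / (np.trace(b.S) + 1e-8)
                for b in pen_blocks
            ]
        )
        crit = _reml_neg2 if selection == "REML" else _gcv_score
        obj = lambda rho: crit(np.exp(np.clip(rho, -25, 25)), design, XtX, Xty, yty)
        opts = {
            "maxiter": maxiter * max(1, len(pen_blocks)),
            "maxfev": maxiter * max(1, len(pen_blocks)),
            "xatol": 0.02,  # ~2% precision on each lambda
            "fatol": 1e-5,
        }
        res = minimize(obj, np.log(lam0), method="Nelder-Mead", options=opts)
        if not res.success:  # restart once from the best point found
            res2 = minimize(obj, res.x, method="Nelder-Mead", options=opts)
            if res2.fun <= res.fun:
                res = res2
        if not np.isfinite(res.fun):
            raise GamConvergenceError(
                f"smoothing-parameter search diverged: {res.message}"
            )
        if not res.success:
            warnings.warn(
                f"smoothing-parameter search did not fully converge: "
                f"{res.message}",
                RuntimeWarning,
            )
        lam = np.exp(np.clip(res.x, -25, 25))

    if pen_blocks:
        reml_val = float(_reml_neg2(lam, design, XtX, Xty, yty))
        gcv_val = float(_gcv_score(lam, design, XtX, Xty, yty))

    H = XtX + _assemble_penalty(design, lam)
    beta, L = _chol_solve(H, Xty)
    fitted = design.X @ beta
    resid = design.y - fitted
    rss = float(resid @ resid)

    # per-term effective degrees of freedom: block traces of (H^-1 X'X)
    A = sla.cho_solve((L, True), XtX)
    diag_A = np.diag(A)
    edf_by_term = {
        b.name: float(np.sum(diag_A[b.sl])) for b in design.blocks
    }
    total_edf = float(np.sum(diag_A))
    if n - total_edf <= 0:
        raise GamError("model saturates the data: no residual degrees of freedom")
    sigma2 = rss / (n - total_edf)
    Hinv = sla.cho_solve((L, True), np.eye(p))
    V_beta = sigma2 * 0.5 * (Hinv + Hinv.T)

    tss = float(np.sum((design.y - design.y.mean()) ** 2))
    dev_expl = 1.0 - rss / tss if tss > 0 else 0.0

    lam_by_name = {b.name: float(l) for b, l in zip(pen_blocks, lam)}
    return GamFit(
        design=design,
        beta=beta,
        V_beta=V_beta,
        lambdas=lam_by_name,
        edf_by_term=edf_by_term,
        sigma2=sigma2,
        fitted=fitted,
        deviance_explained=float(np.clip(dev_expl, 0.0, 1.0)),
        reml_criterion=reml_val,
        gcv_score=gcv_val,
        selection=selection if lambdas is None else "fixed",
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def build_prediction_matrix(
    fit_or_design: "GamFit | Design",
    newdata: pd.DataFrame,
    include_random: bool = False,
    allow_extrapolation: bool = False,
) -> np.ndarray:
    """Model-matrix rows for new data under the fitted coding."""
    design = (
        fit_or_design.design if isinstance(fit_or_design, GamFit) else fit_or_design
    )
    spec = design.spec
    n = len(newdata)
    X = np.zeros((n, design.n_coef))
    for b in design.blocks:
        if b.kind == "intercept":
            X[:, b.start] = 1.0
        elif b.kind == "parametric":
            f = b.meta["factor"]
            levels = b.meta["levels"]
            if f not in newdata.columns:
                raise GamError(f"newdata lack factor {f!r}")
            vals = newdata[f].astype(str).to_numpy()
            unknown = set(vals) - set(levels)
            if unknown:
                raise GamError(f"unknown level(s) {sorted(unknown)} for {f!r}")
            for j, lev in enumerate(levels[1:]):
                X[:, b.start + j] = (vals == lev).astype(float)
        elif b.kind == "smooth":
            var, by, lev = b.meta["var"], b.meta["by"], b.meta["level"]
            if var not in newdata.columns:
                raise GamError(f"newdata lack smooth covariate {var!r}")
            x = newdata[var].to_numpy(dtype=float)
            mask = (
                np.ones(n, dtype=bool)
                if by is None
                else (newdata[by].astype(str) == lev).to_numpy()
            )
            if mask.any():
                xm = x[mask]
                lo, hi = b.meta["xmin"], b.meta["xmax"]
                if (xm.min() < lo or xm.max() > hi):
                    if not allow_extrapolation:
                        raise GamError(
                            f"{var} values outside fitted range [{lo}, {hi}]; "
                            "pass allow_extrapolation=True to clamp"
                        )
                    xm = np.clip(xm, lo, hi)
                X[np.ix_(mask, range(b.start, b.stop))] = (
                    bspline_basis(xm, b.meta["knots"]) @ b.meta["Z"]
                )
        elif b.kind == "random":
            if include_random:
                f = b.meta["factor"]
                if f not in newdata.columns:
                    raise GamError(
                        f"include_random=True but newdata lack {f!r}"
                    )
                vals = newdata[f].astype(str).to_numpy()
                for j, lev in enumerate(b.meta["levels"]):
                    X[:, b.start + j] = (vals == lev).astype(float)
    return X


def predict(
    fit: GamFit,
    newdata: pd.DataFrame,
    include_random: bool = False,
    allow_extrapolation: bool = False,
) -> pd.DataFrame:
    """Predicted mean, SE and 95% CI per row of ``newdata``.

    Random-effect columns are zeroed (population-level prediction) unless
    ``include_random`` is set.
    """
    X = build_prediction_matrix(
        fit, newdata, include_random=include_random,
        allow_extrapolation=allow_extrapolation,
    )
    mean = X @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.V_beta, X), 0.0))
    return pd.DataFrame(
        {
            "mean": mean,
            "se": se,
            "ci_lo": mean - 1.96 * se,
            "ci_hi": mean + 1.96 * se,
        },
        index=newdata.index,
    )


# ---------------------------------------------------------------------------
# inference on terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermTest:
    """Wald test of one model term."""

    term: str
    kind: str  # "parametric" | "smooth" | "random"
    statistic: float
    df: float  # t tests: residual df; F tests: numerator df
    edf: float | None
    p_value: float


def term_tests(fit: GamFit) -> list[TermTest]:
    """Wald tests for every parametric level and smooth term.

    Parametric dummy coefficients get two-sided t tests against the
    residual degrees of freedom ``n - total edf``.  Each smooth (and the
    random-effect block) gets a Wald quadratic form on its coefficients
    using the pseudo-inverse of its covariance block, referred to an F
    distribution with numerator df equal to the rounded edf.
    """
    out: list[TermTest] = []
    nu = fit.residual_df
    for b in fit.design.blocks:
        if b.kind == "intercept":
            continue
        if b.kind == "parametric":
            for j in range(b.size):
                idx = b.start + j
                se = np.sqrt(max(fit.V_beta[idx, idx], 0.0))
                tstat = fit.beta[idx] / se if se > 0 else np.inf
                p = 2.0 * scipy.stats.t.sf(abs(tstat), nu)
                out.append(
                    TermTest(
                        term=fit.design.col_names[idx],
                        kind="parametric",
                        statistic=float(tstat),
                        df=float(nu),
                        edf=None,
                        p_value=float(p),
                    )
                )
        else:
            beta_b = fit.beta[b.sl]
            V_b = fit.V_beta[b.sl, b.sl]
            edf = fit.edf_by_term[b.name]
            r = max(1, int(round(edf)))
            Vinv = np.linalg.pinv(V_b, rcond=1e-10, hermitian=True)
            wald = float(beta_b @ Vinv @ beta_b)
            fstat = wald / r
            p = scipy.stats.f.sf(fstat, r, nu)
            out.append(
                TermTest(
                    term=b.name,
                    kind=b.kind,
                    statistic=float(fstat),
                    df=float(r),
                    edf=float(edf),
                    p_value=float(p),
                )
            )
    return out


# ---------------------------------------------------------------------------
# adequacy checks and model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BasisCheck:
    """Basis-dimension adequacy diagnostic for one smooth."""

    term: str
    k_prime: float  # maximum attainable edf of the block
    edf: float
    k_index: float
    p_value: float
    flagged: bool


def check_basis_dimension(
    fit: GamFit,
    n_shuffles: int = 500,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> list[BasisCheck]:
    """Residual-autocorrelation check of each smooth's basis dimension.

    ``k_index`` is the mean squared difference of time-adjacent residuals
    (within each assay-by-group series) divided by twice the residual
    variance; values well below 1 indicate structure the basis could not
    follow.  The p-value comes from randomly permuting residuals over time
    within each series.  A smooth is flagged when its edf is within 0.5 of
    the basis ceiling or the permutation p-value falls below ``alpha``.
    Saturation only counts when there is residual variation left to absorb
    (an essentially exact fit, residuals at numerical precision, cannot
    indicate an inadequate basis even though its edf sits at the ceiling).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    design = fit.design
    resid = fit.residuals
    rows = design.rows
    spec = design.spec
    # an (essentially) exact fit leaves only numerical-precision residuals;
    # neither residual structure nor edf saturation can indicate an
    # inadequate basis there
    noise_floor = 1e-8 * float(np.mean(design.y**2) + 1e-300)
    exact_fit = fit.sigma2 <= noise_floor

    series_cols = [c for c in rows.columns if c not in
                   {s.var for s in spec.smooth_terms}]
    time_var = spec.smooth_terms[0].var if spec.smooth_terms else None
    out: list[BasisCheck] = []
    for b in design.blocks:
        if b.kind != "smooth":
            continue
        var, by, lev = b.meta["var"], b.meta["by"], b.meta["level"]
        mask = (
            np.ones(design.n_obs, dtype=bool)
            if by is None
            else (rows[by].astype(str) == lev).to_numpy()
        )
        sub = rows.loc[mask].copy()
        sub["_resid"] = resid[mask]
        sub = sub.sort_values(var)
        group_cols = [c for c in series_cols if c != var]
        # time-adjacent residual pairs within each series
        sq_diffs: list[np.ndarray] = []
        series: list[np.ndarray] = []
        if group_cols:
            grouped = sub.groupby(group_cols, sort=False)
            for _, g in grouped:
                r = g["_resid"].to_numpy()
                if r.size >= 2:
                    series.append(r)
        else:
            series.append(sub["_resid"].to_numpy())
        all_r = np.concatenate(series)
        var_r = float(np.mean(all_r**2))
        if var_r == 0 or exact_fit:
            out.append(BasisCheck(b.name, float(b.size),
                                  float(fit.edf_by_term[b.name]),
                                  np.nan, 1.0, False))
            continue

        def msd(rs: list[np.ndarray]) -> float:
            return float(
                np.mean(np.concatenate([np.diff(r) ** 2 for r in rs]))
            )

        obs = msd(series) / (2.0 * var_r)
        count = 0
        for _ in range(n_shuffles):
            perm = [rng.permutation(r) for r in series]
            if msd(perm) / (2.0 * var_r) <= obs:
                count += 1
        p = (1.0 + count) / (1.0 + n_shuffles)
        edf = fit.edf_by_term[b.name]
        saturated = edf >= b.size - 0.5
        flagged = saturated or (p < alpha)
        out.append(BasisCheck(b.name, float(b.size), float(edf),
                              float(obs), float(p), bool(flagged)))
    return out


def compare_models_aic(fits: Sequence[GamFit]) -> pd.DataFrame:
    """Rank fits of the same data by AIC (ascending)."""
    if not fits:
        raise GamError("no fits to compare")
    y0 = fits[0].design.y
    for f in fits[1:]:
        if f.n_obs != fits[0].n_obs or not np.array_equal(f.design.y, y0):
            raise GamError("AIC comparison requires fits on identical data")
    df = pd.DataFrame(
        {
            "model": [
                " + ".join(b.name for b in f.design.blocks if b.kind != "intercept")
                or "(intercept)"
                for f in fits
            ],
            "edf": [f.total_edf for f in fits],
            "aic": [f.aic() for f in fits],
            "deviance_explained": [f.deviance_explained for f in fits],
        }
    )
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df.sort_values("aic").reset_index(drop=True)
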