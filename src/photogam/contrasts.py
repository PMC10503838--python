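"""Estimated marginal means and Tukey-adjusted contrast trajectories.

For a fitted additive model, the estimated marginal mean (EMM,
least-squares mean) of a group level at time t is the model prediction at
that (time, level) with random effects zeroed and any other parametric
factors averaged with equal weights over their levels.  All pairwise
EMM differences are tested at every analyzed second; p-values are
Tukey-adjusted across the pairs at that second via the studentized-range
distribution with ``sqrt(2)|t|`` as the range statistic and residual
degrees of freedom ``n - total edf``.  With two groups the adjustment
reduces analytically to the two-sided t test.

Note the adjustment is across pairs within one second only -- there is no
correction across the thousands of seconds of a trajectory.  That
time-wise multiplicity is a property of the per-second workflow this
module reproduces, not an oversight; treat the significance trajectory as
descriptive, and the period-level proportion summaries as its intended
aggregation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from numpy.polynomial.legendre import leggauss
from scipy.special import gammaln

from .gam import GamError, GamFit, build_prediction_matrix


class ContrastError(ValueError):
    """Invalid contrast request or degenerate standard error."""


# ---------------------------------------------------------------------------
# studentized-range upper tail, vectorized over the statistic
# ---------------------------------------------------------------------------

_Z_NODES, _Z_WEIGHTS = leggauss(160)
_S_NODES, _S_WEIGHTS = leggauss(48)


def _range_cdf(q: np.ndarray, m: int) -> np.ndarray:
    """P(range of m iid std normals <= q), Gauss-Legendre over the z axis."""
    lo, hi = -9.0, 9.0
    z = 0.5 * (hi - lo) * _Z_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _Z_WEIGHTS
    phi = scipy.stats.norm.pdf(z)
    Phi = scipy.stats.norm.cdf(z)
    # inner[i, j] = (Phi(z_j) - Phi(z_j - q_i))^(m-1)
    inner = (Phi[None, :] - scipy.stats.norm.cdf(z[None, :] - q[:, None])) ** (m - 1)
    return np.clip(m * inner @ (w * phi), 0.0, 1.0)


def studentized_range_sf(q, m: int, df: float) -> np.ndarray:
    """P(Q_{m, df} >= q) for the studentized range, vectorized in q.

    Q = R / S with R the range of m standard normals and S the square root
    of a chi-squared over its df.  The mixture over S is integrated by
    Gauss-Legendre on a +-12-standard-deviation window around E[S] ~ 1,
    which covers S's mass for any practical df.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if m < 2:
        raise ContrastError("studentized range needs m >= 2 means")
    if df <= 0:
        raise ContrastError("df must be positive")
    sd_s = 1.0 / np.sqrt(2.0 * df)
    lo = max(1e-4, 1.0 - 12.0 * sd_s)
    hi = 1.0 + 12.0 * sd_s
    s = 0.5 * (hi - lo) * _S_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _S_WEIGHTS
    # density of S: 2 (df/2)^(df/2) / Gamma(df/2) * s^(df-1) exp(-df s^2 / 2)
    log_fs = (
        np.log(2.0)
        + 0.5 * df * np.log(0.5 * df)
        - gammaln(0.5 * df)
        + (df - 1.0) * np.log(s)
        - 0.5 * df * s**2
    )
    fs = np.exp(log_fs)
    qpos = np.maximum(q, 0.0)
    cdf = np.zeros_like(qpos)
    for si, wi, fi in zip(s, w, fs):
        cdf += wi * fi * _range_cdf(qpos * si, m)
    return np.clip(1.0 - cdf, 0.0, 1.0)


def tukey_p_adjust(t_ratio, m: int, df: float) -> np.ndarray:
    """Tukey-adjusted p for pairwise t ratios among m means.

    ``p = P(Q_{m, df} >= sqrt(2) |t|)``; for m = 2 the studentized range of
    two means is exactly ``sqrt(2) |t|`` so the adjusted p equals the
    two-sided t-test p, computed directly from the t distribution.
    """
    t_ratio = np.atleast_1d(np.asarray(t_ratio, dtype=float))
    if m == 2:
        return 2.0 * scipy.stats.t.sf(np.abs(t_ratio), df)
    return studentized_range_sf(np.sqrt(2.0) * np.abs(t_ratio), m, df)


# ---------------------------------------------------------------------------
# estimated marginal means
# ---------------------------------------------------------------------------


def _emm_rows(
    fit: GamFit, group_factor: str, times: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Equal-weight averaged design rows, shape (n_times, n_levels, p)."""
    design = fit.design
    spec = design.spec
    if group_factor not in design.factor_levels:
        raise ContrastError(f"{group_factor!r} is not a fitted parametric factor")
    levels = design.factor_levels[group_factor]
    other = [f for f in spec.parametric_factors if f != group_factor]
    other_grids = [design.factor_levels[f] for f in other]
    combos = list(itertools.product(*other_grids)) if other else [()]
    time_var = spec.smooth_terms[0].var if spec.smooth_terms else None

    T, L = len(times), len(levels)
    p = design.n_coef
    rows = np.zeros((T, L, p))
    for li, lev in enumerate(levels):
        for combo in combos:
            newdata = pd.DataFrame({group_factor: lev}, index=range(T))
            for f, v in zip(other, combo):
                newdata[f] = v
            if time_var is not None:
                newdata[time_var] = times
            rows[:, li, :] += build_prediction_matrix(
                fit, newdata, include_random=False
            )
    rows /= len(combos)
    return rows, levels


def emm_at(fit: GamFit, group_factor: str, t_s: float) -> pd.DataFrame:
    """EMM and SE for every level of ``group_factor`` at one time point."""
    rows, levels = _emm_rows(fit, group_factor, np.asarray([t_s], dtype=float))
    X = rows[0]
    emm = X @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.V_beta, X), 0.0))
    return pd.DataFrame({"level": levels, "emm": emm, "se": se})


@dataclass
class ContrastTrajectory:
    """Per-second EMMs and Tukey-adjusted pairwise differences."""

    group_factor: str
    levels: list[str]
    alpha: float
    df: float
    emms: pd.DataFrame  # time_s, level, emm, se
    pairs: pd.DataFrame  # time_s, pair, a, b, diff, se, t_ratio, df, p_adj, ...

    @property
    def pair_names(self) -> list[str]:
        return sorted(self.pairs["pair"].unique())

    def pair_table(self, a: str, b: str) -> pd.DataFrame:
        """Rows for the unordered pair (a, b), oriented as a minus b."""
        fwd = self.pairs[(self.pairs["a"] == a) & (self.pairs["b"] == b)]
        if len(fwd):
            return fwd
        rev = self.pairs[(self.pairs["a"] == b) & (self.pairs["b"] == a)]
        if not len(rev):
            raise ContrastError(f"no contrast for pair ({a}, {b})")
        out = rev.copy()
        out["a"], out["b"] = a, b
        out["pair"] = f"{a} - {b}"
        out["diff"] = -out["diff"]
        out["t_ratio"] = -out["t_ratio"]
        out["direction"] = np.where(
            out["diff"] > 0, a, np.where(out["diff"] < 0, b, "")
        )
        return out


def pairwise_trajectory(
    fit: GamFit,
    group_factor: str,
    times: np.ndarray | None = None,
    alpha: float = 0.05,
) -> ContrastTrajectory:
    """All pairwise EMM contrasts of ``group_factor`` at every time point.

    ``times`` defaults to the distinct fitted time values.  Each row of the
    pair table carries the difference (a minus b in level order), its
    standard error from the coefficient covariance, the t ratio, the
    Tukey-adjusted p-value, the direction (level with the larger EMM) and
    the significance flag at ``alpha``.
    """
    design = fit.design
    spec = design.spec
    time_var = spec.smooth_terms[0].var if spec.smooth_terms else None
    if times is None:
        if time_var is None:
            raise ContrastError("model has no smooth: supply explicit times")
        times = np.unique(design.rows[time_var].to_numpy(dtype=float))
    times = np.asarray(times, dtype=float)

    rows, levels = _emm_rows(fit, group_factor, times)
    m = len(levels)
    if m < 2:
        raise ContrastError("need at least 2 levels for pairwise contrasts")
    nu = fit.residual_df

    emm = rows @ fit.beta  # (T, L)
    # per-level variance terms via Y_l = X_l V
    VX = np.einsum("tlp,pq->tlq", rows, fit.V_beta)
    emm_se = np.sqrt(np.maximum(np.einsum("tlp,tlp->tl", rows, VX), 0.0))
    emms = pd.DataFrame(
        {
            "time_s": np.repeat(times, m),
            "level": np.tile(levels, len(times)),
            "emm": emm.reshape(-1),
            "se": emm_se.reshape(-1),
        }
    )

    records = []
    for ai, bi in itertools.combinations(range(m), 2):
        d_rows = rows[:, ai, :] - rows[:, bi, :]
        diff = emm[:, ai] - emm[:, bi]
        var = np.einsum(
            "tp,tp->t", d_rows, np.einsum("tp,pq->tq", d_rows, fit.V_beta)
        )
        se = np.sqrt(np.maximum(var, 0.0))
        bad = (se == 0) & (diff != 0)
        if np.any(bad):
            raise ContrastError(
                f"degenerate zero SE with nonzero difference for pair "
                f"({levels[ai]}, {levels[bi]})"
            )
        with np.errstate(invalid="ignore"):
            t_ratio = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
        p_adj = tukey_p_adjust(t_ratio, m, nu)
        p_adj = np.where((se == 0) & (diff == 0), 1.0, p_adj)
        a, b = levels[ai], levels[bi]
        records.append(
            pd.DataFrame(
                {
                    "time_s": times,
                    "pair": f"{a} - {b}",
                    "a": a,
                    "b": b,
                    "diff": diff,
                    "se": se,
                    "t_ratio": t_ratio,
                    "df": nu,
                    "p_adj": p_adj,
                    "direction": np.where(diff > 0, a, np.where(diff < 0, b, "")),
                    "significant": p_adj < alpha,
                }
            )
        )
    pair_df = pd.concat(records, ignore_index=True)
    return ContrastTrajectory(
        group_factor=group_factor,
        levels=levels,
        alpha=alpha,
        df=float(nu),
        emms=emms,
        pairs=pair_df,
    )
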