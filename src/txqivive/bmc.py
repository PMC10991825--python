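"""Per-gene benchmark-concentration (BMC) modelling with model averaging.

Four monotone concentration-response families are fitted to each gene's
log2 expression by multi-start nonlinear least squares:

    hill    f(x) = a + b * x^n / (k^n + x^n)
    power   f(x) = a + b * x^p               (p >= 1)
    exp3    f(x) = a * exp(s * (b*x)^d)      (s = +/-1 by direction)
    exp5    f(x) = a * (c - (c-1) * exp(-(b*x)^d))

The benchmark response is 1 residual standard deviation (BMR = 1 SD), so
the BMC solves |f(BMC) - f(0)| = sigma. Point estimates are averaged across
families with Akaike weights (geometric mean on the BMC scale); BMDL/BMDU
are the 5th/95th percentiles of a parametric bootstrap in which each
replicate draws a family by weight, simulates new residuals, refits and
recomputes the BMC (two-sided 90% interval by default).

Genes are then screened with three filter rules: adequate fit
(lack-of-fit p > 0.001), precision (BMDU/BMDL <= 40) and in-range potency
(BMC <= highest tested concentration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._lm import lm_fit_batch
from .config import BMCConfig
from .dataset import ConcentrationResponseDataset

__all__ = [
    "DoseResponseModelFit",
    "BMDEstimate",
    "GeneBMDRecord",
    "MODEL_IDS",
    "fit_model",
    "fit_pvalue",
    "compute_bmd",
    "compute_bmd_numeric",
    "model_average",
    "fit_gene",
    "fit_dataset",
    "filter_genes",
    "rank_genes",
    "records_to_frame",
    "accumulation_table",
]

MODEL_IDS = ("hill", "power", "exp3", "exp5")

# restricted-model convention: shape/slope parameters >= 1 so curves stay
# sublinear-free at the origin (avoids infinite-slope artifacts at x -> 0)
_SHAPE_LO, _SHAPE_HI = 1.0, 18.0


# --------------------------------------------------------------------------
# model functions
# --------------------------------------------------------------------------


def _hill(x, p):
    a, b, k, n = p
    xn = np.power(np.maximum(x, 0.0), n)
    return a + b * xn / (k**n + xn)


def _power(x, p):
    a, b, pw = p
    return a + b * np.power(np.maximum(x, 0.0), pw)


def _exp3(x, p, s):
    a, b, d = p
    # exponent clipped to keep the optimizer in finite territory; the
    # clip only binds at absurd parameter combinations far from any fit
    z = np.clip(np.power(b * np.maximum(x, 0.0), d), 0.0, 50.0)
    return a * np.exp(s * z)


def _exp5(x, p):
    a, b, c, d = p
    z = np.clip(np.power(b * np.maximum(x, 0.0), d), 0.0, 50.0)
    return a * (c - (c - 1.0) * np.exp(-z))


def model_curve(model_id: str, params: np.ndarray, direction: int):
    """Return f(x) for a fitted family (direction matters for exp3 only)."""
    if model_id == "hill":
        return lambda x: _hill(np.asarray(x, dtype=float), params)
    if model_id == "power":
        return lambda x: _power(np.asarray(x, dtype=float), params)
    if model_id == "exp3":
        return lambda x: _exp3(np.asarray(x, dtype=float), params, direction)
    if model_id == "exp5":
        return lambda x: _exp5(np.asarray(x, dtype=float), params)
    raise ValueError(f"unknown model {model_id!r}")


@dataclass
class DoseResponseModelFit:
    """One family fitted to one gene."""

    model_id: str
    params: np.ndarray
    sigma: float                    # residual SD (MLE, SSE/N)
    loglik: float
    aic: float
    converged: bool
    direction: int                  # +1 increasing, -1 decreasing
    n_params: int                   # mean-function parameters (excl. sigma)
    sse: float
    n_obs: int = 0

    def predict(self, x):
        return model_curve(self.model_id, self.params, self.direction)(x)

    @property
    def sigma_bmr(self) -> float:
        """Degrees-of-freedom-corrected residual SD used as the BMR
        (sqrt(SSE / (N - p)); the MLE ``sigma`` feeds the likelihood)."""
        df = max(self.n_obs - self.n_params, 1)
        return math.sqrt(self.sse / df) if np.isfinite(self.sse) else np.nan


@dataclass
class BMDEstimate:
    """Model-averaged benchmark concentration with bootstrap bounds (µM)."""

    bmd: float
    bmdl: float
    bmdu: float
    bmr_type: str = "1sd"
    weights: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.bmd)


@dataclass
class GeneBMDRecord:
    gene_id: str
    estimate: BMDEstimate
    fit_p: float
    pass_fit_p: bool
    pass_ratio: bool
    pass_range: bool

    @property
    def responsive(self) -> bool:
        return self.pass_fit_p and self.pass_ratio and self.pass_range

    @property
    def bmdl_for_ranking(self) -> float:
        b = self.estimate.bmdl
        return b if np.isfinite(b) else math.inf


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _starts(model_id, x, y, direction, n_starts):
    """Coarse multi-start grid informed by the data."""
    pos = x[x > 0]
    cmin, cmax = pos.min(), pos.max()
    a0 = float(np.mean(y[x == 0])) if (x == 0).any() else float(y[0])
    span = float(np.ptp(y)) or 0.1
    b0 = direction * span
    ks = np.geomspace(cmin, cmax, max(2, n_starts // 2))
    shapes = (1.0, 3.0)
    starts = []
    if model_id == "hill":
        for k in ks:
            for n in shapes:
                starts.append([a0, b0, k, n])
    elif model_id == "power":
        # variable projection: power is linear in (a, b) given the
        # exponent, so profile a dense exponent grid exactly and keep the
        # best few as starts for the LM polish
        for a_p, b_p, pw in _power_profile_starts(x, y, direction):
            starts.append([a_p, b_p, pw])
    elif model_id == "exp3":
        amag = max(abs(a0), 0.1)
        for k in ks:
            for d in shapes:
                starts.append([amag, 1.0 / k, d])
    elif model_id == "exp5":
        amag = max(abs(a0), 0.1)
        c0 = 1.0 + direction * span / amag
        c0 = max(c0, 1e-3)
        for k in ks:
            for d in shapes:
                starts.append([amag, 1.0 / k, c0, d])
    return starts[: max(n_starts, 2)]


def _power_profile_starts(x, y, direction, n_grid=40, n_keep=4):
    pws = np.geomspace(_SHAPE_LO, _SHAPE_HI, n_grid)
    xp = np.power(x[None, :], pws[:, None])
    xp[:, x <= 0] = 0.0
    n = len(x)
    sx = xp.sum(axis=1)
    sxx = (xp * xp).sum(axis=1)
    sy = y.sum()
    sxy = xp @ y
    det = n * sxx - sx * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (n * sxy - sx * sy) / det
        a = (sy - b * sx) / n
    # wrong-sign slopes collapse to the flat solution under the direction
    # constraint
    bad = (b * direction < 0) | ~np.isfinite(b)
    b[bad] = 0.0
    a[bad] = y.mean()
    resid = a[:, None] + b[:, None] * xp - y[None, :]
    sse = np.einsum("gn,gn->g", resid, resid)
    order = np.argsort(sse)[:n_keep]
    return [(a[i], b[i], pws[i]) for i in order]


def _bounds(model_id, x, direction):
    pos = x[x > 0]
    cmin, cmax = pos.min(), pos.max()
    klo, khi = cmin / 10.0, 10.0 * cmax
    big = np.inf
    if model_id == "hill":
        if direction > 0:
            return ([-big, 0.0, klo, _SHAPE_LO], [big, big, khi, _SHAPE_HI])
        return ([-big, -big, klo, _SHAPE_LO], [big, 0.0, khi, _SHAPE_HI])
    if model_id == "power":
        if direction > 0:
            return ([-big, 0.0, 1.0], [big, big, _SHAPE_HI])
        return ([-big, -big, 1.0], [big, 0.0, _SHAPE_HI])
    if model_id == "exp3":
        return ([1e-8, 1.0 / khi, _SHAPE_LO], [big, 1.0 / klo, _SHAPE_HI])
    if model_id == "exp5":
        if direction > 0:
            clo, chi = 1.0 + 1e-9, big
        else:
            clo, chi = 1e-9, 1.0
        return (
            [1e-8, 1.0 / khi, clo, _SHAPE_LO],
            [big, 1.0 / klo, chi, _SHAPE_HI],
        )
    raise ValueError(model_id)


def _batch_fun_jac(model_id: str, x: np.ndarray, direction: int):
    """Batched model value/Jacobian closures for the LM engine.

    Parameters are row vectors (B, p); x is shared (n,)."""
    x = np.asarray(x, dtype=float)
    pos = x > 0
    logx = np.zeros_like(x)
    logx[pos] = np.log(x[pos])

    if model_id == "hill":

        def fun(p):
            a, b, k, n = p.T
            t = np.power(x[None, :] / k[:, None], n[:, None])
            u = t / (1.0 + t)
            return a[:, None] + b[:, None] * u

        def jac(p):
            a, b, k, n = p.T
            t = np.power(x[None, :] / k[:, None], n[:, None])
            u = t / (1.0 + t)
            uu = u * (1.0 - u)
            lkx = logx[None, :] - np.log(k)[:, None]
            lkx[:, ~pos] = 0.0
            j = np.empty((p.shape[0], len(x), 4))
            j[:, :, 0] = 1.0
            j[:, :, 1] = u
            j[:, :, 2] = -b[:, None] * uu * (n / k)[:, None]
            j[:, :, 3] = b[:, None] * uu * lkx
            return j

        return fun, jac

    if model_id == "power":

        def fun(p):
            a, b, pw = p.T
            xp = np.power(x[None, :], pw[:, None])
            xp[:, ~pos] = 0.0  # x = 0 contributes nothing (pw >= 1)
            return a[:, None] + b[:, None] * xp

        def jac(p):
            a, b, pw = p.T
            xp = np.power(x[None, :], pw[:, None])
            xp[:, ~pos] = 0.0
            j = np.empty((p.shape[0], len(x), 3))
            j[:, :, 0] = 1.0
            j[:, :, 1] = xp
            j[:, :, 2] = b[:, None] * xp * logx[None, :]
            return j

        return fun, jac

    if model_id == "exp3":
        s = float(direction)

        def _z(p):
            _a, b, d = p.T
            z = np.power(b[:, None] * x[None, :], d[:, None])
            return np.clip(z, 0.0, 50.0)

        def fun(p):
            a = p[:, 0]
            return a[:, None] * np.exp(s * _z(p))

        def jac(p):
            a, b, d = p.T
            z = _z(p)
            clipped = z >= 50.0
            ez = np.exp(s * z)
            lbx = logx[None, :] + np.log(b)[:, None]
            lbx[:, ~pos] = 0.0
            dz_db = np.where(clipped, 0.0, d[:, None] * z / b[:, None])
            dz_dd = np.where(clipped, 0.0, z * lbx)
            j = np.empty((p.shape[0], len(x), 3))
            j[:, :, 0] = ez
            j[:, :, 1] = a[:, None] * s * ez * dz_db
            j[:, :, 2] = a[:, None] * s * ez * dz_dd
            return j

        return fun, jac

    if model_id == "exp5":

        def _z(p):
            b, d = p[:, 1], p[:, 3]
            z = np.power(b[:, None] * x[None, :], d[:, None])
            return np.clip(z, 0.0, 50.0)

        def fun(p):
            a, _b, c, _d = p.T
            e = np.exp(-_z(p))
            return a[:, None] * (c[:, None] - (c[:, None] - 1.0) * e)

        def jac(p):
            a, b, c, d = p.T
            z = _z(p)
            clipped = z >= 50.0
            e = np.exp(-z)
            lbx = logx[None, :] + np.log(b)[:, None]
            lbx[:, ~pos] = 0.0
            dz_db = np.where(clipped, 0.0, d[:, None] * z / b[:, None])
            dz_dd = np.where(clipped, 0.0, z * lbx)
            cm1 = (c - 1.0)[:, None]
            j = np.empty((p.shape[0], len(x), 4))
            j[:, :, 0] = c[:, None] - cm1 * e
            j[:, :, 1] = a[:, None] * cm1 * e * dz_db
            j[:, :, 2] = a[:, None] * (1.0 - e)
            j[:, :, 3] = a[:, None] * cm1 * e * dz_dd
            return j

        return fun, jac

    raise ValueError(model_id)


def infer_direction(x: np.ndarray, y: np.ndarray) -> int:
    """Trend direction from the Spearman correlation of group means with
    concentration (+1 on ties)."""
    conc = np.unique(x)
    means = np.array([y[x == c].mean() for c in conc])
    if np.ptp(means) == 0:
        return 1
    rho = stats.spearmanr(conc, means).statistic
    if not np.isfinite(rho) or rho == 0:
        # fall back to endpoint difference
        rho = means[-1] - means[0]
    return 1 if rho >= 0 else -1


def fit_model(
    x: np.ndarray,
    y: np.ndarray,
    model_id: str,
    direction: int | None = None,
    n_starts: int = 6,
    x0: np.ndarray | None = None,
    max_nfev: int = 200,
) -> DoseResponseModelFit:
    """Fit one family by (multi-start) bounded nonlinear least squares.

    ``x0`` short-circuits the multi-start grid (used by the bootstrap,
    which restarts from the original solution).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x[x > 0])) < 4:
        raise ValueError("need >=4 distinct non-control concentrations")
    if direction is None:
        direction = infer_direction(x, y)
    lo, hi = _bounds(model_id, x, direction)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    starts = [x0] if x0 is not None else _starts(model_id, x, y, direction, n_starts)
    p0 = np.clip(
        np.asarray(starts, dtype=float),
        np.where(np.isfinite(lo), lo + 1e-12, lo),
        np.where(np.isfinite(hi), hi - 1e-12, hi),
    )
    fun, jacf = _batch_fun_jac(model_id, x, direction)
    yb = np.broadcast_to(y, (p0.shape[0], len(y)))
    params, sses = lm_fit_batch(
        fun, jacf, yb, p0, lo, hi, max_iter=max(max_nfev // 2, 30)
    )
    ok = np.isfinite(sses)
    n = len(y)
    if not ok.any():
        return DoseResponseModelFit(
            model_id, np.full(len(lo), np.nan), np.nan, -np.inf, np.inf,
            False, direction, len(lo), np.inf, n,
        )
    best = int(np.nanargmin(np.where(ok, sses, np.inf)))
    sse = float(sses[best])
    sigma2 = max(sse / n, 1e-300)
    sigma = math.sqrt(sigma2)
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = len(lo) + 1  # mean params + sigma
    aic = 2 * k - 2 * loglik
    return DoseResponseModelFit(
        model_id, params[best], sigma, loglik, aic, True, direction,
        len(lo), sse, n,
    )


def fit_pvalue(fit: DoseResponseModelFit, x: np.ndarray, y: np.ndarray) -> float:
    """Lack-of-fit F test of the fitted curve against the saturated
    group-means model; large p = adequate fit.

    With no replication (pure-error df = 0) the test is undefined and p is
    reported as 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.unique(x)
    n, g = len(y), len(groups)
    df_pe = n - g
    df_lof = g - fit.n_params
    if df_pe <= 0 or df_lof <= 0:
        return 1.0
    sse_pe = 0.0
    for c in groups:
        yc = y[x == c]
        sse_pe += float(((yc - yc.mean()) ** 2).sum())
    sse_lof = max(fit.sse - sse_pe, 0.0)
    if sse_pe <= 0:
        return 1.0 if sse_lof <= 1e-12 else 0.0
    f_stat = (sse_lof / df_lof) / (sse_pe / df_pe)
    return float(stats.f.sf(f_stat, df_lof, df_pe))


# --------------------------------------------------------------------------
# benchmark concentration
# --------------------------------------------------------------------------


def compute_bmd(fit: DoseResponseModelFit, bmr: float | None = None) -> float:
    """Closed-form BMC: solve |f(BMC) - f(0)| = bmr (default 1 residual SD).

    Returns NaN when the response never reaches the BMR (effect smaller
    than sigma).
    """
    if not fit.converged:
        return np.nan
    bmr = fit.sigma_bmr if bmr is None else bmr
    if bmr <= 0 or not np.isfinite(bmr):
        return np.nan
    p = fit.params
    if fit.model_id == "hill":
        a, b, k, nshape = p
        if abs(b) <= bmr:
            return np.nan
        u = bmr / abs(b)
        return float(k * (u / (1.0 - u)) ** (1.0 / nshape))
    if fit.model_id == "power":
        a, b, pw = p
        if b == 0:
            return np.nan
        return float((bmr / abs(b)) ** (1.0 / pw))
    if fit.model_id == "exp3":
        a, b, d = p
        if a <= 0 or b <= 0:
            return np.nan
        arg = 1.0 + fit.direction * bmr / a
        if arg <= 0:
            return np.nan  # decreasing curve cannot drop below zero
        return float(abs(math.log(arg)) ** (1.0 / d) / b)
    if fit.model_id == "exp5":
        a, b, c, d = p
        if a <= 0 or b <= 0:
            return np.nan
        dmax = abs(a * (c - 1.0))
        if dmax <= bmr:
            return np.nan
        r = bmr / dmax
        return float((-math.log(1.0 - r)) ** (1.0 / d) / b)
    raise ValueError(fit.model_id)


def compute_bmd_numeric(
    fit: DoseResponseModelFit,
    bmr: float | None = None,
    x_hi: float = 1e6,
    rtol: float = 1e-9,
) -> float:
    """Bracketed root-finding BMC, independent of the closed forms."""
    if not fit.converged:
        return np.nan
    bmr = fit.sigma_bmr if bmr is None else bmr
    if bmr <= 0 or not np.isfinite(bmr):
        return np.nan
    f0 = float(fit.predict(0.0))

    def g(xv):
        return fit.direction * (float(fit.predict(xv)) - f0) - bmr

    lo = 1e-12
    if g(x_hi) < 0:
        return np.nan
    try:
        return float(optimize.brentq(g, lo, x_hi, rtol=rtol, maxiter=200))
    except ValueError:
        return np.nan


# --------------------------------------------------------------------------
# model averaging
# --------------------------------------------------------------------------


def _bmd_closed_batch(
    model_id: str, params: np.ndarray, bmr: np.ndarray, direction: int
) -> np.ndarray:
    """Vectorized closed-form BMC over a parameter batch; +inf where the
    benchmark response is unreachable."""
    out = np.full(params.shape[0], np.inf)
    with np.errstate(all="ignore"):
        if model_id == "hill":
            a, b, k, n = params.T
            reach = np.abs(b) > bmr
            u = np.where(reach, bmr / np.abs(b), 0.5)
            out[reach] = (k * (u / (1.0 - u)) ** (1.0 / n))[reach]
        elif model_id == "power":
            a, b, pw = params.T
            reach = np.abs(b) > 0
            out[reach] = ((bmr / np.abs(b)) ** (1.0 / pw))[reach]
        elif model_id == "exp3":
            a, b, d = params.T
            arg = 1.0 + direction * bmr / a
            reach = (arg > 0) & (a > 0) & (b > 0)
            val = np.abs(np.log(arg)) ** (1.0 / d) / b
            out[reach] = val[reach]
        elif model_id == "exp5":
            a, b, c, d = params.T
            dmax = np.abs(a * (c - 1.0))
            reach = (dmax > bmr) & (a > 0) & (b > 0)
            r = np.where(reach, bmr / dmax, 0.5)
            val = (-np.log(1.0 - r)) ** (1.0 / d) / b
            out[reach] = val[reach]
        else:
            raise ValueError(model_id)
    out[~np.isfinite(out) | (out <= 0)] = np.inf
    return out


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    d = aics - np.min(aics)
    w = np.exp(-0.5 * d)
    return w / w.sum()


def model_average(
    fits: list[DoseResponseModelFit],
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 200,
    seed: int | None = 0,
    level: float = 0.90,
    rng: np.random.Generator | None = None,
) -> BMDEstimate:
    """Akaike-weight model averaging with a parametric bootstrap interval.

    Point estimate: weighted geometric mean of per-family BMCs over the
    converged fits with a defined BMC. Interval: each bootstrap replicate
    draws a family by weight, simulates y* = fitted + N(0, sigma), refits
    that family from the original solution, recomputes the BMC; BMDL/BMDU
    are the (1-level)/2 and (1+level)/2 percentiles of the replicates.
    """
    usable = []
    bmds = []
    for f in fits:
        if not f.converged:
            continue
        b = compute_bmd(f)
        if np.isfinite(b) and b > 0:
            usable.append(f)
            bmds.append(b)
    if not usable:
        return BMDEstimate(np.nan, np.nan, np.nan)
    # the constant (no-response) model competes in the averaging: it has no
    # BMC of its own, but the bootstrap mass it attracts turns into +inf
    # replicates, so genes whose data are nearly as consistent with "no
    # response" cannot obtain a tight (BMDU/BMDL) interval
    y = np.asarray(y, dtype=float)
    n_obs = len(y)
    sse_flat = float(((y - y.mean()) ** 2).sum())
    sigma2_flat = max(sse_flat / n_obs, 1e-300)
    aic_flat = 2 * 2 + n_obs * (math.log(2 * math.pi * sigma2_flat) + 1.0)
    aics = np.array([f.aic for f in usable] + [aic_flat])
    w_all = akaike_weights(aics)
    w_effect = w_all[:-1]
    w_flat = float(w_all[-1])
    if w_effect.sum() <= 0:
        return BMDEstimate(np.nan, np.nan, np.nan, weights={"flat": w_flat})
    w = w_effect / w_effect.sum()
    log_bmd = float(np.dot(w, np.log(bmds)))
    bmd = math.exp(log_bmd)
    weights = {f.model_id: float(wi) for f, wi in zip(usable, w_effect)}
    weights["flat"] = w_flat
    if n_boot <= 0:
        return BMDEstimate(bmd, np.nan, np.nan, weights=weights)

    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    boot = np.full(n_boot, np.inf)
    # draw from the full weight vector incl. the constant model, whose
    # replicates have no benchmark concentration and stay at +inf.
    # Separate child streams for model choice and noise give common random
    # numbers across n_boot settings: the first B replicates of a larger
    # run reproduce a smaller run exactly.
    rng_choice, rng_noise = rng.spawn(2)
    choice = rng_choice.choice(len(usable) + 1, size=n_boot, p=w_all)
    noise = rng_noise.standard_normal((n_boot, len(x)))
    for m, f in enumerate(usable):
        rows = np.flatnonzero(choice == m)
        if len(rows) == 0:
            continue
        y_star = f.predict(x)[None, :] + f.sigma_bmr * noise[rows]
        fun, jacf = _batch_fun_jac(f.model_id, x, f.direction)
        lo_b, hi_b = _bounds(f.model_id, x, f.direction)
        p0 = np.broadcast_to(f.params, (len(rows), len(f.params))).copy()
        params, sses = lm_fit_batch(
            fun, jacf, y_star, p0,
            np.asarray(lo_b, dtype=float), np.asarray(hi_b, dtype=float),
            max_iter=40,
        )
        df = max(len(x) - f.n_params, 1)
        bmr_rep = np.sqrt(np.maximum(sses, 0.0) / df)
        boot[rows] = _bmd_closed_batch(f.model_id, params, bmr_rep,
                                       f.direction)
    # replicates whose simulated response never reaches the BMR stay at
    # +inf: they widen the upper bound instead of being silently dropped
    # (dropping them would condition the interval on detectability)
    if np.isfinite(boot).sum() < 10:
        return BMDEstimate(bmd, np.nan, np.nan, weights=weights)
    alpha = (1.0 - level) / 2.0
    log_boot = np.sort(np.log(boot))
    # conservative order statistics (outward rounding); also exact with
    # +inf replicates, where interpolation would be undefined
    lo_q = log_boot[int(np.floor(alpha * (n_boot - 1)))]
    hi_q = log_boot[int(np.ceil((1 - alpha) * (n_boot - 1)))]
    # the percentile interval is clamped to bracket the point estimate
    bmdl = min(math.exp(lo_q), bmd)
    bmdu = max(math.exp(hi_q), bmd) if np.isfinite(hi_q) else math.inf
    return BMDEstimate(bmd, bmdl, bmdu, weights=weights)


# --------------------------------------------------------------------------
# per-gene / per-dataset drivers
# --------------------------------------------------------------------------


def fit_gene(
    gene_id: str,
    x: np.ndarray,
    y: np.ndarray,
    config: BMCConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GeneBMDRecord:
    """Full single-gene analysis: fit all families, lack-of-fit p of the
    best (minimum-AIC) family, model-averaged BMC with bootstrap bounds,
    filter flags."""
    cfg = config or BMCConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    direction = infer_direction(x, y)
    fits = [
        fit_model(x, y, m, direction=direction, n_starts=cfg.n_starts)
        for m in MODEL_IDS
    ]
    converged = [f for f in fits if f.converged]
    if converged:
        best = min(converged, key=lambda f: f.aic)
        p = fit_pvalue(best, x, y)
    else:
        p = 0.0
    est = model_average(
        fits, x, y, n_boot=cfg.n_boot, level=cfg.confidence_level, rng=rng
    )
    ratio_ok = (
        np.isfinite(est.bmdl)
        and np.isfinite(est.bmdu)
        and est.bmdl > 0
        and est.bmdu / est.bmdl <= cfg.max_bmdu_bmdl_ratio
    )
    range_ok = np.isfinite(est.bmd) and est.bmd <= cfg.max_bmc
    return GeneBMDRecord(
        gene_id=gene_id,
        estimate=est,
        fit_p=p,
        pass_fit_p=p > cfg.fit_p_min,
        pass_ratio=bool(ratio_ok),
        pass_range=bool(range_ok),
    )


def fit_dataset(
    ds: ConcentrationResponseDataset,
    config: BMCConfig | None = None,
    seed: int = 0,
) -> list[GeneBMDRecord]:
    """Run the BMC engine over every gene of a dataset (deterministic for a
    given seed; each gene gets an independent substream)."""
    cfg = config or BMCConfig()
    x = ds.sample_concentrations
    values = ds.values.to_numpy(dtype=float)
    records = []
    ss = np.random.SeedSequence(entropy=seed)
    children = ss.spawn(ds.n_genes)
    for i, gene in enumerate(ds.gene_ids):
        rng = np.random.default_rng(children[i])
        records.append(fit_gene(gene, x, values[i], cfg, rng=rng))
    return records


def filter_genes(
    records: list[GeneBMDRecord], max_conc: float | None = None
) -> list[GeneBMDRecord]:
    """Responsive subset: fit p > 0.001, BMDU/BMDL <= 40, BMC <= max_conc.

    ``max_conc`` re-applies the range rule when it differs from the config
    used at fit time.
    """
    out = []
    for r in records:
        ok = r.responsive
        if max_conc is not None:
            ok = (
                r.pass_fit_p
                and r.pass_ratio
                and np.isfinite(r.estimate.bmd)
                and r.estimate.bmd <= max_conc
            )
        if ok:
            out.append(r)
    return out


def rank_genes(records: list[GeneBMDRecord]) -> list[GeneBMDRecord]:
    """All genes ordered by ascending BMDL; genes without a defined BMDL
    rank last (infinite sentinel); ties break lexicographically."""
    return sorted(records, key=lambda r: (r.bmdl_for_ranking, r.gene_id))


def records_to_frame(records: list[GeneBMDRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        e = r.estimate
        rows.append(
            {
                "gene_id": r.gene_id,
                "bmd": e.bmd,
                "bmdl": e.bmdl,
                "bmdu": e.bmdu,
                "fit_p": r.fit_p,
                "pass_fit_p": r.pass_fit_p,
                "pass_ratio": r.pass_ratio,
                "pass_range": r.pass_range,
                "responsive": r.responsive,
                **{f"w_{m}": e.weights.get(m, 0.0) for m in MODEL_IDS},
            }
        )
    return pd.DataFrame(rows)


def accumulation_table(records: list[GeneBMDRecord]) -> pd.DataFrame:
    """Sorted-BMDL vs cumulative gene count (gene-accumulation plot data)."""
    ranked = [r for r in rank_genes(records) if np.isfinite(r.bmdl_for_ranking)]
    return pd.DataFrame(
        {
            "bmdl": [r.estimate.bmdl for r in ranked],
            "cumulative_genes": np.arange(1, len(ranked) + 1),
            "gene_id": [r.gene_id for r in ranked],
        }
    )
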