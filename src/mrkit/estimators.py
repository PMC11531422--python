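"""Causal-effect estimators for two-sample Mendelian randomization.

Every estimator consumes a harmonized table of per-variant exposure and
outcome associations (beta_exp, se_exp, beta_out, se_out) and returns a
causal effect per 1 SD increase in the exposure — on the ln-odds-ratio scale
for binary outcomes, the SD scale for continuous ones.

The estimators are scikit-learn-style classes: construct with tuning
parameters, call :meth:`fit` on a harmonized table, read fitted attributes
(``estimate_``, ``se_``, ``ci_``, ``pvalue_``, ``extras_``), and call
:meth:`result` for a packaged :class:`MRResult`.  Module-level functions
(:func:`ivw`, :func:`egger`, ...) are thin wrappers over the classes.

Methods implemented, ordered roughly by their robustness assumptions:

* inverse-variance weighting (IVW), fixed or multiplicative random effects —
  consistent when all instruments are valid;
* MR-Egger — weighted regression with an intercept estimating the average
  directional pleiotropic effect, consistent under the InSIDE assumption;
* weighted median — consistent when >= 50% of the weight comes from valid
  instruments;
* weighted mode — consistent when the largest group of agreeing instruments
  is valid;
* MR-Lasso — per-variant pleiotropy intercepts under an L1 penalty; variants
  with non-zero intercepts are removed and IVW re-run on the rest;
* MR-RAPS — profile-likelihood estimation with an overdispersion variance
  absorbing systematic (balanced) pleiotropy;
* MR-PRESSO — leave-one-out residual-sum-of-squares global test, per-variant
  outlier test and distortion test, with an outlier-corrected IVW estimate.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .sumstats import HarmonizedRow, usable_frame

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class MRInputError(ValueError):
    """Harmonized input unusable for the requested method."""


class MRConfigError(ValueError):
    """Bad estimator configuration."""


class MRConvergenceError(RuntimeError):
    """Iterative estimator failed to converge."""


@dataclass
class MRResult:
    """A causal-effect estimate from one method."""

    method: str
    n_snp: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    or_estimate: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat mapping matching the results-TSV column layout."""
        ex = self.extras
        return {
            "METHOD": self.method, "NSNP": self.n_snp, "BETA": self.estimate,
            "SE": self.se, "CI_LO": self.ci_low, "CI_HI": self.ci_high,
            "P": self.pvalue, "OR": self.or_estimate,
            "OR_CI_LO": self.or_ci_low, "OR_CI_HI": self.or_ci_high,
            "Q": ex.get("Q"), "I2": ex.get("I2"),
            "EGGER_INTERCEPT": ex.get("intercept"),
            "EGGER_INT_P": ex.get("intercept_p"),
            "EXTRAS_JSON": json.dumps(
                {k: v for k, v in ex.items()
                 if k not in ("Q", "I2", "intercept", "intercept_p")},
                default=_jsonable),
        }


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


@dataclass
class EstimatorConfig:
    """Shared tuning parameters for the estimator battery."""

    re_mode: str = "multiplicative_random"  # or "fixed"
    bootstrap_reps: int = 1000
    mode_bandwidth_factor: float = 1.0
    presso_sims: int = 1000
    presso_outlier_alpha: float = 0.05
    lasso_heterogeneity_quantile: float = 0.95
    raps_overdispersion: bool = True
    seed: int | None = None
    outcome_scale: str = "sd"  # "lnor" populates OR fields

    def __post_init__(self):
        if self.re_mode not in ("fixed", "multiplicative_random"):
            raise MRConfigError(f"unknown re_mode {self.re_mode!r}")
        for name in ("bootstrap_reps", "presso_sims"):
            if getattr(self, name) < 1:
                raise MRConfigError(f"{name} must be >= 1")
        if self.mode_bandwidth_factor <= 0:
            raise MRConfigError("mode_bandwidth_factor must be > 0")

    def method_seed(self, method: str) -> int | None:
        """Stable per-method substream seed derived from the master seed."""
        if self.seed is None:
            return None
        return (int(self.seed) * 2654435761 + zlib.crc32(method.encode())) % (2**31)


# ---------------------------------------------------------------------------
# input handling


def extract_arrays(rows) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """(beta_exp, se_exp, beta_out, se_out, variant_ids) from any rows form.

    Accepts a DataFrame in the harmonized dialect (upper- or lower-case
    column names) or an iterable of :class:`HarmonizedRow`; dropped rows are
    excluded.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows and isinstance(rows[0], HarmonizedRow):
            df = usable_frame(rows)
        else:
            df = pd.DataFrame(rows)
    cols = {c.upper(): c for c in df.columns}
    try:
        bx = df[cols["BETA_EXP"]].to_numpy(float)
        sx = df[cols["SE_EXP"]].to_numpy(float)
        by = df[cols["BETA_OUT"]].to_numpy(float)
        sy = df[cols["SE_OUT"]].to_numpy(float)
    except KeyError as e:
        raise MRInputError(f"harmonized table missing column {e}") from e
    ids = (df[cols["SNP"]].astype(str).tolist()
           if "SNP" in cols else [f"snp{i}" for i in range(len(df))])
    mask = np.isfinite(bx) & np.isfinite(sx) & np.isfinite(by) & np.isfinite(sy)
    if not mask.all():
        bx, sx, by, sy = bx[mask], sx[mask], by[mask], sy[mask]
        ids = [i for i, m in zip(ids, mask) if m]
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise MRInputError("non-positive SE in harmonized table")
    return bx, sx, by, sy, ids


def _require(n: int, minimum: int, method: str) -> None:
    if n < minimum:
        hint = " (use wald_ratio for a single variant)" if minimum == 2 else ""
        raise MRInputError(f"{method} requires >= {minimum} variants, got {n}{hint}")


def _ratio_weights(bx, sy):
    """First-order inverse-variance weights of the Wald ratios."""
    return bx * bx / (sy * sy)


# ---------------------------------------------------------------------------
# Wald ratio


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float,
               se_out: float) -> tuple[float, float]:
    """Per-variant causal estimate beta_out/beta_exp with first-order SE.

    The delta-method SE ``se_out/|beta_exp|`` ignores uncertainty in the
    exposure association (first-order approximation).
    """
    if beta_exp == 0:
        raise MRInputError(
            "beta_exp is 0: the Wald ratio is undefined; exclude the variant")
    return beta_out / beta_exp, se_out / abs(beta_exp)


# ---------------------------------------------------------------------------
# estimator classes


class BaseMREstimator(BaseEstimator):
    """Common fit/result machinery for summary-data MR estimators."""

    method_name: str = "base"
    min_snps: int = 2

    def fit(self, rows, y=None):
        bx, sx, by, sy, ids = extract_arrays(rows)
        _require(len(bx), self.min_snps, self.method_name)
        self.n_snp_ = len(bx)
        self.variant_ids_ = ids
        self.extras_ = {}
        self._fit(bx, sx, by, sy)
        self.ci_ = (self.estimate_ - Z95 * self.se_, self.estimate_ + Z95 * self.se_)
        if not hasattr(self, "pvalue_"):
            self.pvalue_ = float(2 * stats.norm.sf(abs(self.estimate_ / self.se_)))
        return self

    def _fit(self, bx, sx, by, sy):  # pragma: no cover - abstract
        raise NotImplementedError

    def result(self, outcome_scale: str = "sd") -> MRResult:
        res = MRResult(
            method=self.method_name, n_snp=self.n_snp_,
            estimate=float(self.estimate_), se=float(self.se_),
            ci_low=float(self.ci_[0]), ci_high=float(self.ci_[1]),
            pvalue=float(self.pvalue_), extras=dict(self.extras_))
        if outcome_scale == "lnor":
            res.or_estimate = float(np.exp(res.estimate))
            res.or_ci_low = float(np.exp(res.ci_low))
            res.or_ci_high = float(np.exp(res.ci_high))
        return res


def _ivw_core(bx, by, sy):
    """Fixed-effect IVW point estimate, SE, Q and I2."""
    w = _ratio_weights(bx, sy)
    r = by / bx
    sw = w.sum()
    theta = float((w * r).sum() / sw)
    se_fe = float(1.0 / np.sqrt(sw))
    q = float((w * (r - theta) ** 2).sum())
    df = len(bx) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return theta, se_fe, q, i2


class IVWEstimator(BaseMREstimator):
    """Inverse-variance-weighted estimator.

    Weights each Wald ratio by ``beta_exp^2/se_out^2`` (equivalently a
    weighted zero-intercept regression of beta_out on beta_exp with weights
    ``1/se_out^2``).  Under ``re_mode='multiplicative_random'`` — the
    convention for summary-data MR with heterogeneous instruments — the
    fixed-effect SE is inflated by ``max(1, sqrt(Q/(J-1)))``.
    """

    method_name = "ivw"
    min_snps = 2

    def __init__(self, re_mode: str = "multiplicative_random"):
        self.re_mode = re_mode

    def _fit(self, bx, sx, by, sy):
        if self.re_mode not in ("fixed", "multiplicative_random"):
            raise MRConfigError(f"unknown re_mode {self.re_mode!r}")
        theta, se_fe, q, i2 = _ivw_core(bx, by, sy)
        df = len(bx) - 1
        scale = 1.0
        if self.re_mode == "multiplicative_random" and df > 0:
            scale = max(1.0, float(np.sqrt(q / df)))
        self.estimate_ = theta
        self.se_ = se_fe * scale
        self.extras_.update({"Q": q, "Q_df": df,
                             "Q_p": float(stats.chi2.sf(q, df)) if df > 0 else np.nan,
                             "I2": i2, "re_scale": scale,
                             "se_fixed": se_fe, "re_mode": self.re_mode})


class EggerEstimator(BaseMREstimator):
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Rows are first re-oriented so every beta_exp > 0 (the method's sign
    convention); the slope is the causal estimate and the intercept estimates
    the average directional pleiotropic effect.  Inference uses t with J-2
    degrees of freedom and a multiplicative residual dispersion floored at 1.
    """

    method_name = "egger"
    min_snps = 3

    def _fit(self, bx, sx, by, sy):
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        x = bx * flip
        y = by * flip
        w = 1.0 / (sy * sy)
        X = np.column_stack([np.ones_like(x), x])
        XtW = X.T * w
        cov_unit = np.linalg.inv(XtW @ X)
        coef = cov_unit @ (XtW @ y)
        resid = y - X @ coef
        dof = len(x) - 2
        sigma2 = max(1.0, float((w * resid**2).sum() / dof)) if dof > 0 else 1.0
        cov = cov_unit * sigma2
        intercept, slope = coef
        se_int, se_slope = np.sqrt(np.diag(cov))
        self.estimate_ = float(slope)
        self.se_ = float(se_slope)
        self.pvalue_ = float(2 * stats.t.sf(abs(slope / se_slope), dof))
        self.extras_.update({
            "intercept": float(intercept), "intercept_se": float(se_int),
            "intercept_p": float(2 * stats.t.sf(abs(intercept / se_int), dof)),
            "dispersion": sigma2, "df": dof,
        })

    def fit(self, rows, y=None):
        super().fit(rows)
        # Egger CI uses the t quantile consistent with its p-value
        tq = stats.t.ppf(0.975, self.extras_["df"])
        self.ci_ = (self.estimate_ - tq * self.se_, self.estimate_ + tq * self.se_)
        return self


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of normalized cumulative weight.

    With ratios sorted, the cumulative-midpoint positions
    ``p_j = (cumsum(w)_j - w_j/2) / sum(w)`` are interpolated to 0.5; with
    equal weights this reproduces the ordinary interpolated median.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, p, r))


class _BootstrapMixin:
    def _bootstrap_se(self, bx, sx, by, sy, point_fn, reps, seed):
        rng = np.random.default_rng(seed)
        est = np.empty(reps)
        for i in range(reps):
            bxs = rng.normal(bx, sx)
            bys = rng.normal(by, sy)
            est[i] = point_fn(bxs, bys, sy)
        return float(est.std(ddof=1))


class WeightedMedianEstimator(BaseMREstimator, _BootstrapMixin):
    """Weighted median of Wald ratios; valid if >= 50% of weight is valid.

    SE comes from a seeded parametric bootstrap resampling (beta_exp,
    beta_out) from independent normals at their observed values and SEs.
    """

    method_name = "weighted_median"
    min_snps = 3

    def __init__(self, bootstrap_reps: int = 1000, seed: int | None = None):
        self.bootstrap_reps = bootstrap_reps
        self.seed = seed

    @staticmethod
    def _point(bx, by, sy):
        return weighted_median_point(by / bx, _ratio_weights(bx, sy))

    def _fit(self, bx, sx, by, sy):
        self.estimate_ = self._point(bx, by, sy)
        self.se_ = self._bootstrap_se(bx, sx, by, sy, self._point,
                                      self.bootstrap_reps, self.seed)


def weighted_mode_point(ratios: np.ndarray, weights: np.ndarray,
                        bandwidth_factor: float = 1.0,
                        grid_size: int = 512) -> float:
    """Argmax of a Gaussian-kernel weighted density over the Wald ratios.

    Bandwidth is the modified Silverman rule
    ``phi * 0.9 * min(sd, MAD/0.6745) * J^(-1/5)``; the argmax is located on
    a uniform grid spanning the ratio range (padded by 3 bandwidths) and
    refined by bounded scalar maximization around the best grid point.
    Degenerate spread (all ratios identical) returns the common ratio.
    """
    r = np.asarray(ratios, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    sd = r.std(ddof=1) if len(r) > 1 else 0.0
    mad = np.median(np.abs(r - np.median(r))) / 0.6745
    spread = min(sd, mad)
    if spread <= 0:
        # fall back to the other scale estimate, then to exact degeneracy
        spread = max(sd, mad)
    if spread <= 0:
        return float(r[0])
    h = bandwidth_factor * 0.9 * spread * len(r) ** (-0.2)

    def neg_density(x):
        x = np.atleast_1d(x)
        u = (x[:, None] - r[None, :]) / h
        return -(w[None, :] * np.exp(-0.5 * u * u)).sum(axis=1)

    lo, hi = r.min() - 3 * h, r.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = -neg_density(grid)
    k = int(np.argmax(dens))
    a = grid[max(0, k - 1)]
    b = grid[min(grid_size - 1, k + 1)]
    res = optimize.minimize_scalar(lambda x: neg_density(x)[0],
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


class WeightedModeEstimator(BaseMREstimator, _BootstrapMixin):
    """Mode-based estimator: the densest cluster of ratios is taken as valid."""

    method_name = "weighted_mode"
    min_snps = 3

    def __init__(self, bandwidth_factor: float = 1.0,
                 bootstrap_reps: int = 1000, seed: int | None = None):
        self.bandwidth_factor = bandwidth_factor
        self.bootstrap_reps = bootstrap_reps
        self.seed = seed

    def _point(self, bx, by, sy):
        return weighted_mode_point(by / bx, _ratio_weights(bx, sy),
                                   self.bandwidth_factor)

    def _fit(self, bx, sx, by, sy):
        self.estimate_ = self._point(bx, by, sy)
        self.se_ = self._bootstrap_se(bx, sx, by, sy, self._point,
                                      self.bootstrap_reps, self.seed)


class MRLassoEstimator(BaseMREstimator):
    """IVW after removing variants with L1-detected pleiotropy intercepts.

    Fits ``beta_out_j = theta * beta_exp_j + alpha_j`` with outcome-precision
    weights and penalty ``lambda * sum|alpha_j|``.  The penalty has a closed
    per-variant soft-threshold update, so invalid variants get exactly
    non-zero alphas.  Lambda is chosen by walking a decreasing grid from the
    all-retained limit and stopping at the first (largest) value where the
    Cochran Q of the retained variants stays below the configured null
    chi-square quantile; the final estimate is fixed-effect IVW on the
    retained set.
    """

    method_name = "mr_lasso"
    min_snps = 3

    def __init__(self, heterogeneity_quantile: float = 0.95,
                 n_lambda: int = 60):
        self.heterogeneity_quantile = heterogeneity_quantile
        self.n_lambda = n_lambda

    @staticmethod
    def _fit_at_lambda(bx, by, w, lam, theta0, tol=1e-12, max_iter=1000):
        theta = theta0
        alpha = np.zeros_like(bx)
        for _ in range(max_iter):
            resid = by - theta * bx
            # soft-threshold per-variant intercepts
            thr = lam / (2.0 * w)
            alpha_new = np.sign(resid) * np.maximum(np.abs(resid) - thr, 0.0)
            yadj = by - alpha_new
            theta_new = float((w * bx * yadj).sum() / (w * bx * bx).sum())
            if abs(theta_new - theta) + np.abs(alpha_new - alpha).max() < tol:
                theta, alpha = theta_new, alpha_new
                break
            theta, alpha = theta_new, alpha_new
        return theta, alpha

    def _fit(self, bx, sx, by, sy):
        w = 1.0 / (sy * sy)
        theta_ivw, _, _, _ = _ivw_core(bx, by, sy)
        resid0 = by - theta_ivw * bx
        lam_max = 2.0 * float(np.max(w * np.abs(resid0))) * 1.05 + 1e-12
        lambdas = np.geomspace(lam_max, lam_max * 1e-4, self.n_lambda)
        chosen = None
        for lam in lambdas:
            theta, alpha = self._fit_at_lambda(bx, by, w, lam, theta_ivw)
            keep = alpha == 0.0
            if keep.sum() < 2:
                continue
            kb, kby, ksy = bx[keep], by[keep], sy[keep]
            theta_k, se_k, q_k, _ = _ivw_core(kb, kby, ksy)
            dfk = keep.sum() - 1
            if q_k <= stats.chi2.ppf(self.heterogeneity_quantile, dfk):
                chosen = (lam, keep, theta_k, se_k, q_k)
                break
        if chosen is None:
            # even the loosest penalty keeps a heterogeneous core: report the
            # smallest-lambda solution with >= 2 retained variants
            for lam in lambdas[::-1]:
                theta, alpha = self._fit_at_lambda(bx, by, w, lam, theta_ivw)
                keep = alpha == 0.0
                if keep.sum() >= 2:
                    kb, kby, ksy = bx[keep], by[keep], sy[keep]
                    theta_k, se_k, q_k, _ = _ivw_core(kb, kby, ksy)
                    chosen = (lam, keep, theta_k, se_k, q_k)
                    break
        if chosen is None:
            raise MRInputError(
                "mr_lasso: fewer than 2 variants retained along the entire "
                f"penalty path (lambda {lambdas[-1]:.3g}..{lambdas[0]:.3g})")
        lam, keep, theta_k, se_k, q_k = chosen
        self.estimate_ = theta_k
        self.se_ = se_k
        self.extras_.update({
            "lambda": float(lam),
            "retained": [i for i, k in zip(self.variant_ids_, keep) if k],
            "removed": [i for i, k in zip(self.variant_ids_, keep) if not k],
            "n_retained": int(keep.sum()), "Q_retained": q_k,
        })


class MRRapsEstimator(BaseMREstimator):
    """Robust adjusted profile score estimator.

    Model: beta_out_j ~ N(theta*gamma_j, se_out_j^2 + tau^2) and
    beta_exp_j ~ N(gamma_j, se_exp_j^2) with the true instrument effects
    gamma_j profiled out, leaving the marginal
    ``beta_out_j - theta*beta_exp_j ~ N(0, V_j)`` with
    ``V_j = se_out_j^2 + tau^2 + theta^2 se_exp_j^2``.  theta and the
    overdispersion tau^2 >= 0 (systematic pleiotropy variance) solve the two
    profile estimating equations, iterated from the IVW start; the SE is the
    sandwich variance of the theta-score.
    """

    method_name = "mr_raps"
    min_snps = 3

    def __init__(self, overdispersion: bool = True, tol: float = 1e-8,
                 max_iter: int = 200):
        self.overdispersion = overdispersion
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _theta_score(theta, tau2, bx, sx, by, sy):
        r = by - theta * bx
        V = sy * sy + tau2 + theta * theta * sx * sx
        return ((bx * r) / V + theta * sx * sx * (r * r / (V * V) - 1.0 / V)).sum()

    @staticmethod
    def _tau2_score(tau2, theta, bx, sx, by, sy):
        r = by - theta * bx
        V = sy * sy + tau2 + theta * theta * sx * sx
        return ((r * r - V) / (V * V)).sum()

    def _solve_theta(self, tau2, bx, sx, by, sy, theta0):
        f = lambda t: self._theta_score(t, tau2, bx, sx, by, sy)
        # bracket around the current value, widening as needed
        width = 10.0 * max(abs(theta0), 0.1)
        for _ in range(60):
            lo, hi = theta0 - width, theta0 + width
            if f(lo) * f(hi) < 0:
                return float(optimize.brentq(f, lo, hi, xtol=1e-12))
            width *= 2.0
        raise MRConvergenceError("mr_raps: could not bracket the theta score root")

    def _solve_tau2(self, theta, bx, sx, by, sy):
        g = lambda t2: self._tau2_score(t2, theta, bx, sx, by, sy)
        if g(0.0) <= 0:
            return 0.0
        hi = float((by * by).max() + 1.0)
        for _ in range(60):
            if g(hi) < 0:
                return float(optimize.brentq(g, 0.0, hi, xtol=1e-14))
            hi *= 4.0
        raise MRConvergenceError("mr_raps: could not bracket the tau2 score root")

    def _fit(self, bx, sx, by, sy):
        theta, _, _, _ = _ivw_core(bx, by, sy)
        tau2 = 0.0
        trace = []
        for it in range(self.max_iter):
            theta_new = self._solve_theta(tau2, bx, sx, by, sy, theta)
            tau2_new = (self._solve_tau2(theta_new, bx, sx, by, sy)
                        if self.overdispersion else 0.0)
            delta = abs(theta_new - theta) + abs(tau2_new - tau2)
            trace.append((it, theta_new, tau2_new, delta))
            theta, tau2 = theta_new, tau2_new
            if delta < self.tol:
                break
        else:
            tail = "; ".join(f"it{t[0]}: theta={t[1]:.6g} tau2={t[2]:.3g} "
                             f"d={t[3]:.3g}" for t in trace[-3:])
            raise MRConvergenceError(
                f"mr_raps did not converge in {self.max_iter} iterations ({tail})")
        # sandwich variance of the theta estimating equation
        eps = 1e-6 * max(abs(theta), 1.0)
        r = by - theta * bx
        V = sy * sy + tau2 + theta * theta * sx * sx
        psi = (bx * r) / V + theta * sx * sx * (r * r / (V * V) - 1.0 / V)
        d_psi = (self._theta_score(theta + eps, tau2, bx, sx, by, sy)
                 - self._theta_score(theta - eps, tau2, bx, sx, by, sy)) / (2 * eps)
        B = float((psi * psi).sum())
        A = float(d_psi)
        self.estimate_ = float(theta)
        self.se_ = float(np.sqrt(B / (A * A)))
        self.extras_.update({"tau2": float(tau2), "iterations": len(trace),
                             "overdispersion": self.overdispersion})


class MRPressoEstimator(BaseMREstimator):
    """MR-PRESSO: pleiotropy residual sum and outlier test.

    With leave-one-out IVW estimates theta_{-j} and ratio weights w_j, the
    observed global statistic is ``RSS = sum_j w_j (beta_out_j -
    theta_{-j} beta_exp_j)^2``.  Its null distribution — and each variant's
    residual-term distribution — comes from parametric simulations drawing
    beta_exp_j* ~ N(beta_exp_j, se_exp_j) and
    beta_out_j* ~ N(theta_{-j} beta_exp_j, se_out_j).  Variants whose
    Bonferroni-corrected simulated residual p falls below ``outlier_alpha``
    are outliers; the returned estimate is IVW with outliers removed (raw IVW
    if none), and a distortion p compares the with/without-outlier estimate
    difference against its simulated distribution.
    """

    method_name = "mr_presso"
    min_snps = 4

    def __init__(self, n_sims: int = 1000, outlier_alpha: float = 0.05,
                 seed: int | None = None, re_mode: str = "multiplicative_random"):
        self.n_sims = n_sims
        self.outlier_alpha = outlier_alpha
        self.seed = seed
        self.re_mode = re_mode

    @staticmethod
    def _loo_theta(bx, by, sy):
        w = _ratio_weights(bx, sy)
        r = by / bx
        sw, swr = w.sum(), (w * r).sum()
        return (swr - w * r) / (sw - w)

    def _fit(self, bx, sx, by, sy):
        rng = np.random.default_rng(self.seed)
        J = len(bx)
        w = _ratio_weights(bx, sy)
        theta_loo = self._loo_theta(bx, by, sy)
        obs_terms = w * (by - theta_loo * bx) ** 2
        rss_obs = float(obs_terms.sum())

        S = self.n_sims
        bx_s = rng.normal(bx, sx, size=(S, J))
        by_s = rng.normal(theta_loo * bx, sy, size=(S, J))
        w_s = bx_s * bx_s / (sy * sy)
        r_s = by_s / bx_s
        sw_s = w_s.sum(axis=1, keepdims=True)
        swr_s = (w_s * r_s).sum(axis=1, keepdims=True)
        theta_loo_s = (swr_s - w_s * r_s) / (sw_s - w_s)
        terms_s = w_s * (by_s - theta_loo_s * bx_s) ** 2
        rss_s = terms_s.sum(axis=1)

        global_p = float((1 + (rss_s >= rss_obs).sum()) / (S + 1))
        pvar = (1 + (terms_s >= obs_terms[None, :]).sum(axis=0)) / (S + 1)
        pvar_bonf = np.minimum(1.0, pvar * J)
        outliers = pvar_bonf < self.outlier_alpha
        if outliers.all():
            raise MRInputError("mr_presso: every variant flagged as an outlier")

        ivw_all = IVWEstimator(re_mode=self.re_mode).fit(pd.DataFrame({
            "BETA_EXP": bx, "SE_EXP": sx, "BETA_OUT": by, "SE_OUT": sy,
            "SNP": self.variant_ids_}))
        extras = {"global_rss": rss_obs, "global_p": global_p,
                  "outlier_p_bonferroni": dict(zip(self.variant_ids_,
                                                   pvar_bonf.tolist())),
                  "outliers": [i for i, o in zip(self.variant_ids_, outliers) if o]}
        if outliers.any():
            keep = ~outliers
            ivw_corr = IVWEstimator(re_mode=self.re_mode).fit(pd.DataFrame({
                "BETA_EXP": bx[keep], "SE_EXP": sx[keep],
                "BETA_OUT": by[keep], "SE_OUT": sy[keep],
                "SNP": [i for i, k in zip(self.variant_ids_, keep) if k]}))
            # distortion: observed estimate shift vs its simulated distribution
            d_obs = ivw_all.estimate_ - ivw_corr.estimate_
            theta_all_s = (w_s * r_s).sum(axis=1) / w_s.sum(axis=1)
            wk, rk = w_s[:, keep], r_s[:, keep]
            theta_keep_s = (wk * rk).sum(axis=1) / wk.sum(axis=1)
            d_s = theta_all_s - theta_keep_s
            d_s = d_s - d_s.mean()
            distortion_p = float((1 + (np.abs(d_s) >= abs(d_obs)).sum()) / (S + 1))
            extras.update({"distortion": float(d_obs),
                           "distortion_p": distortion_p,
                           "n_outliers": int(outliers.sum())})
            chosen = ivw_corr
        else:
            extras["n_outliers"] = 0
            chosen = ivw_all
        self.estimate_ = chosen.estimate_
        self.se_ = chosen.se_
        self.pvalue_ = chosen.pvalue_
        extras["Q"] = chosen.extras_["Q"]
        extras["I2"] = chosen.extras_["I2"]
        self.extras_.update(extras)
        self.n_snp_ = chosen.n_snp_


# ---------------------------------------------------------------------------
# functional wrappers


def _cfg(config: EstimatorConfig | None) -> EstimatorConfig:
    return config if config is not None else EstimatorConfig()


def ivw(rows, config: EstimatorConfig | None = None) -> MRResult:
    c = _cfg(config)
    return IVWEstimator(re_mode=c.re_mode).fit(rows).result(c.outcome_scale)


def egger(rows, config: EstimatorConfig | None = None) -> MRResult:
    c = _cfg(config)
    return EggerEstimator().fit(rows).result(c.outcome_scale)


def weighted_median(rows, config: EstimatorConfig | None = None) -> MRResult:
    c = _cfg(config)
    est = WeightedMedianEstimator(bootstrap_reps=c.bootstrap_reps,
                                  seed=c.method_seed("weighted_median"))
    return est.fit(rows).result(c.outcome_scale)


def weighted_mode(rows, config: EstimatorConfig | None = None) -> MRResult:
    c = _cfg(config)
    est = WeightedModeEstimator(bandwidth_factor=c.mode_bandwidth_factor,
                                bootstrap_reps=c.bootstrap_reps,
                                seed=c.method_seed("weighted_mode"))
    return est.fit(rows).result(c.outcome_scale)


def mr_lasso(rows, config: EstimatorConfig | None = None) -> MRResult:
    c = _cfg(config)
    est = MRLassoEstimator(heterogeneity_quantile=c.lasso_heterogeneity_quantile)
    return est.fit(rows).result(c.outcome_scale)


def mr_raps(rows, config: EstimatorConfig | None = None) -> MRResult:
    c = _cfg(config)
    est = MRRapsEstimator(overdispersion=c.raps_overdispersion)
    return est.fit(rows).result(c.outcome_scale)


def mr_presso(rows, config: EstimatorConfig | None = None) -> MRResult:
    c = _cfg(config)
    est = MRPressoEstimator(n_sims=c.presso_sims,
                            outlier_alpha=c.presso_outlier_alpha,
                            seed=c.method_seed("mr_presso"), re_mode=c.re_mode)
    return est.fit(rows).result(c.outcome_scale)


METHODS = {
    "ivw": ivw,
    "egger": egger,
    "weighted_median": weighted_median,
    "weighted_mode": weighted_mode,
    "mr_lasso": mr_lasso,
    "mr_raps": mr_raps,
    "mr_presso": mr_presso,
}


def run_battery(rows, config: EstimatorConfig | None = None,
                methods: Sequence[str] = tuple(METHODS)) -> list[MRResult]:
    """Run a requested set of methods on one harmonized table.

    Output order matches the request.  A method that raises is captured as an
    MRResult with NaN fields and the error message in ``extras['error']``;
    an unknown method name is a configuration error and aborts the battery.
    """
    c = _cfg(config)
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise MRConfigError(
            f"unknown method(s) {unknown}; available: {sorted(METHODS)}")
    results = []
    for m in methods:
        try:
            results.append(METHODS[m](rows, c))
        except (MRInputError, MRConvergenceError) as e:
            results.append(MRResult(
                method=m, n_snp=0, estimate=float("nan"), se=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"), pvalue=float("nan"),
                extras={"error": str(e)}))
    return results


def results_frame(results: Iterable[MRResult]) -> pd.DataFrame:
    """Results as the documented one-row-per-method TSV layout."""
    return pd.DataFrame([r.to_row() for r in results])
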