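"""Causal-effect estimators for two-sample Mendelian randomization.

Each estimator combines per-SNP exposure effects ``gamma_hat`` (s.e.
``sigma_x``) and outcome effects ``Gamma_hat`` (s.e. ``sigma_y``) into an
estimate of the causal effect theta of exposure on outcome on the log-odds
scale.  Implemented methods:

* Wald ratio — single-SNP estimate Gamma_hat / gamma_hat.
* IVW — inverse-variance-weighted mean of Wald ratios (fixed or
  multiplicative random effects).
* MR-Egger — weighted regression with an intercept; the intercept estimates
  directional pleiotropy, the slope the causal effect.
* Weighted median — consistent when instruments carrying at least half the
  weight are valid; bootstrap standard error.
* Maximum likelihood — joint normal likelihood over theta and the true
  per-SNP exposure effects, profiled to a one-dimensional likelihood.
* RAPS — robust adjusted profile score, consistent under weak instruments;
  optional overdispersion and Huber loss.
* BWMR — Bayesian hierarchical model with per-instrument inlier weights
  that down-weight outlying (pleiotropic) instruments.

All methods report exact two-sided p-values against the normal reference,
and a 95% confidence interval on the odds-ratio scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
import statsmodels.api as sm

from .harmonize import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "EstimationError",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "max_likelihood",
    "raps",
    "bwmr",
    "all_estimates",
]

_Z975 = stats.norm.ppf(0.975)


class EstimationError(RuntimeError):
    """An estimator failed to converge; carries diagnostic details."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect result on the log-odds scale with OR-scale CI."""

    method: str
    beta: float
    se: float
    pval: float
    or_point: float
    ci_low: float
    ci_high: float
    n_snps: int
    extra: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snps: int, **extra) -> "MREstimate":
        z = beta / se if se > 0 else math.inf * np.sign(beta)
        pval = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 0.0
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            pval=float(pval),
            or_point=float(np.exp(beta)),
            ci_low=float(np.exp(beta - _Z975 * se)),
            ci_high=float(np.exp(beta + _Z975 * se)),
            n_snps=n_snps,
            extra=extra,
        )


def _arrays(insts: Sequence[HarmonizedInstrument]):
    g = np.array([i.gamma_hat for i in insts], dtype=float)
    sx = np.array([i.sigma_x for i in insts], dtype=float)
    G = np.array([i.Gamma_hat for i in insts], dtype=float)
    sy = np.array([i.sigma_y for i in insts], dtype=float)
    return g, sx, G, sy


def _wald_weights(g, sx, G, sy, order: str = "first"):
    """Inverse-variance weights of the per-SNP Wald ratios.

    First-order weights use the outcome variance only (se_j = sigma_y /
    |gamma_hat|); second-order weights add the delta-method term from the
    exposure-side noise.
    """
    if order == "first":
        var = sy**2 / g**2
    elif order == "second":
        var = sy**2 / g**2 + G**2 * sx**2 / g**4
    else:
        raise ValueError(f"unknown weight order {order!r}")
    return 1.0 / var


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate Gamma_hat / gamma_hat.

    The default standard error is first order, sigma_y / |gamma_hat|; with
    ``second_order`` the delta-method expansion adds the exposure-noise term
    Gamma_hat^2 sigma_x^2 / gamma_hat^4.
    """
    if inst.gamma_hat == 0:
        raise EstimationError(f"{inst.snp_id}: zero exposure effect")
    beta = inst.Gamma_hat / inst.gamma_hat
    var = inst.sigma_y**2 / inst.gamma_hat**2
    if second_order:
        var += inst.Gamma_hat**2 * inst.sigma_x**2 / inst.gamma_hat**4
    return MREstimate.from_beta_se("wald", beta, math.sqrt(var), 1, snp_id=inst.snp_id)


def ivw(
    insts: Sequence[HarmonizedInstrument],
    effects_model: str = "multiplicative_random",
    weights: str = "first",
) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``effects_model='fixed'`` uses se = (sum of weights)^(-1/2);
    ``'multiplicative_random'`` (default) multiplies it by
    max(1, sqrt(Q / (J - 1))), inflating the error under heterogeneity and
    never deflating it.
    """
    if len(insts) < 2:
        raise EstimationError("IVW needs at least 2 instruments")
    g, sx, G, sy = _arrays(insts)
    w = _wald_weights(g, sx, G, sy, weights)
    ratios = G / g
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - beta) ** 2))
    if effects_model == "fixed":
        se = se_fixed
    elif effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, math.sqrt(q / (len(insts) - 1)))
    else:
        raise ValueError(f"unknown effects model {effects_model!r}")
    return MREstimate.from_beta_se("ivw", beta, se, len(insts), q_stat=q)


def egger(insts: Sequence[HarmonizedInstrument]) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: weighted fit of Gamma_hat on gamma_hat with an
    intercept, weights 1/sigma_y^2, after re-orienting every instrument so
    gamma_hat >= 0.

    Returns ``(slope, intercept)`` estimates.  The slope is the causal
    estimate; a non-zero intercept indicates directional pleiotropy
    (requires pleiotropic effects independent of instrument strength).
    Standard errors from the weighted fit are scaled by max(1, residual
    scale) so heterogeneity never shrinks them.
    """
    if len(insts) < 3:
        raise EstimationError("MR-Egger needs at least 3 instruments")
    g, sx, G, sy = _arrays(insts)
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    w = 1.0 / sy**2
    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=w).fit()
    scale = math.sqrt(fit.scale)  # residual scale of the weighted fit
    adj = max(1.0, scale) / scale
    intercept_se, slope_se = fit.bse * adj
    intercept, slope = fit.params
    return (
        MREstimate.from_beta_se("egger_slope", slope, slope_se, len(insts)),
        MREstimate.from_beta_se("egger_intercept", intercept, intercept_se, len(insts)),
    )


def _weighted_median_core(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    ratios, weights = ratios[order], weights[order]
    weights = weights / weights.sum()
    cum = np.cumsum(weights) - 0.5 * weights
    if cum[0] >= 0.5:
        return float(ratios[0])
    if cum[-1] <= 0.5:
        return float(ratios[-1])
    return float(np.interp(0.5, cum, ratios))


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 20240715,
) -> MREstimate:
    """Weighted median of the Wald ratios.

    Consistent when instruments carrying at least 50% of the inverse-variance
    weight are valid.  The estimate interpolates the ratio at cumulative
    weight 0.5 (weights centered by half their own mass); the standard error
    comes from a parametric bootstrap resampling gamma_hat and Gamma_hat
    from their sampling distributions.
    """
    if len(insts) < 3:
        raise EstimationError("weighted median needs at least 3 instruments")
    g, sx, G, sy = _arrays(insts)
    w = _wald_weights(g, sx, G, sy)
    beta = _weighted_median_core(G / g, w)

    rng = np.random.default_rng(seed)
    g_star = rng.normal(g, sx, size=(n_boot, len(insts)))
    G_star = rng.normal(G, sy, size=(n_boot, len(insts)))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        gb = g_star[b]
        if np.any(gb == 0):
            gb = np.where(gb == 0, np.finfo(float).tiny, gb)
        boot[b] = _weighted_median_core(G_star[b] / gb, gb**2 / sy**2)
    se = float(np.std(boot, ddof=1))
    return MREstimate.from_beta_se(
        "weighted_median", beta, se, len(insts), n_boot=n_boot, seed=seed
    )


def _profile_loglik(theta: float, g, sx, G, sy) -> float:
    # per-SNP true exposure effects profiled out in closed form
    var = sy**2 + theta**2 * sx**2
    return float(-0.5 * np.sum((G - theta * g) ** 2 / var))


def max_likelihood(insts: Sequence[HarmonizedInstrument]) -> MREstimate:
    """Maximum-likelihood causal estimate.

    The joint model is gamma_hat_j ~ N(gamma_j, sigma_x^2) and
    Gamma_hat_j ~ N(theta gamma_j, sigma_y^2); maximizing over the nuisance
    gamma_j gives the profile log-likelihood
    -1/2 sum (Gamma_hat_j - theta gamma_hat_j)^2 / (sigma_y^2 + theta^2 sigma_x^2),
    which is maximized numerically.  The standard error comes from the
    curvature of the profile likelihood at the optimum.  As sigma_x -> 0
    this reduces to fixed-effect IVW.
    """
    if len(insts) < 2:
        raise EstimationError("maximum likelihood needs at least 2 instruments")
    g, sx, G, sy = _arrays(insts)
    start = float(np.sum(g * G / sy**2) / np.sum(g**2 / sy**2))
    res = optimize.minimize_scalar(
        lambda t: -_profile_loglik(t, g, sx, G, sy),
        bracket=(start - 1.0, start, start + 1.0),
        method="brent",
        options={"xtol": 1e-10},
    )
    if not res.success:
        raise EstimationError("likelihood maximization did not converge", {"result": res})
    theta = float(res.x)
    h = 1e-5 * max(1.0, abs(theta))
    curv = -(
        _profile_loglik(theta + h, g, sx, G, sy)
        - 2.0 * _profile_loglik(theta, g, sx, G, sy)
        + _profile_loglik(theta - h, g, sx, G, sy)
    ) / h**2
    if curv <= 0:
        raise EstimationError(
            "non-positive observed information at the optimum",
            {"theta": theta, "curvature": curv},
        )
    return MREstimate.from_beta_se("max_likelihood", theta, curv**-0.5, len(insts))


_HUBER_K = 1.345
# E[psi(Z)^2] for standard-normal Z, used in the sandwich variance
_HUBER_C = float(
    stats.norm.cdf(_HUBER_K)
    - stats.norm.cdf(-_HUBER_K)
    - 2.0 * _HUBER_K * stats.norm.pdf(_HUBER_K)
    + 2.0 * _HUBER_K**2 * stats.norm.sf(_HUBER_K)
)


def _raps_score(theta: float, tau2: float, g, sx, G, sy, loss: str) -> float:
    s2 = sy**2 + theta**2 * sx**2 + tau2
    s = np.sqrt(s2)
    t = (G - theta * g) / s
    dt = -g / s - t * theta * sx**2 / s2
    psi = t if loss == "squared" else np.clip(t, -_HUBER_K, _HUBER_K)
    return float(np.sum(psi * dt))


def raps(
    insts: Sequence[HarmonizedInstrument],
    overdispersion: Optional[bool] = None,
    loss: str = "squared",
) -> MREstimate:
    """Robust adjusted profile score estimator.

    Solves the profile-score equation sum psi(t_j) dt_j/dtheta = 0 with
    t_j = (Gamma_hat_j - theta gamma_hat_j) / sqrt(sigma_y^2 + theta^2
    sigma_x^2 + tau^2).  Because the exposure-side noise enters the
    denominator, the estimator stays consistent under weak instruments where
    naive IVW attenuates.  With ``overdispersion`` (default: enabled for
    >= 10 instruments) a systematic-pleiotropy variance tau^2 is estimated
    jointly from the second-moment equation mean(t_j^2) = 1; ``loss='huber'``
    bounds each instrument's influence.
    """
    if len(insts) < 3:
        raise EstimationError("RAPS needs at least 3 instruments")
    if loss not in ("squared", "huber"):
        raise ValueError(f"unknown loss {loss!r}")
    if overdispersion is None:
        overdispersion = len(insts) >= 10
    g, sx, G, sy = _arrays(insts)

    def solve_theta(tau2: float, start: float) -> float:
        span = 1.0
        lo, hi = start - span, start + span
        f_lo = _raps_score(lo, tau2, g, sx, G, sy, loss)
        f_hi = _raps_score(hi, tau2, g, sx, G, sy, loss)
        for _ in range(40):
            if f_lo * f_hi <= 0:
                break
            span *= 2.0
            lo, hi = start - span, start + span
            f_lo = _raps_score(lo, tau2, g, sx, G, sy, loss)
            f_hi = _raps_score(hi, tau2, g, sx, G, sy, loss)
        else:
            raise EstimationError(
                "no sign change for the profile score in the search bracket",
                {"bracket": (lo, hi), "score": (f_lo, f_hi)},
            )
        return float(optimize.brentq(
            lambda t: _raps_score(t, tau2, g, sx, G, sy, loss), lo, hi, xtol=1e-12
        ))

    theta = solve_theta(0.0, float(np.sum(g * G / sy**2) / np.sum(g**2 / sy**2)))
    tau2 = 0.0
    if overdispersion:
        for _ in range(50):
            # Solve mean((G - theta g)^2 / (base + tau2)) = 1 for tau2 >= 0
            resid2 = (G - theta * g) ** 2
            base = sy**2 + theta**2 * sx**2
            if np.mean(resid2 / base) <= 1.0:
                tau2_new = 0.0
            else:
                tau2_new = float(optimize.brentq(
                    lambda v: np.mean(resid2 / (base + v)) - 1.0,
                    0.0,
                    float(np.max(resid2)) + 1.0,
                ))
            theta_new = solve_theta(tau2_new, theta)
            if abs(theta_new - theta) < 1e-10 and abs(tau2_new - tau2) < 1e-12:
                theta, tau2 = theta_new, tau2_new
                break
            theta, tau2 = theta_new, tau2_new

    # sandwich variance: Var(theta) = B / A^2 with A the score slope
    h = 1e-5 * max(1.0, abs(theta))
    a = (
        _raps_score(theta + h, tau2, g, sx, G, sy, loss)
        - _raps_score(theta - h, tau2, g, sx, G, sy, loss)
    ) / (2.0 * h)
    s2 = sy**2 + theta**2 * sx**2 + tau2
    dt = -g / np.sqrt(s2) - ((G - theta * g) / s2) * theta * sx**2 / np.sqrt(s2)
    c_psi = 1.0 if loss == "squared" else _HUBER_C
    b = c_psi * float(np.sum(dt**2))
    if a == 0:
        raise EstimationError("flat profile score; cannot form a standard error")
    se = math.sqrt(b) / abs(a)
    return MREstimate.from_beta_se(
        "raps", theta, se, len(insts), tau2=tau2, overdispersion=overdispersion, loss=loss
    )


def _bwmr_negloglik(params, g, sx, G, sy, w):
    theta, log_tau2, log_s02 = params
    tau2, s02 = math.exp(log_tau2), math.exp(log_s02)
    v11 = s02 + sx**2
    v22 = theta**2 * s02 + sy**2 + tau2
    v12 = theta * s02
    det = v11 * v22 - v12**2
    if np.any(det <= 0):
        return np.inf
    quad = (v22 * g**2 - 2.0 * v12 * g * G + v11 * G**2) / det
    return float(np.sum(w * (0.5 * np.log(det) + 0.5 * quad)))


def bwmr(
    insts: Sequence[HarmonizedInstrument],
    max_iter: int = 100,
    tol: float = 1e-8,
    outlier_var_ratio: float = 10.0,
    inlier_prob: float = 0.99,
    seed: int = 20240715,
) -> MREstimate:
    """Bayesian-weighted causal estimate with outlier down-weighting.

    Hierarchical model: gamma_hat_j ~ N(gamma_j, sigma_x^2),
    Gamma_hat_j ~ N(theta gamma_j, sigma_y^2 + tau^2), gamma_j ~ N(0,
    sigma_0^2).  Marginally each (gamma_hat_j, Gamma_hat_j) is bivariate
    normal, and (theta, tau^2, sigma_0^2) are fitted by an
    expectation-maximization loop in which each instrument carries a weight
    equal to the posterior probability of belonging to the inlier component
    of a two-component scale mixture on its standardized residual (outlier
    component variance ``outlier_var_ratio`` times the inlier's, prior
    inlier probability ``inlier_prob``).  The reported effect is the
    posterior mode of theta with a standard error from the curvature of the
    weighted log-likelihood at convergence; the final per-instrument weights
    are returned in ``extra['weights']``.
    """
    if len(insts) < 3:
        raise EstimationError("BWMR needs at least 3 instruments")
    g, sx, G, sy = _arrays(insts)
    J = len(insts)
    w = np.ones(J)
    theta = float(np.sum(g * G / sy**2) / np.sum(g**2 / sy**2))
    # seed only drives the jittered restart used if the first EM pass stalls
    rng = np.random.default_rng(seed)
    params = np.array([theta, math.log(1e-6), math.log(max(float(np.var(g)), 1e-6))])
    trace = []
    converged = False
    iteration = 0
    restarts = 0
    while iteration < max_iter:
        res = optimize.minimize(
            _bwmr_negloglik,
            params,
            args=(g, sx, G, sy, w),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 2000},
        )
        new_params = res.x
        theta_new, tau2, s02 = new_params[0], math.exp(new_params[1]), math.exp(new_params[2])
        # standardized residuals of the outcome equation
        s2 = sy**2 + tau2 + theta_new**2 * sx**2
        r = (G - theta_new * g) / np.sqrt(s2)
        dens_in = stats.norm.pdf(r, scale=1.0)
        dens_out = stats.norm.pdf(r, scale=math.sqrt(outlier_var_ratio))
        w_new = inlier_prob * dens_in / (inlier_prob * dens_in + (1.0 - inlier_prob) * dens_out)
        shift = abs(theta_new - params[0]) + float(np.max(np.abs(w_new - w)))
        trace.append({"iter": iteration, "theta": float(theta_new), "shift": float(shift)})
        params, w = new_params, w_new
        if shift < tol:
            converged = True
            break
        if not res.success and restarts < 3:
            params = params + rng.normal(0.0, 0.1, size=3)
            restarts += 1
        iteration += 1
    if not converged:
        raise EstimationError(
            f"BWMR did not converge in {max_iter} iterations", {"trace": trace}
        )
    theta = float(params[0])
    h = 1e-4 * max(1.0, abs(theta))
    f0 = _bwmr_negloglik(params, g, sx, G, sy, w)
    fp = _bwmr_negloglik(params + np.array([h, 0, 0]), g, sx, G, sy, w)
    fm = _bwmr_negloglik(params - np.array([h, 0, 0]), g, sx, G, sy, w)
    curv = (fp - 2.0 * f0 + fm) / h**2
    if curv <= 0:
        raise EstimationError("non-positive curvature at the BWMR optimum", {"trace": trace})
    return MREstimate.from_beta_se(
        "bwmr",
        theta,
        curv**-0.5,
        J,
        weights=[float(x) for x in w],
        tau2=float(math.exp(params[1])),
        sigma0_sq=float(math.exp(params[2])),
        n_iter=len(trace),
    )


def all_estimates(
    insts: Sequence[HarmonizedInstrument],
    weighted_median_seed: int = 20240715,
    bwmr_seed: int = 20240715,
    n_boot: int = 1000,
) -> list[MREstimate]:
    """Run the full estimator panel on one harmonized instrument set.

    The Wald ratio is reported for the strongest instrument (largest
    |gamma_hat| / sigma_x); Egger contributes both slope and intercept rows.
    """
    strongest = max(insts, key=lambda i: abs(i.gamma_hat) / i.sigma_x)
    slope, intercept = egger(insts)
    return [
        wald_ratio(strongest),
        ivw(insts),
        slope,
        intercept,
        weighted_median(insts, n_boot=n_boot, seed=weighted_median_seed),
        max_likelihood(insts),
        raps(insts),
        bwmr(insts, seed=bwmr_seed),
    ]
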