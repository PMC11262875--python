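"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

These checks probe the validity of the instrument set behind a causal
estimate: Cochran's Q and I^2 quantify heterogeneity across per-SNP Wald
ratios; leave-one-out shows the influence of each instrument; radial
(Galbraith) coordinates decompose Q into per-SNP contributions for
visualization; and the residual-sum-and-outlier resampling test (MR-PRESSO
style) detects horizontal pleiotropy globally, per SNP, and as distortion of
the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .estimators import MREstimate, EstimationError, egger, ivw
from .harmonize import HarmonizedInstrument

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "RadialPoint",
    "RadialResult",
    "cochran_q",
    "heterogeneity_pvalue",
    "leave_one_out",
    "radial",
    "presso",
    "write_radial_table",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value and the I^2 transform.

    Degrees of freedom are J - 1 for the IVW fit and J - 2 for the Egger
    fit (one more parameter estimated).
    """

    method: str
    q_stat: float
    df: int
    pval: float
    i2: float


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: list[str]
    distortion_pval: Optional[float]
    n_sim: int
    seed: int


@dataclass(frozen=True)
class RadialPoint:
    snp_id: str
    x: float
    y: float
    q_contribution: float
    outlier_flag: bool


@dataclass(frozen=True)
class RadialResult:
    points: list[RadialPoint]
    ivw_fit: MREstimate
    egger_slope: MREstimate
    egger_intercept: MREstimate


def heterogeneity_pvalue(q_stat: float, df: int) -> float:
    """Upper-tail chi-square probability of a Q statistic."""
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(stats.chi2.sf(q_stat, df))


def _ratio_arrays(insts: Sequence[HarmonizedInstrument]):
    g = np.array([i.gamma_hat for i in insts])
    sy = np.array([i.sigma_y for i in insts])
    ratios = np.array([i.Gamma_hat for i in insts]) / g
    weights = g**2 / sy**2  # first-order Wald weights
    return g, sy, ratios, weights


def cochran_q(
    insts: Sequence[HarmonizedInstrument],
    fit: MREstimate | tuple[MREstimate, MREstimate] | None = None,
) -> HeterogeneityResult:
    """Cochran's Q around a fitted causal model.

    For an IVW fit, Q = sum w_j (ratio_j - beta)^2 with first-order weights
    and J - 1 degrees of freedom.  For an Egger fit (pass the
    ``(slope, intercept)`` pair), the fitted value for SNP j is
    intercept/gamma_hat_j + slope, and df = J - 2.  ``fit=None`` computes
    the IVW fit internally.  I^2 = max(0, (Q - df) / Q).
    """
    J = len(insts)
    g, sy, ratios, weights = _ratio_arrays(insts)
    if fit is None:
        fit = ivw(insts)
    if isinstance(fit, tuple):
        slope, intercept = fit
        if slope.method != "egger_slope":
            raise ValueError("expected an (egger_slope, egger_intercept) pair")
        # Egger fits on data re-oriented to gamma_hat >= 0; on the ratio
        # scale its prediction for SNP j is slope + intercept / |gamma_j|
        fitted = slope.beta + intercept.beta / np.abs(g)
        df = J - 2
        method = "egger"
    else:
        fitted = np.full(J, fit.beta)
        df = J - 1
        method = "ivw"
    if df <= 0:
        raise ValueError("too few instruments for a heterogeneity test")
    q = float(np.sum(weights * (ratios - fitted) ** 2))
    i2 = 0.0 if q == 0 else max(0.0, (q - df) / q)
    return HeterogeneityResult(method, q, df, heterogeneity_pvalue(q, df), i2)


def leave_one_out(
    insts: Sequence[HarmonizedInstrument],
    effects_model: str = "multiplicative_random",
) -> tuple[list[tuple[str, MREstimate]], MREstimate]:
    """IVW re-estimated with each instrument removed in turn.

    Returns the per-SNP list (snp_id, estimate-without-that-SNP) and the
    all-instrument reference estimate.
    """
    if len(insts) < 3:
        raise EstimationError("leave-one-out needs at least 3 instruments")
    full = ivw(insts, effects_model=effects_model)
    rows = []
    for j, inst in enumerate(insts):
        subset = [x for k, x in enumerate(insts) if k != j]
        rows.append((inst.snp_id, ivw(subset, effects_model=effects_model)))
    return rows, full


def radial(
    insts: Sequence[HarmonizedInstrument],
    alpha: float = 0.05,
) -> RadialResult:
    """Radial (Galbraith) decomposition of the instrument set.

    Each SNP is placed at x = sqrt(w_j), y = ratio_j * sqrt(w_j) with
    first-order weights; the through-origin slope of y on x equals the IVW
    estimate and each SNP's squared residual w_j (ratio_j - slope)^2 is its
    contribution to Cochran's Q.  A SNP is flagged as an outlier when its
    contribution exceeds the chi-square(1) quantile at the
    Bonferroni-corrected level alpha / J.  The radial Egger fit adds an
    intercept.
    """
    if len(insts) < 3:
        raise EstimationError("radial diagnostics need at least 3 instruments")
    J = len(insts)
    g, sy, ratios, weights = _ratio_arrays(insts)
    x = np.sqrt(weights)
    y = ratios * x

    slope_ivw = float(np.sum(x * y) / np.sum(x * x))  # equals IVW beta
    se_ivw = float(np.sum(x * x) ** -0.5)
    q_contrib = weights * (ratios - slope_ivw) ** 2
    q = float(np.sum(q_contrib))
    se_ivw *= max(1.0, math.sqrt(q / (J - 1)))
    cutoff = stats.chi2.ppf(1.0 - alpha / J, df=1)

    # radial Egger: weighted-with-intercept fit in radial coordinates
    X = np.column_stack([np.ones(J), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = J - 2
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    adj = max(1.0, math.sqrt(sigma2)) / math.sqrt(sigma2)
    inter_se, slope_se = math.sqrt(cov[0, 0]) * adj, math.sqrt(cov[1, 1]) * adj

    points = [
        RadialPoint(
            snp_id=inst.snp_id,
            x=float(x[j]),
            y=float(y[j]),
            q_contribution=float(q_contrib[j]),
            outlier_flag=bool(q_contrib[j] > cutoff),
        )
        for j, inst in enumerate(insts)
    ]
    return RadialResult(
        points=points,
        ivw_fit=MREstimate.from_beta_se("ivw", slope_ivw, se_ivw, J, q_stat=q),
        egger_slope=MREstimate.from_beta_se("egger_slope", float(coef[1]), slope_se, J),
        egger_intercept=MREstimate.from_beta_se("egger_intercept", float(coef[0]), inter_se, J),
    )


def _loo_estimates(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized leave-one-out IVW point estimates (first-order weights)."""
    tw = weights.sum(axis=-1, keepdims=True)
    tb = (weights * ratios).sum(axis=-1, keepdims=True)
    return (tb - weights * ratios) / (tw - weights)


def presso(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 20240715,
    significance: float = 0.05,
) -> PressoResult:
    """Residual-sum-and-outlier resampling test for horizontal pleiotropy.

    The observed global statistic is the weighted residual sum of squares of
    each SNP against the IVW fit that excludes it.  Its null distribution is
    built from ``n_sim`` parametric draws Gamma*_j ~ N(theta_hat_{-j}
    gamma_hat_j, sigma_y_j^2) with the RSS recomputed per draw; the global
    p-value is the fraction of simulated RSS at or above the observed one.
    Per-SNP outlier p-values compare each SNP's observed weighted squared
    residual with its own simulated distribution, Bonferroni-adjusted; SNPs
    significant at ``significance`` are flagged.  When outliers are flagged,
    a distortion test compares the shift in the IVW estimate after removing
    them with the shifts produced by removing equally many random SNPs.
    Empirical p-values use the (1 + exceedances) / (1 + n_sim) convention,
    so they are never zero.  Fully deterministic given ``seed``.
    """
    J = len(insts)
    if J < 4:
        raise EstimationError("the outlier resampling test needs at least 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100 for usable empirical p-values")
    if n_sim * significance < 1:
        raise ValueError("n_sim too small for the requested significance resolution")
    g, sy, ratios, weights = _ratio_arrays(insts)

    theta_loo = _loo_estimates(ratios, weights)  # shape (J,)
    obs_resid2 = weights * (ratios - theta_loo) ** 2
    obs_rss = float(np.sum(obs_resid2))

    rng = np.random.default_rng(seed)
    G_star = rng.normal(theta_loo * g, sy, size=(n_sim, J))
    ratios_star = G_star / g
    w_star = np.broadcast_to(weights, (n_sim, J))
    theta_loo_star = _loo_estimates(ratios_star, w_star)
    sim_resid2 = w_star * (ratios_star - theta_loo_star) ** 2
    sim_rss = sim_resid2.sum(axis=1)

    global_pval = (1.0 + float(np.sum(sim_rss >= obs_rss))) / (1.0 + n_sim)
    raw = (1.0 + (sim_resid2 >= obs_resid2).sum(axis=0)) / (1.0 + n_sim)
    outlier_pvals = {inst.snp_id: min(1.0, float(p) * J) for inst, p in zip(insts, raw)}
    outliers = [sid for sid, p in outlier_pvals.items() if p < significance]

    distortion_pval = None
    if outliers:
        theta_all = float(np.sum(weights * ratios) / np.sum(weights))
        keep = np.array([inst.snp_id not in outliers for inst in insts])
        if keep.sum() >= 2:
            theta_no = float(
                np.sum(weights[keep] * ratios[keep]) / np.sum(weights[keep])
            )
            obs_shift = theta_no - theta_all
            n_out = int((~keep).sum())
            shifts = np.empty(n_sim)
            for b in range(n_sim):
                drop = rng.choice(J, size=n_out, replace=False)
                mask = np.ones(J, dtype=bool)
                mask[drop] = False
                shifts[b] = (
                    np.sum(weights[mask] * ratios[mask]) / np.sum(weights[mask])
                    - theta_all
                )
            distortion_pval = (
                1.0 + float(np.sum(np.abs(shifts) >= abs(obs_shift)))
            ) / (1.0 + n_sim)

    return PressoResult(
        global_rss=obs_rss,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )


def write_radial_table(result: RadialResult, path: str | Path) -> None:
    """Plot-ready radial coordinates as a tab-separated table."""
    with open(path, "w") as handle:
        handle.write("snp_id\tx\ty\tq_contribution\toutlier\n")
        for p in result.points:
            handle.write(
                f"{p.snp_id}\t{p.x!r}\t{p.y!r}\t{p.q_contribution!r}\t{int(p.outlier_flag)}\n"
            )
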