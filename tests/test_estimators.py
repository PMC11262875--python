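"""Causal estimators: exact examples, oracles, and equivariance properties."""

import math

import numpy as np
import pytest

from mrlink.estimators import (
    EstimationError,
    bwmr,
    egger,
    ivw,
    max_likelihood,
    raps,
    wald_ratio,
    weighted_median,
)
from mrlink.harmonize import HarmonizedInstrument
from tests.conftest import make_inst, sim_insts


# ------------------------------------------------------------- Wald ratio

def test_wald_ratio_arithmetic():
    est = wald_ratio(make_inst(gamma=0.5, Gamma=0.1, sy=0.02))
    assert est.beta == pytest.approx(0.2)
    assert est.se == pytest.approx(0.04)


def test_wald_identity_instrument():
    est = wald_ratio(make_inst(gamma=1.0, Gamma=0.37, sy=0.05))
    assert est.beta == pytest.approx(0.37)


def test_wald_zero_exposure_effect_rejected():
    with pytest.raises(EstimationError, match="zero exposure"):
        wald_ratio(make_inst(gamma=0.0))


def test_wald_second_order_se_matches_monte_carlo():
    """Delta-method se of the ratio checked against 10^6 simulated draws."""
    gamma, sx, Gamma, sy = 0.5, 0.05, 0.1, 0.02
    est = wald_ratio(make_inst(gamma=gamma, sx=sx, Gamma=Gamma, sy=sy), second_order=True)
    rng = np.random.default_rng(99)
    draws = rng.normal(Gamma, sy, 10**6) / rng.normal(gamma, sx, 10**6)
    # the delta expansion truncates terms of order (sigma_x/gamma)^4, which
    # contribute ~2% here; 5% brackets both MC noise and the truncation
    assert est.se == pytest.approx(float(np.std(draws)), rel=0.05)
    # and it must exceed the first-order se, which ignores exposure noise
    first = wald_ratio(make_inst(gamma=gamma, sx=sx, Gamma=Gamma, sy=sy))
    assert est.se > first.se


# --------------------------------------------------------------------- IVW

def test_ivw_identical_ratios():
    insts = [make_inst(snp_id=f"rs{i}", gamma=0.5, Gamma=0.1) for i in range(3)]
    est = ivw(insts)
    assert est.beta == pytest.approx(0.2)
    assert est.extra["q_stat"] == pytest.approx(0.0, abs=1e-20)


def test_ivw_weighted_mean_oracle():
    # ratios {0.1, 0.3} with weights {100, 300}: gamma = 1 so the Wald se is
    # sigma_y and the weight 1/sigma_y^2
    insts = [
        make_inst(snp_id="a", gamma=1.0, Gamma=0.1, sy=0.1),
        make_inst(snp_id="b", gamma=1.0, Gamma=0.3, sy=1 / math.sqrt(300)),
    ]
    est = ivw(insts, effects_model="fixed")
    assert est.beta == pytest.approx((100 * 0.1 + 300 * 0.3) / 400)
    assert est.se == pytest.approx(400 ** -0.5)


def test_ivw_of_duplicated_instrument_is_the_wald_ratio():
    inst = make_inst(gamma=0.4, Gamma=0.1, sy=0.03)
    est = ivw([inst, inst], effects_model="fixed")
    assert est.beta == pytest.approx(wald_ratio(inst).beta)


def test_ivw_needs_two_instruments():
    with pytest.raises(EstimationError):
        ivw([make_inst()])


def test_ivw_random_effects_never_deflates_se(default_insts):
    fixed = ivw(default_insts, effects_model="fixed")
    random = ivw(default_insts, effects_model="multiplicative_random")
    assert random.se >= fixed.se
    assert random.beta == pytest.approx(fixed.beta)


# ------------------------------------------------------------------- Egger

def test_egger_exact_fit_recovers_line():
    gammas = [0.1, 0.2, 0.3, 0.4]
    insts = [
        make_inst(snp_id=f"rs{i}", gamma=g, Gamma=0.05 + 0.2 * g, sy=0.01 * (i + 1))
        for i, g in enumerate(gammas)
    ]
    slope, intercept = egger(insts)
    assert slope.beta == pytest.approx(0.2, abs=1e-10)
    assert intercept.beta == pytest.approx(0.05, abs=1e-10)


def test_egger_matches_normal_equations_oracle():
    """Hand-solved weighted normal equations on a random 10-instrument set."""
    rng = np.random.default_rng(5)
    g = rng.uniform(0.1, 0.5, 10)
    G = 0.03 + 0.25 * g + rng.normal(0, 0.02, 10)
    sy = rng.uniform(0.01, 0.05, 10)
    insts = [
        make_inst(snp_id=f"rs{i}", gamma=g[i], Gamma=G[i], sy=sy[i]) for i in range(10)
    ]
    slope, intercept = egger(insts)
    w = 1 / sy**2
    sw, swx, swxx = w.sum(), (w * g).sum(), (w * g * g).sum()
    swy, swxy = (w * G).sum(), (w * g * G).sum()
    det = sw * swxx - swx**2
    b0 = (swxx * swy - swx * swxy) / det
    b1 = (sw * swxy - swx * swy) / det
    assert intercept.beta == pytest.approx(b0, rel=1e-10)
    assert slope.beta == pytest.approx(b1, rel=1e-10)


def test_egger_orientation_invariance():
    """Flipping an instrument's reported alleles must not change the fit."""
    insts, _ = sim_insts(seed=21, n_snps=10)
    slope_a, inter_a = egger(insts)
    flipped = [
        HarmonizedInstrument(
            i.snp_id, -i.gamma_hat, i.sigma_x, -i.Gamma_hat, i.sigma_y,
            1 - i.eaf_exposure,
        )
        for i in insts[:5]
    ] + list(insts[5:])
    slope_b, inter_b = egger(flipped)
    assert slope_a.beta == pytest.approx(slope_b.beta)
    assert inter_a.beta == pytest.approx(inter_b.beta)


def test_egger_needs_three_instruments():
    with pytest.raises(EstimationError):
        egger([make_inst(), make_inst(snp_id="rs2")])


# --------------------------------------------------------- weighted median

def test_weighted_median_symmetric_case():
    insts = [
        make_inst(snp_id=f"rs{i}", gamma=1.0, Gamma=r, sy=0.1)
        for i, r in enumerate([0.1, 0.2, 0.3])
    ]
    assert weighted_median(insts, n_boot=100, seed=1).beta == pytest.approx(0.2)


def test_weighted_median_resists_minority_outliers():
    """6 valid instruments at theta = 0.2 carrying > 50% of the weight, 4
    gross outliers at 1.0: the estimate stays near the truth."""
    rng = np.random.default_rng(2)
    insts = []
    for i in range(6):
        insts.append(make_inst(snp_id=f"v{i}", gamma=1.0, Gamma=0.2 + rng.normal(0, 0.005), sy=0.01))
    for i in range(4):
        insts.append(make_inst(snp_id=f"o{i}", gamma=1.0, Gamma=1.0, sy=0.02))
    est = weighted_median(insts, n_boot=500, seed=3)
    assert abs(est.beta - 0.2) < 2 * est.se
    assert abs(est.beta - 0.2) < 0.05


def test_weighted_median_bootstrap_is_seeded():
    insts, _ = sim_insts(seed=31)
    a = weighted_median(insts, n_boot=200, seed=7)
    b = weighted_median(insts, n_boot=200, seed=7)
    assert a == b


# ------------------------------------------------------- maximum likelihood

def test_max_likelihood_reduces_to_fixed_ivw_without_exposure_noise():
    insts, _ = sim_insts(seed=41)
    tiny = [
        HarmonizedInstrument(i.snp_id, i.gamma_hat, 1e-10, i.Gamma_hat, i.sigma_y, 0.3)
        for i in insts
    ]
    ml = max_likelihood(tiny)
    fixed = ivw(tiny, effects_model="fixed")
    assert ml.beta == pytest.approx(fixed.beta, abs=1e-6)
    assert ml.se == pytest.approx(fixed.se, rel=1e-3)


def test_max_likelihood_recovers_truth():
    errors = []
    for seed in range(20):
        insts, truth = sim_insts(seed=seed, theta=0.3)
        est = max_likelihood(insts)
        errors.append((est.beta - 0.3) / est.se)
    # each standardized error within 3, and no systematic drift
    assert max(abs(e) for e in errors) < 3.5
    assert abs(np.mean(errors)) < 3 / math.sqrt(20)


# -------------------------------------------------------------------- RAPS

def test_raps_exact_on_noiseless_proportional_data():
    insts = [
        HarmonizedInstrument(f"rs{i}", g, 1e-9, 0.25 * g, 1e-9, 0.3)
        for i, g in enumerate([0.1, 0.2, 0.3])
    ]
    assert raps(insts).beta == pytest.approx(0.25, abs=1e-8)


def test_raps_unbiased_under_weak_instruments_where_ivw_attenuates():
    """50 instruments with per-SNP F around 5: the profile score stays
    centred on theta = 0.2 while naive IVW shrinks toward zero."""
    theta = 0.2
    raps_est, ivw_est = [], []
    for seed in range(200):
        insts, _ = sim_insts(
            seed=seed, n_snps=50, theta=theta, n_exposure=2000, n_outcome=2000,
            gamma_sd=0.08,
        )
        raps_est.append(raps(insts, overdispersion=False).beta)
        ivw_est.append(ivw(insts).beta)
    raps_mean, ivw_mean = np.mean(raps_est), np.mean(ivw_est)
    mc_se = np.std(raps_est, ddof=1) / math.sqrt(len(raps_est))
    assert abs(raps_mean - theta) < 3 * mc_se
    assert ivw_mean < raps_mean  # attenuation of the naive estimator
    assert abs(ivw_mean - theta) > abs(raps_mean - theta)


def test_raps_huber_close_to_squared_on_clean_data(default_insts):
    sq = raps(default_insts, overdispersion=False, loss="squared")
    hu = raps(default_insts, overdispersion=False, loss="huber")
    assert hu.beta == pytest.approx(sq.beta, abs=3 * sq.se)


# -------------------------------------------------------------------- BWMR

def test_bwmr_noiseless_proportional_data():
    rng = np.random.default_rng(8)
    g = rng.uniform(0.1, 0.4, 10)
    insts = [
        HarmonizedInstrument(f"rs{i}", g[i], 1e-6, 0.3 * g[i], 1e-6, 0.3)
        for i in range(10)
    ]
    est = bwmr(insts)
    assert est.beta == pytest.approx(0.3, abs=1e-3)
    assert min(est.extra["weights"]) > 0.99
    assert est.extra["tau2"] < 1e-8


def test_bwmr_downweights_planted_outlier():
    """One gross outlier among 30 instruments: its inlier weight collapses
    and the estimate stays near the truth; removing the outlier component
    (inlier prior 1.0) reproduces the biased fit."""
    theta = 0.25
    insts, _ = sim_insts(seed=17, n_snps=30, theta=theta)
    outlier = insts[0]
    insts = [
        HarmonizedInstrument(
            outlier.snp_id, outlier.gamma_hat, outlier.sigma_x,
            outlier.Gamma_hat + 10 * outlier.sigma_y, outlier.sigma_y, 0.3,
        )
    ] + list(insts[1:])
    est = bwmr(insts)
    weights = est.extra["weights"]
    assert weights[0] < 0.5
    assert min(weights[1:]) > weights[0]
    assert abs(est.beta - theta) < 3 * est.se

    unweighted = bwmr(insts, inlier_prob=1.0)
    assert abs(unweighted.beta - theta) > abs(est.beta - theta)


# -------------------------------------------------- shared property checks

_METHODS = {
    "ivw": lambda insts: ivw(insts).beta,
    "egger": lambda insts: egger(insts)[0].beta,
    "weighted_median": lambda insts: weighted_median(insts, n_boot=50, seed=1).beta,
    "max_likelihood": lambda insts: max_likelihood(insts).beta,
    "raps": lambda insts: raps(insts, overdispersion=False).beta,
    "bwmr": lambda insts: bwmr(insts).beta,
    "wald": lambda insts: wald_ratio(insts[0]).beta,
}


def _scale_outcome(insts, c):
    return [
        HarmonizedInstrument(
            i.snp_id, i.gamma_hat, i.sigma_x, c * i.Gamma_hat, abs(c) * i.sigma_y,
            i.eaf_exposure,
        )
        for i in insts
    ]


@pytest.mark.parametrize("method", sorted(_METHODS))
def test_scale_and_sign_equivariance(method):
    """Multiplying all outcome effects (and their errors) by c multiplies the
    causal estimate by c; negating them negates it."""
    insts, _ = sim_insts(seed=13, n_snps=12)
    f = _METHODS[method]
    base = f(insts)
    tol = 1e-3 if method == "bwmr" else 1e-6
    assert f(_scale_outcome(insts, 2.5)) == pytest.approx(2.5 * base, rel=tol, abs=tol)
    assert f(_scale_outcome(insts, -1.0)) == pytest.approx(-base, rel=tol, abs=tol)


def test_confidence_interval_invariants(default_insts):
    for est in [ivw(default_insts), max_likelihood(default_insts)]:
        assert est.ci_low == pytest.approx(math.exp(est.beta - 1.96 * est.se), rel=1e-3)
        assert est.ci_high == pytest.approx(math.exp(est.beta + 1.96 * est.se), rel=1e-3)
        assert est.ci_low <= est.or_point <= est.ci_high
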