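"""Core math: product of experts, KL, likelihood registry, adversarial loss."""

import math

import numpy as np
import pytest
from scipy import stats

from scpoe.io_and_data import BatchFactorDesign
from scpoe.model_core import (
    ExpertPosterior,
    JointPosterior,
    adversarial_loss,
    kl_loss,
    poe_combine,
    reconstruction_loss,
    sample_latent,
    total_loss,
)


def product_moments_numeric(means, variances, prior=(0.0, 1.0)):
    """Moments of the normalized product of 1-D Gaussian densities, on a grid."""
    grid = np.linspace(-15, 15, 60001)
    log_dens = stats.norm.logpdf(grid, prior[0], np.sqrt(prior[1]))
    for m, v in zip(means, variances):
        log_dens += stats.norm.logpdf(grid, m, np.sqrt(v))
    dens = np.exp(log_dens - log_dens.max())
    dens /= np.trapezoid(dens, grid)
    mean = np.trapezoid(grid * dens, grid)
    var = np.trapezoid((grid - mean) ** 2 * dens, grid)
    return mean, var


class TestPoECombine:
    def test_no_experts_returns_prior(self):
        joint = poe_combine([], prior=(np.zeros(3), np.ones(3)))
        np.testing.assert_allclose(joint.mean, np.zeros((1, 3)))
        np.testing.assert_allclose(joint.variance, np.ones((1, 3)))

    def test_single_standard_expert_halves_variance(self):
        e = ExpertPosterior(mean=np.zeros((1, 1)), variance=np.ones((1, 1)))
        joint = poe_combine([e])
        np.testing.assert_allclose(joint.variance, 0.5)
        np.testing.assert_allclose(joint.mean, 0.0)

    def test_two_experts_worked_case(self):
        # N(2,1) x N(0,1) x prior N(0,1): precision 3, mean (2+0+0)/3
        e1 = ExpertPosterior(mean=[[2.0]], variance=[[1.0]])
        e2 = ExpertPosterior(mean=[[0.0]], variance=[[1.0]])
        joint = poe_combine([e1, e2])
        np.testing.assert_allclose(joint.variance, 1 / 3, rtol=1e-12)
        np.testing.assert_allclose(joint.mean, 2 / 3, rtol=1e-12)
        m, v = product_moments_numeric([2.0, 0.0], [1.0, 1.0])
        np.testing.assert_allclose(joint.mean.ravel()[0], m, atol=1e-6)
        np.testing.assert_allclose(joint.variance.ravel()[0], v, atol=1e-6)

    def test_matches_numeric_density_product(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            k = rng.integers(1, 5)
            means = rng.uniform(-2, 2, k)
            variances = rng.uniform(0.1, 4.0, k)
            experts = [ExpertPosterior([[m]], [[v]]) for m, v in zip(means, variances)]
            joint = poe_combine(experts)
            m, v = product_moments_numeric(means, variances)
            np.testing.assert_allclose(joint.mean.ravel()[0], m, atol=1e-6)
            np.testing.assert_allclose(joint.variance.ravel()[0], v, atol=1e-6)

    def test_absent_expert_contributes_nothing(self):
        e1 = ExpertPosterior(mean=[[5.0], [5.0]], variance=[[0.5], [0.5]],
                             present=[1, 0])
        joint = poe_combine([e1])
        assert joint.mean[0, 0] > 0  # expert pulls first cell
        np.testing.assert_allclose(joint.mean[1], 0.0)  # prior only
        np.testing.assert_allclose(joint.variance[1], 1.0)

    def test_contraction_and_mean_containment(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = rng.integers(1, 4)
            means = rng.uniform(-3, 3, (1, k))
            variances = rng.uniform(0.05, 5.0, (1, k))
            experts = [ExpertPosterior([[means[0, i]]], [[variances[0, i]]])
                       for i in range(k)]
            joint = poe_combine(experts)
            assert joint.variance.min() <= variances.min() + 1e-12
            lo = min(means.min(), 0.0)
            hi = max(means.max(), 0.0)
            assert lo - 1e-9 <= joint.mean.ravel()[0] <= hi + 1e-9

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            ExpertPosterior(mean=[[0.0]], variance=[[0.0]])


class TestSampleLatent:
    def test_same_seed_identical(self):
        p = JointPosterior(np.zeros((4, 3)), np.ones((4, 3)))
        np.testing.assert_array_equal(sample_latent(p, 5), sample_latent(p, 5))

    def test_moments_match(self):
        p = JointPosterior(np.full((100_000, 1), 1.0), np.full((100_000, 1), 4.0))
        z = sample_latent(p, 0)
        se_mean = 2.0 / np.sqrt(z.size)
        assert abs(z.mean() - 1.0) < 3 * se_mean
        se_var = 4.0 * np.sqrt(2.0 / (z.size - 1))
        assert abs(z.var() - 4.0) < 3 * se_var

    def test_degenerate_variance_returns_mean(self):
        p = JointPosterior(np.full((2, 2), 3.0), np.full((2, 2), 1e-6))
        z = sample_latent(p, 1)
        np.testing.assert_allclose(z, 3.0, atol=0.05)


class TestKLLoss:
    def test_standard_normal_gives_zero(self):
        p = JointPosterior(np.zeros((3, 4)), np.ones((3, 4)))
        assert kl_loss(p, 1.0) == 0.0

    def test_unit_mean_shift_gives_half(self):
        p = JointPosterior(np.ones((1, 1)), np.ones((1, 1)))
        np.testing.assert_allclose(kl_loss(p, 1.0), 0.5)

    def test_weight_is_linear(self):
        p = JointPosterior(np.ones((2, 3)) * 0.7, np.ones((2, 3)) * 1.4)
        np.testing.assert_allclose(kl_loss(p, 2.0), 2 * kl_loss(p, 1.0))

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(8)
        n = 200_000
        for _ in range(5):
            mu, var = rng.uniform(-2, 2), rng.uniform(0.2, 3.0)
            p = JointPosterior([[mu]], [[var]])
            closed = kl_loss(p, 1.0)
            z = rng.normal(mu, np.sqrt(var), n)
            log_ratio = stats.norm.logpdf(z, mu, np.sqrt(var)) - stats.norm.logpdf(z)
            mc, se = log_ratio.mean(), log_ratio.std() / np.sqrt(n)
            assert abs(closed - mc) < 3 * se


class TestReconstructionLoss:
    def test_poisson_worked_value(self):
        # y=3, rate=3: 3 - 3 log 3 + log 3!
        expected = 3 - 3 * math.log(3) + math.log(math.factorial(3))
        got = reconstruction_loss("poisson", [[3.0]], {"rate": [[3.0]]})
        np.testing.assert_allclose(got, expected, atol=1e-9)
        np.testing.assert_allclose(got, 1.4959, atol=1e-4)

    @pytest.mark.parametrize(
        "family,y,params,logpmf",
        [
            ("poisson", 4.0, {"rate": 2.5}, lambda y, p: stats.poisson.logpmf(y, p["rate"])),
            ("negative_binomial", 7.0, {"mu": 3.0, "theta": 2.0},
             lambda y, p: stats.nbinom.logpmf(y, p["theta"], p["theta"] / (p["theta"] + p["mu"]))),
            ("bernoulli", 1.0, {"logit": 0.3},
             lambda y, p: stats.bernoulli.logpmf(y, 1 / (1 + np.exp(-p["logit"])))),
            ("gaussian", 0.7, {"mu": 0.2, "var": 1.7},
             lambda y, p: stats.norm.logpdf(y, p["mu"], np.sqrt(p["var"]))),
        ],
    )
    def test_families_match_scipy_log_pmf(self, family, y, params, logpmf):
        got = reconstruction_loss(family, [[y]], {k: [[v]] for k, v in params.items()})
        np.testing.assert_allclose(got, -logpmf(y, params), atol=1e-9)

    def test_negative_multinomial_matches_direct_formula(self):
        y = np.array([[2.0, 0.0, 5.0]])
        lam = np.array([[1.5, 0.5, 4.0]])
        r = 2.0
        S, T = lam.sum(), y.sum()
        logp = (
            math.lgamma(r + T) - math.lgamma(r)
            - sum(math.lgamma(v + 1) for v in y.ravel())
            + float((y * np.log(lam / (r + S))).sum())
            + r * math.log(r / (r + S))
        )
        got = reconstruction_loss("negative_multinomial", y,
                                  {"rate": lam, "r": [[r]]})
        np.testing.assert_allclose(got * y.size, -logp, atol=1e-9)

    def test_bernoulli_perfect_reconstruction_tends_to_zero(self):
        loss = reconstruction_loss("bernoulli", [[1.0]], {"logit": [[30.0]]})
        assert loss < 1e-12

    @pytest.mark.parametrize("family,params,y", [
        ("poisson", "rate", 6.0),
        ("negative_binomial", "mu", 6.0),
        ("gaussian", "mu", 0.3),
    ])
    def test_nll_minimised_at_observation(self, family, params, y):
        grid = np.linspace(max(y - 3, 0.05), y + 3, 301)
        losses = []
        for g in grid:
            p = {params: [[g]]}
            if family == "negative_binomial":
                p["theta"] = [[2.0]]
            if family == "gaussian":
                p["var"] = [[1.0]]
            losses.append(reconstruction_loss(family, [[y]], p))
        argmin = grid[int(np.argmin(losses))]
        assert abs(argmin - y) <= (grid[1] - grid[0]) + 1e-9

    def test_masked_entries_contribute_exactly_zero(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(4.0, (5, 6)).astype(float)
        rate = rng.uniform(0.5, 5.0, (5, 6))
        mask = (rng.random((5, 6)) > 0.4).astype(float)
        base = reconstruction_loss("poisson", y, {"rate": rate}, mask)
        y2 = y.copy()
        y2[mask == 0] = 1e6  # garbage at masked-out positions
        assert reconstruction_loss("poisson", y2, {"rate": rate}, mask) == base

    def test_unknown_family_and_domain_errors(self):
        with pytest.raises(KeyError):
            reconstruction_loss("zeta", [[1.0]], {})
        with pytest.raises(ValueError):
            reconstruction_loss("poisson", [[-1.0]], {"rate": [[1.0]]})
        with pytest.raises(ValueError):
            reconstruction_loss("bernoulli", [[1.5]], {"logit": [[0.0]]})


class TestAdversarialLoss:
    def test_uniform_scores_give_log_k(self):
        design = BatchFactorDesign("b", "categorical",
                                   np.eye(4)[[0, 1, 2, 3]], list("abcd"))
        loss = adversarial_loss(design, np.zeros((4, 4)))
        np.testing.assert_allclose(loss, math.log(4), rtol=1e-12)

    def test_confident_correct_scores_give_zero(self):
        enc = np.eye(3)
        design = BatchFactorDesign("b", "categorical", enc, list("xyz"))
        loss = adversarial_loss(design, enc * 1e4)
        assert loss < 1e-8

    def test_continuous_exact_prediction_gives_zero(self):
        design = BatchFactorDesign("age", "continuous",
                                   np.array([[-1.0], [0.0], [1.0]]))
        assert adversarial_loss(design, design.encoded.copy()) == 0.0

    def test_shape_mismatch_rejected(self):
        design = BatchFactorDesign("b", "categorical", np.eye(2), ["a", "b"])
        with pytest.raises(ValueError):
            adversarial_loss(design, np.zeros((2, 3)))


class TestTotalLoss:
    def test_arithmetic(self):
        bd = total_loss(0.5, [1.0, 2.0], [0.3])
        np.testing.assert_allclose(bd.total, 3.2)

    def test_no_adversaries(self):
        bd = total_loss(0.5, [1.0, 2.0])
        np.testing.assert_allclose(bd.total, 3.5)

    def test_adversary_gain_decreases_total(self):
        low = total_loss(0.5, [1.0], [0.1]).total
        high = total_loss(0.5, [1.0], [0.9]).total
        assert high < low

    def test_nan_component_named(self):
        with pytest.raises(ValueError, match="kl"):
            total_loss(float("nan"), [1.0], [0.1])
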