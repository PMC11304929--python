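"""Core model mathematics.

Each assay's encoder emits a Gaussian "expert" posterior over the shared
K-dimensional latent space.  Experts are combined with a standard-normal
prior by a product of experts: for Gaussians the product is again Gaussian,
with precisions adding and means precision-weighted,

    1/var_joint = 1/var_0 + sum_i 1/var_i
    mu_joint    = var_joint * (mu_0/var_0 + sum_i mu_i/var_i).

Absent experts (whole-modality missingness) simply drop out of the sums, so a
cell with a single measured assay still receives a well-defined posterior.

The total training objective is

    L_total = L_kl + sum_i L_recon(Y^i, Yhat^i) - sum_j L_adv(b^j),

with the KL term in the standard closed form against N(0, I), per-assay
reconstruction negative log-likelihoods from a pluggable family registry
(negative binomial, Poisson, negative multinomial, Bernoulli, Gaussian), and
per-factor adversarial losses (categorical cross-entropy with softmax, or
squared error for continuous factors) evaluated on the deterministic
embedding mu_joint.  The minus sign on the adversarial sum is realised during
training by a gradient-reversal layer; see `network_and_training`.

All loss functions accept a 0/1 mask and guarantee that masked-out entries
contribute exactly zero to both value and gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .io_and_data import BatchFactorDesign

__all__ = [
    "VARIANCE_FLOOR",
    "ExpertPosterior",
    "JointPosterior",
    "LossBreakdown",
    "LikelihoodFamily",
    "FAMILIES",
    "register_family",
    "poe_combine",
    "sample_latent",
    "kl_loss",
    "reconstruction_loss",
    "adversarial_loss",
    "total_loss",
]

VARIANCE_FLOOR = 1e-6

#: families whose observations are counts (encoder inputs get a log1p
#: transform; imputation quality is assessed on the log1p scale)
COUNT_FAMILY_NAMES = {"negative_binomial", "poisson", "negative_multinomial"}


@dataclass
class ExpertPosterior:
    """Per-assay Gaussian posterior: cell x K mean and variance, plus a
    per-cell 0/1 presence flag (0 = modality missing, expert drops out)."""

    mean: np.ndarray
    variance: np.ndarray
    present: np.ndarray | None = None

    def __post_init__(self):
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=np.float64))
        self.variance = np.atleast_2d(np.asarray(self.variance, dtype=np.float64))
        if self.present is None:
            self.present = np.ones(self.mean.shape[0])
        self.present = np.asarray(self.present, dtype=np.float64).ravel()
        bad = (self.variance <= 0) & (self.present[:, None] > 0)
        if np.any(bad):
            raise ValueError("expert variance must be positive where present")


@dataclass
class JointPosterior:
    """Joint Gaussian over the latent space for a batch of cells."""

    mean: np.ndarray
    variance: np.ndarray
    prior_mean: np.ndarray | None = None
    prior_variance: np.ndarray | None = None

    def __post_init__(self):
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=np.float64))
        self.variance = np.atleast_2d(np.asarray(self.variance, dtype=np.float64))
        K = self.mean.shape[1]
        if self.prior_mean is None:
            self.prior_mean = np.zeros(K)
        if self.prior_variance is None:
            self.prior_variance = np.ones(K)
        if np.any(self.variance <= 0):
            raise ValueError("joint variance must be positive")


@dataclass
class LossBreakdown:
    """Components of the total objective, stored for logging."""

    kl: float
    recon: dict[str, float] = field(default_factory=dict)
    adv: dict[str, float] = field(default_factory=dict)
    kl_weight: float = 1.0

    @property
    def total(self) -> float:
        return self.kl + sum(self.recon.values()) - sum(self.adv.values())


# ---------------------------------------------------------------------------
# product of experts


def poe_combine_t(
    means: list[Tensor],
    variances: list[Tensor],
    present: list[np.ndarray],
    prior_mean: np.ndarray,
    prior_variance: np.ndarray,
) -> tuple[Tensor, Tensor]:
    """Differentiable PoE over a list of expert (mean, variance) pairs.

    `present[i]` is a per-cell 0/1 vector; absent experts contribute nothing
    to the precision and mean sums.  Returns (mu_joint, var_joint) Tensors.
    """
    prior_prec = 1.0 / np.asarray(prior_variance, dtype=np.float64)
    precision = Tensor(np.broadcast_to(prior_prec, means[0].data.shape).copy()) if means else Tensor(prior_prec)
    weighted_mean = Tensor(
        np.broadcast_to(np.asarray(prior_mean) * prior_prec, means[0].data.shape).copy()
    ) if means else Tensor(np.asarray(prior_mean) * prior_prec)
    for mu, var, pres in zip(means, variances, present):
        p = np.asarray(pres, dtype=np.float64).reshape(-1, 1)
        var = var.clip_min(VARIANCE_FLOOR)
        precision = precision + Tensor(p) / var
        weighted_mean = weighted_mean + Tensor(p) * mu / var
    var_joint = 1.0 / precision
    mu_joint = weighted_mean * var_joint
    return mu_joint, var_joint


def poe_combine(
    experts: list[ExpertPosterior],
    prior: tuple[np.ndarray, np.ndarray] | None = None,
) -> JointPosterior:
    """Combine expert posteriors with the prior into the joint posterior.

    With no experts present the joint equals the prior; each present expert
    tightens the joint (variance never exceeds any contributor's variance).
    """
    if experts:
        n_cells, K = experts[0].mean.shape
    else:
        n_cells, K = 1, (len(prior[0]) if prior else 1)
    if prior is None:
        prior = (np.zeros(K), np.ones(K))
    mu0, var0 = np.asarray(prior[0], dtype=np.float64), np.asarray(prior[1], dtype=np.float64)
    if np.any(var0 <= 0):
        raise ValueError("prior variance must be positive")
    for e in experts:
        if e.mean.shape != (n_cells, K):
            raise ValueError("experts disagree on (n_cells, K)")
    mu_t, var_t = poe_combine_t(
        [Tensor(e.mean) for e in experts],
        [Tensor(np.where(e.present[:, None] > 0, e.variance, 1.0)) for e in experts],
        [e.present for e in experts],
        mu0,
        var0,
    )
    return JointPosterior(mu_t.data, var_t.data, mu0, var0)


def sample_latent(posterior: JointPosterior, rng_seed: int) -> np.ndarray:
    """Reparameterised draw z = mu + sqrt(var) * eps with seeded noise."""
    rng = np.random.default_rng(rng_seed)
    eps = rng.standard_normal(posterior.mean.shape)
    return posterior.mean + np.sqrt(np.maximum(posterior.variance, VARIANCE_FLOOR)) * eps


# ---------------------------------------------------------------------------
# KL divergence


def kl_loss_t(mu: Tensor, var: Tensor, kl_weight: float) -> Tensor:
    """w * KL(N(mu, var) || N(0, I)) averaged over the minibatch."""
    var = var.clip_min(VARIANCE_FLOOR)
    per_cell = (1.0 + var.log() - mu * mu - var).sum(axis=1)
    return per_cell.mean() * (-0.5 * kl_weight)


def kl_loss(posterior: JointPosterior, kl_weight: float = 1.0) -> float:
    if kl_weight < 0:
        raise ValueError("kl_weight must be non-negative")
    if np.any(posterior.variance <= 0):
        raise ValueError("variance must be positive")
    return float(kl_loss_t(Tensor(posterior.mean), Tensor(posterior.variance), kl_weight).data)


# ---------------------------------------------------------------------------
# likelihood family registry


class LikelihoodFamily:
    """One reconstruction likelihood.  Subclasses define how raw decoder
    outputs map to natural parameters, the masked NLL, and the family mean
    used for imputation.  New families register via `register_family` without
    touching the core."""

    name: str = ""
    #: number of per-feature auxiliary parameters learned outside the decoder
    n_aux: int = 0

    def validate(self, observed: np.ndarray) -> None:
        pass

    def activate(self, raw: Tensor, aux: list[Tensor]) -> dict[str, Tensor]:
        raise NotImplementedError

    def nll(self, observed: np.ndarray, params: dict[str, Tensor], mask: np.ndarray) -> Tensor:
        """Mean NLL over masked-in entries; masked-out entries contribute 0."""
        raise NotImplementedError

    def mean(self, params: dict[str, Tensor]) -> np.ndarray:
        raise NotImplementedError

    def init_aux(self, n_features: int) -> list[np.ndarray]:
        return []


def _masked_mean(elementwise: Tensor, mask: np.ndarray) -> Tensor:
    total = max(float(mask.sum()), 1.0)
    return (elementwise * Tensor(mask)).sum() * (1.0 / total)


class PoissonFamily(LikelihoodFamily):
    name = "poisson"

    def validate(self, observed):
        if np.any(observed < 0):
            raise ValueError("poisson observations must be non-negative counts")

    def activate(self, raw, aux):
        # log link, clamped for numerical safety
        return {"rate": raw.clip_max(12.0).exp() + 1e-8}

    def nll(self, observed, params, mask):
        y = np.asarray(observed, dtype=np.float64) * mask
        rate = params["rate"]
        from scipy.special import gammaln

        elem = rate - Tensor(y) * rate.log() + Tensor(gammaln(y + 1.0))
        return _masked_mean(elem, mask)

    def mean(self, params):
        return params["rate"].data

    def param_names(self):
        return ["rate"]


class NegativeBinomialFamily(LikelihoodFamily):
    """NB parameterised by (mean mu, inverse-dispersion theta); one learnable
    theta per feature.  Var = mu + mu^2/theta."""

    name = "negative_binomial"
    n_aux = 1  # log_theta per feature

    def validate(self, observed):
        if np.any(observed < 0):
            raise ValueError("negative binomial observations must be non-negative counts")

    def activate(self, raw, aux):
        return {"mu": raw.clip_max(12.0).exp() + 1e-8, "theta": aux[0].exp()}

    def init_aux(self, n_features):
        return [np.zeros((1, n_features))]  # theta = 1 initially

    def nll(self, observed, params, mask):
        y = np.asarray(observed, dtype=np.float64) * mask
        mu, theta = params["mu"], params["theta"]
        yt = Tensor(y)
        log_mu_t = (mu + theta).log()
        elem = (
            -(yt + theta).lgamma()
            + theta.lgamma()
            + Tensor(_gammaln(y + 1.0))
            - theta * (theta.log() - log_mu_t)
            - yt * (mu.log() - log_mu_t)
        )
        return _masked_mean(elem, mask)

    def mean(self, params):
        return params["mu"].data


class BernoulliFamily(LikelihoodFamily):
    """Binary / beta-valued reconstruction via a logit link; suits the
    bimodal marginals of methylation beta values."""

    name = "bernoulli"

    def validate(self, observed):
        if np.any((observed < 0) | (observed > 1)):
            raise ValueError("bernoulli observations must lie in [0, 1]")

    def activate(self, raw, aux):
        return {"logit": raw}

    def nll(self, observed, params, mask):
        y = np.asarray(observed, dtype=np.float64) * mask
        x = params["logit"]
        # stable binary cross-entropy with logits: softplus(x) - x*y
        elem = x.softplus() - x * Tensor(y)
        return _masked_mean(elem, mask)

    def mean(self, params):
        from scipy.special import expit

        return expit(params["logit"].data)


class GaussianFamily(LikelihoodFamily):
    name = "gaussian"
    n_aux = 1  # log-variance per feature

    def activate(self, raw, aux):
        return {"mu": raw, "var": aux[0].exp() + 1e-8}

    def init_aux(self, n_features):
        return [np.zeros((1, n_features))]

    def nll(self, observed, params, mask):
        y = np.asarray(observed, dtype=np.float64) * mask
        mu, var = params["mu"], params["var"]
        diff = mu - Tensor(y)
        elem = 0.5 * (diff * diff / var + var.log() + np.log(2 * np.pi))
        return _masked_mean(elem, mask)

    def mean(self, params):
        return params["mu"].data


class NegativeMultinomialFamily(LikelihoodFamily):
    """Negative multinomial over each cell's observed feature vector with a
    learnable per-assay overdispersion r.  Parameterised through per-entry
    rates lambda so that E[y_f] = lambda_f; the success probabilities are
    p_f = lambda_f / (r + sum lambda), p_0 = r / (r + sum lambda)."""

    name = "negative_multinomial"
    n_aux = 1  # scalar log_r

    def validate(self, observed):
        if np.any(observed < 0):
            raise ValueError("negative multinomial observations must be non-negative counts")

    def activate(self, raw, aux):
        return {"rate": raw.clip_max(12.0).exp() + 1e-8, "r": aux[0].exp()}

    def init_aux(self, n_features):
        return [np.zeros((1, 1))]

    def nll(self, observed, params, mask):
        y = np.asarray(observed, dtype=np.float64) * mask
        lam, r = params["rate"], params["r"]
        lam_obs = lam * Tensor(mask)
        S = lam_obs.sum(axis=1, keepdims=True)  # per-cell total rate
        T = y.sum(axis=1, keepdims=True)
        denom_log = (r + S).log()
        per_cell = -(
            (Tensor(T) + r).lgamma()
            - r.lgamma()
            - Tensor(_gammaln(y + 1.0) * mask).sum(axis=1, keepdims=True)
            + (Tensor(y) * (lam.log() - denom_log)).sum(axis=1, keepdims=True)
            + r * (r.log() - denom_log)
        )
        total = max(float(mask.sum()), 1.0)
        return per_cell.sum() * (1.0 / total)

    def mean(self, params):
        return params["rate"].data


def _gammaln(x):
    from scipy.special import gammaln

    return gammaln(x)


FAMILIES: dict[str, LikelihoodFamily] = {}


def register_family(family: LikelihoodFamily) -> None:
    FAMILIES[family.name] = family


for _fam in (
    PoissonFamily(),
    NegativeBinomialFamily(),
    BernoulliFamily(),
    GaussianFamily(),
    NegativeMultinomialFamily(),
):
    register_family(_fam)


def reconstruction_loss(
    family: str,
    observed: np.ndarray,
    predicted_params: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
) -> float:
    """Masked mean negative log-likelihood for a named family.

    `predicted_params` are natural-scale parameters (e.g. NB mean "mu" and
    dispersion "theta", Poisson "rate", Bernoulli "logit", Gaussian
    "mu"/"var", negative multinomial "rate"/"r").
    """
    if family not in FAMILIES:
        raise KeyError(f"unknown likelihood family {family!r}; registered: {sorted(FAMILIES)}")
    fam = FAMILIES[family]
    observed = np.atleast_2d(np.asarray(observed, dtype=np.float64))
    if mask is None:
        mask = np.ones_like(observed)
    mask = np.atleast_2d(np.asarray(mask, dtype=np.float64))
    fam.validate(observed * mask)
    params = {
        k: Tensor(np.atleast_2d(np.asarray(v, dtype=np.float64)))
        for k, v in predicted_params.items()
    }
    return float(fam.nll(observed, params, mask).data)


# ---------------------------------------------------------------------------
# adversarial losses


def adversarial_loss_t(design: BatchFactorDesign, scores: Tensor) -> Tensor:
    """Differentiable per-factor adversary loss on raw network outputs.

    Categorical: mean over cells of the cross-entropy between the one-hot
    target and the softmax of the scores.  Continuous: mean squared error.
    """
    target = design.encoded
    if scores.data.shape != target.shape:
        raise ValueError(
            f"adversary predictions {scores.data.shape} do not match design "
            f"{target.shape} for factor {design.name!r}"
        )
    if design.kind == "categorical":
        return (-(Tensor(target) * scores.log_softmax(axis=1)).sum(axis=1)).mean()
    diff = scores - Tensor(target)
    return (diff * diff).sum(axis=1).mean()


def adversarial_loss(design: BatchFactorDesign, predictions: np.ndarray) -> float:
    return float(adversarial_loss_t(design, Tensor(np.atleast_2d(predictions))).data)


def total_loss(
    kl: float,
    recon: dict[str, float] | list[float],
    adv: dict[str, float] | list[float] | None = None,
    kl_weight: float = 1.0,
) -> LossBreakdown:
    """Assemble the loss breakdown: total = kl + sum(recon) - sum(adv)."""
    if not isinstance(recon, dict):
        recon = {f"assay_{i}": v for i, v in enumerate(recon)}
    adv = adv or {}
    if not isinstance(adv, dict):
        adv = {f"factor_{i}": v for i, v in enumerate(adv)}
    for label, v in [("kl", kl), *recon.items(), *adv.items()]:
        if not np.isfinite(v):
            raise ValueError(f"non-finite loss component {label!r}: {v}")
    return LossBreakdown(kl=float(kl), recon={k: float(v) for k, v in recon.items()},
                         adv={k: float(v) for k, v in adv.items()}, kl_weight=kl_weight)
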