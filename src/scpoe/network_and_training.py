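"""Encoder/decoder/adversary assembly and the seeded training loop.

One encoder-decoder pair per assay, one adversary per batch factor.  Batch
covariates are concatenated to every encoder input and every decoder input,
so batch-driven variance need not be stored in the latent space; adversaries
read the deterministic joint mean through a gradient-reversal layer, which
trains them to predict their factor while pushing the embedding to be
uninformative about it — the minimax of the total objective in one
optimiser step.

Masks are applied at three points: encoder inputs are zero-filled at missing
entries, cells with a fully missing modality drop that expert out of the
product-of-experts, and the reconstruction loss averages over observed
entries only, so missing measurements contribute no gradient anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Adam, Tensor, concat, grad_reverse
from .io_and_data import BatchFactorDesign, MultiomicsDataset
from .model_core import (
    COUNT_FAMILY_NAMES,
    FAMILIES,
    VARIANCE_FLOOR,
    LossBreakdown,
    adversarial_loss_t,
    kl_loss_t,
    poe_combine_t,
)

__all__ = ["ModelConfig", "TrainedModel", "build_model", "train"]


@dataclass
class ModelConfig:
    """Hyperparameters of one model run.

    `families` maps assay name -> likelihood family.  `use_covariates` /
    `use_adversaries` are the ablation switches for the batch-correction
    mechanisms (both on by default).
    """

    latent_dim: int = 10
    encoder_hidden: list[int] = field(default_factory=lambda: [512, 256])
    decoder_hidden: list[int] = field(default_factory=lambda: [256])
    adversary_hidden: list[int] = field(default_factory=lambda: [128, 128])
    input_dropout: float = 0.1
    #: reconstruction losses average over observed entries, so the KL weight
    #: is small by default (roughly 1/n_features for a typical assay)
    kl_weight: float = 0.005
    batch_size: int = 512
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    families: dict[str, str] = field(default_factory=dict)
    grad_reversal_scale: float = 1.0
    use_covariates: bool = True
    use_adversaries: bool = True

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0.0 <= self.input_dropout < 1.0:
            raise ValueError("input_dropout must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class _MLP:
    """Dense ReLU stack; final layer linear."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for n_in, n_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / n_in)
            self.weights.append(Tensor(rng.normal(0, scale, (n_in, n_out)), requires_grad=True))
            self.biases.append(Tensor(np.zeros((1, n_out)), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ w + b
            if i < len(self.weights) - 1:
                x = x.relu()
        return x

    @property
    def params(self) -> list[Tensor]:
        return self.weights + self.biases


class TrainedModel:
    """Networks + config + per-epoch loss history.  Serialisable."""

    def __init__(self, config: ModelConfig, assay_features: dict[str, int],
                 factor_specs: list[tuple[str, str, int]]):
        self.config = config
        self.assay_features = dict(assay_features)
        self.factor_specs = list(factor_specs)  # (name, kind, width)
        self.history: list[LossBreakdown] = []
        rng = np.random.default_rng(config.seed)
        cov_width = sum(w for _, _, w in factor_specs) if config.use_covariates else 0
        self.encoders: dict[str, _MLP] = {}
        self.enc_mu: dict[str, Tensor] = {}
        self.enc_logvar_head: dict[str, tuple[Tensor, Tensor]] = {}
        self.decoders: dict[str, _MLP] = {}
        self.dec_out: dict[str, tuple[Tensor, Tensor]] = {}
        self.aux: dict[str, list[Tensor]] = {}
        K = config.latent_dim
        for name, n_feat in assay_features.items():
            if n_feat < 1:
                raise ValueError(f"assay {name!r} has zero features")
            enc_widths = [n_feat + cov_width, *config.encoder_hidden]
            self.encoders[name] = _MLP(enc_widths, rng)
            h = enc_widths[-1]
            self.enc_logvar_head[name] = (
                Tensor(rng.normal(0, np.sqrt(1.0 / h), (h, 2 * K)), requires_grad=True),
                Tensor(np.zeros((1, 2 * K)), requires_grad=True),
            )
            dec_widths = [K + cov_width, *config.decoder_hidden]
            self.decoders[name] = _MLP(dec_widths, rng)
            hd = dec_widths[-1]
            self.dec_out[name] = (
                Tensor(rng.normal(0, np.sqrt(1.0 / hd), (hd, n_feat)), requires_grad=True),
                Tensor(np.zeros((1, n_feat)), requires_grad=True),
            )
            fam = FAMILIES[config.families[name]]
            self.aux[name] = [Tensor(a, requires_grad=True) for a in fam.init_aux(n_feat)]
        self.adversaries: dict[str, _MLP] = {}
        if config.use_adversaries:
            for fname, kind, width in factor_specs:
                out = width  # one score per level (categorical) or 1 (continuous)
                self.adversaries[fname] = _MLP([K, *config.adversary_hidden, out], rng)

    # -- parameter access -----------------------------------------------------

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for name in self.assay_features:
            ps += self.encoders[name].params
            ps += list(self.enc_logvar_head[name])
            ps += self.decoders[name].params
            ps += list(self.dec_out[name])
            ps += self.aux[name]
        for adv in self.adversaries.values():
            ps += adv.params
        return ps

    # -- forward pieces -------------------------------------------------------

    def _covariates(self, factors: list[BatchFactorDesign], rows: np.ndarray) -> np.ndarray | None:
        if not self.config.use_covariates or not factors:
            return None
        return np.concatenate([f.encoded[rows] for f in factors], axis=1)

    def encode_assay(self, name: str, x: np.ndarray, cov: np.ndarray | None,
                     dropout_rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Returns (mean, variance) Tensors of the assay's expert posterior."""
        if dropout_rng is not None and self.config.input_dropout > 0:
            keep = (dropout_rng.random(x.shape) >= self.config.input_dropout)
            x = x * keep / (1.0 - self.config.input_dropout)
        inp = Tensor(x if cov is None else np.concatenate([x, cov], axis=1))
        h = self.encoders[name](inp)
        if self.encoders[name].weights:
            h = h.relu()
        w, b = self.enc_logvar_head[name]
        out = h @ w + b
        K = self.config.latent_dim
        mu = out.slice_cols(0, K)
        logvar = out.slice_cols(K, 2 * K).clip_max(10.0)
        return mu, logvar.exp().clip_min(VARIANCE_FLOOR)

    def joint_posterior(self, dataset: MultiomicsDataset, factors: list[BatchFactorDesign],
                        rows: np.ndarray,
                        dropout_rng: np.random.Generator | None = None,
                        exclude: set[str] | None = None) -> tuple[Tensor, Tensor]:
        cov = self._covariates(factors, rows)
        means, variances, present = [], [], []
        for name in self.assay_features:
            if exclude and name in exclude:
                continue
            assay = dataset.assay(name)
            x = assay.dense()[rows] * dataset.masks[name][rows]
            if self.config.families[name] in COUNT_FAMILY_NAMES:
                x = np.log1p(x)  # condition count inputs; decoder still sees counts
            mu, var = self.encode_assay(name, x, cov, dropout_rng)
            means.append(mu)
            variances.append(var)
            present.append(dataset.modality_present(name)[rows])
        K = self.config.latent_dim
        return poe_combine_t(means, variances, present, np.zeros(K), np.ones(K))

    def decode_assay(self, name: str, z: Tensor, cov: np.ndarray | None) -> dict[str, Tensor]:
        inp = z if cov is None else concat([z, Tensor(cov)], axis=1)
        h = self.decoders[name](inp)
        if len(self.decoders[name].weights) > 0:
            h = h.relu()
        w, b = self.dec_out[name]
        raw = h @ w + b
        fam = FAMILIES[self.config.families[name]]
        return fam.activate(raw, self.aux[name])

    # -- serialisation --------------------------------------------------------

    def _named_params(self) -> dict[str, Tensor]:
        out = {}
        for name in self.assay_features:
            for i, p in enumerate(self.encoders[name].params):
                out[f"enc/{name}/{i}"] = p
            out[f"enc_head/{name}/w"], out[f"enc_head/{name}/b"] = self.enc_logvar_head[name]
            for i, p in enumerate(self.decoders[name].params):
                out[f"dec/{name}/{i}"] = p
            out[f"dec_out/{name}/w"], out[f"dec_out/{name}/b"] = self.dec_out[name]
            for i, p in enumerate(self.aux[name]):
                out[f"aux/{name}/{i}"] = p
        for fname, adv in self.adversaries.items():
            for i, p in enumerate(adv.params):
                out[f"adv/{fname}/{i}"] = p
        return out

    def save(self, path) -> None:
        """Checkpoint: parameters (npz) + config/history (json sidecar)."""
        from pathlib import Path

        path = Path(path)
        named = self._named_params()
        np.savez(path.with_suffix(".npz"), **{k: v.data for k, v in named.items()})
        meta = {
            "config": asdict(self.config),
            "assay_features": self.assay_features,
            "factor_specs": self.factor_specs,
            "history": [
                {"kl": h.kl, "recon": h.recon, "adv": h.adv, "total": h.total}
                for h in self.history
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        config = ModelConfig(**meta["config"])
        model = cls(config, meta["assay_features"],
                    [tuple(fs) for fs in meta["factor_specs"]])
        arrays = np.load(path.with_suffix(".npz"))
        for k, p in model._named_params().items():
            p.data = arrays[k]
        for h in meta["history"]:
            model.history.append(LossBreakdown(kl=h["kl"], recon=h["recon"], adv=h["adv"]))
        return model


def build_model(config: ModelConfig, dataset: MultiomicsDataset,
                factors: list[BatchFactorDesign]) -> TrainedModel:
    """Instantiate the untrained networks for a dataset's schema."""
    families = dict(config.families)
    for a in dataset.assays:
        families.setdefault(a.name, "negative_binomial")
        if families[a.name] not in FAMILIES:
            raise KeyError(f"unknown family {families[a.name]!r} for assay {a.name!r}")
    config.families = families
    assay_features = {a.name: a.n_features for a in dataset.assays}
    factor_specs = [(f.name, f.kind, f.width) for f in factors]
    return TrainedModel(config, assay_features, factor_specs)


def _forward_losses(model: TrainedModel, dataset: MultiomicsDataset,
                    factors: list[BatchFactorDesign], rows: np.ndarray,
                    eps: np.ndarray,
                    dropout_rng: np.random.Generator | None):
    """One forward pass; returns (objective Tensor, LossBreakdown)."""
    cfg = model.config
    mu_joint, var_joint = model.joint_posterior(dataset, factors, rows, dropout_rng)
    z = mu_joint + var_joint.clip_min(VARIANCE_FLOOR).sqrt() * Tensor(eps)
    kl = kl_loss_t(mu_joint, var_joint, cfg.kl_weight)
    cov = model._covariates(factors, rows)
    objective = kl
    recon_vals: dict[str, float] = {}
    for name in model.assay_features:
        params = model.decode_assay(name, z, cov)
        fam = FAMILIES[cfg.families[name]]
        nll = fam.nll(dataset.assay(name).dense()[rows], params, dataset.masks[name][rows])
        objective = objective + nll
        recon_vals[name] = float(nll.data)
    adv_vals: dict[str, float] = {}
    if cfg.use_adversaries:
        for f in factors:
            scores = model.adversaries[f.name](grad_reverse(mu_joint, cfg.grad_reversal_scale))
            sub = BatchFactorDesign(f.name, f.kind, f.encoded[rows], f.levels)
            loss = adversarial_loss_t(sub, scores)
            # gradient reversal realises the minus sign of the total loss for
            # the main network while the adversary itself minimises its loss
            objective = objective + loss
            adv_vals[f.name] = float(loss.data)
    breakdown = LossBreakdown(kl=float(kl.data), recon=recon_vals, adv=adv_vals,
                              kl_weight=cfg.kl_weight)
    return objective, breakdown


def train(model: TrainedModel, dataset: MultiomicsDataset,
          factors: list[BatchFactorDesign], config: ModelConfig | None = None,
          log_path=None) -> TrainedModel:
    """Seeded minibatch training of the full objective.

    Records a LossBreakdown per epoch (epoch mean of minibatch components)
    and optionally appends them to a tab-delimited log.  Deterministic for a
    fixed seed.
    """
    cfg = config or model.config
    rng = np.random.default_rng(cfg.seed)
    dropout_rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params, lr=cfg.learning_rate)
    n = dataset.n_cells
    bs = min(cfg.batch_size, n)
    log_lines = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        comps: list[LossBreakdown] = []
        for start in range(0, n, bs):
            rows = order[start:start + bs]
            eps = rng.standard_normal((len(rows), cfg.latent_dim))
            objective, breakdown = _forward_losses(
                model, dataset, factors, rows, eps,
                dropout_rng if cfg.input_dropout > 0 else None)
            if not np.isfinite(objective.data):
                bad = [k for k, v in {**breakdown.recon, **breakdown.adv,
                                      "kl": breakdown.kl}.items() if not np.isfinite(v)]
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: components {bad or ['total']}")
            opt.zero_grad()
            objective.backward()
            opt.step()
            comps.append(breakdown)
        epoch_bd = LossBreakdown(
            kl=float(np.mean([c.kl for c in comps])),
            recon={k: float(np.mean([c.recon[k] for c in comps])) for k in comps[0].recon},
            adv={k: float(np.mean([c.adv[k] for c in comps])) for k in comps[0].adv},
            kl_weight=cfg.kl_weight,
        )
        model.history.append(epoch_bd)
        log_lines.append(epoch_bd)
    if log_path is not None:
        _write_log(log_lines, log_path)
    return model


def _write_log(history: list[LossBreakdown], path) -> None:
    with open(path, "w") as fh:
        recon_keys = sorted(history[0].recon) if history else []
        adv_keys = sorted(history[0].adv) if history else []
        header = ["epoch", "total", "kl"] + [f"recon_{k}" for k in recon_keys] + [
            f"adv_{k}" for k in adv_keys]
        fh.write("\t".join(header) + "\n")
        for i, h in enumerate(history):
            row = [str(i), f"{h.total:.6f}", f"{h.kl:.6f}"]
            row += [f"{h.recon[k]:.6f}" for k in recon_keys]
            row += [f"{h.adv[k]:.6f}" for k in adv_keys]
            fh.write("\t".join(row) + "\n")
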