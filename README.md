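# scpoe

Product-of-experts variational autoencoder for integrating single-cell
multiomics assays into a joint latent space, with multi-factor batch-effect
removal by covariates plus adversarial learning, native handling of missing
modalities, cross-modality imputation, and the clustering/classification
metrics needed to evaluate an integration.

## Who this is for

Analysts with matched multi-assay single-cell data — CITE-seq (RNA + ADT),
SHARE-seq (RNA + ATAC), scNMT-seq (RNA + methylome + accessibility) — who
need one embedding that captures cellular heterogeneity across all assays
while discounting several simultaneous batch factors (donor, site, age, ...),
including datasets where some cells lack some modalities entirely.

## The model

Each assay `i` gets its own encoder producing a Gaussian "expert" posterior
N(μᵢ, σᵢ²) over a shared K-dimensional latent space. Experts are combined
with a standard-normal prior by a product of experts — for Gaussians the
product is Gaussian, with precisions adding and means precision-weighted:

    1/σ²_joint = 1/σ₀² + Σᵢ 1/σᵢ²
    μ_joint    = σ²_joint · (μ₀/σ₀² + Σᵢ μᵢ/σᵢ²)

A per-assay binary mask marks missing measurements: a fully missing modality
simply drops out of the sums, and masked entries contribute exactly zero to
every loss and gradient. Each assay is reconstructed from the sampled latent
by its own decoder under a likelihood chosen per assay — negative binomial or
Poisson for counts, Bernoulli for bimodal methylation beta values, Gaussian
for continuous abundances, negative multinomial for compositional counts —
via an extensible registry.

The training objective is

    L_total = L_kl + Σᵢ L_recon(Yⁱ, Ŷⁱ) − Σⱼ L_adv(bʲ)

with the closed-form KL against N(0, I) weighted by w_kl. Every declared
batch factor bʲ (categorical one-hot or z-scored continuous) is handled
twice: injected as a covariate into every encoder and decoder, and attacked
by a small adversary network that reads μ_joint through a gradient-reversal
layer. The reversal trains the adversary to predict its factor (softmax
cross-entropy, or squared error for continuous factors) while pushing the
embedding to be uninformative about it — the minus sign above, realised in a
single optimiser step.

The networks run on a small, fully tested reverse-mode automatic
differentiation engine over numpy arrays (`scpoe.autodiff`), so the package
has no deep-learning framework dependency.

## Worked example

```python
from scpoe import (default_benchmark_config, simulate_multiomics,
                   encode_batch_factors, build_model, train, embed,
                   louvain_scan, population_auc, silhouette)
from scpoe.benchmark import benchmark_model_config, FACTOR_SPECS

cfg = default_benchmark_config(seed=1, n_cells=600)   # NB counts + Bernoulli methylation
dataset, truth = simulate_multiomics(cfg)             # 3 populations, donor + age batches
factors = encode_batch_factors(dataset.metadata, FACTOR_SPECS)
model = build_model(benchmark_model_config(seed=1), dataset, factors)
train(model, dataset, factors)                        # ~6 s on one CPU
Z = embed(model, dataset, factors)                    # 600 x 10 latent matrix

result = louvain_scan(Z, truth.populations, seed=0)
_, mean_auc = population_auc(Z, truth.populations, folds=10, seed=0)
batch_sil, _ = silhouette(Z, dataset.metadata["donor"].to_numpy())
print(f"best resolution: {result.resolution:.1f}  clusters: {result.n_clusters}")
print(f"AMI: {result.metrics['ami']:.3f}  ARI: {result.metrics['ari']:.3f}  "
      f"purity: {result.metrics['purity']:.3f}")
print(f"population AUC: {mean_auc:.3f}  batch silhouette: {batch_sil:.3f}")
```

prints

```
best resolution: 0.1  clusters: 3
AMI: 0.980  ARI: 0.989  purity: 0.997
population AUC: 0.999  batch silhouette: -0.009
```

The Louvain scan over resolutions 0.1–2.0 recovers the three planted
populations essentially perfectly (AMI/ARI/purity near 1), a linear
classifier separates them with AUC 0.999, and the batch silhouette near zero
means donors are fully mixed in the latent space — on the same data, PCA of
the uncorrected counts has a donor silhouette around +0.2.

The same pipeline is available from the shell:

```bash
scpoe simulate --seed 1 --out fixture/
scpoe train --container fixture/container.h5 \
      --factors donor:categorical,age:continuous --checkpoint ckpt
scpoe embed --container fixture/container.h5 --checkpoint ckpt \
      --factors donor:categorical,age:continuous --out latent.csv
scpoe evaluate --latent latent.csv --labels fixture/metadata.csv --out metrics.json
```

`scpoe preprocess` applies per-assay recipes (median-library-size + log1p
normalisation, CLR for ADT, coverage filters, top-K variable features,
BED-region filtering) and `scpoe impute` reconstructs a held-out modality
from the remaining ones.

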