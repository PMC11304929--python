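"""Latent embedding and cross-modality imputation from a trained model.

The embedding is the deterministic joint-posterior mean mu_joint, computed
with masks honoured in the product-of-experts combination.  Imputation
rebuilds the joint posterior from the *other* (observed) modalities only,
decodes the target assay and reports the likelihood family's mean — e.g. the
negative-binomial mean for counts or the Bernoulli probability for
methylation — which is the natural point prediction for correlation/RMSE
evaluation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import pearsonr

from .io_and_data import BatchFactorDesign, MultiomicsDataset
from .model_core import FAMILIES
from .network_and_training import TrainedModel

__all__ = ["embed", "impute", "imputation_metrics"]


def _check_schema(model: TrainedModel, dataset: MultiomicsDataset) -> None:
    for name, n_feat in model.assay_features.items():
        try:
            assay = dataset.assay(name)
        except KeyError as e:
            raise ValueError(f"dataset lacks assay {name!r} the model was trained on") from e
        if assay.n_features != n_feat:
            raise ValueError(
                f"assay {name!r} has {assay.n_features} features; model was "
                f"trained with {n_feat}"
            )


def embed(model: TrainedModel, dataset: MultiomicsDataset,
          factors: list[BatchFactorDesign] | None = None,
          batch_size: int = 2048) -> np.ndarray:
    """Cell x K matrix of joint posterior means (no sampling, no dropout)."""
    _check_schema(model, dataset)
    factors = factors or []
    rows_all = np.arange(dataset.n_cells)
    out = np.empty((dataset.n_cells, model.config.latent_dim))
    for start in range(0, dataset.n_cells, batch_size):
        rows = rows_all[start:start + batch_size]
        mu, _ = model.joint_posterior(dataset, factors, rows, dropout_rng=None)
        out[rows] = mu.data
    return out


def impute(model: TrainedModel, dataset: MultiomicsDataset, target_assay: str,
           factors: list[BatchFactorDesign] | None = None,
           masked_only: bool = True, exclude_target_expert: bool = True,
           batch_size: int = 2048):
    """Reconstruct `target_assay` from the remaining modalities.

    Returns ``(values, eval_mask)`` where `eval_mask` marks the masked-out
    entries of the target assay.  With ``masked_only`` the full predicted
    matrix is still returned; callers evaluate on `eval_mask`.  By default
    the target's own expert is excluded from the product of experts even for
    cells where it is partially observed, mirroring a held-out-modality
    protocol; set ``exclude_target_expert=False`` to keep it.
    """
    _check_schema(model, dataset)
    if target_assay not in model.assay_features:
        raise KeyError(f"model has no assay {target_assay!r}")
    factors = factors or []
    eval_mask = 1.0 - dataset.masks[target_assay]
    if masked_only and eval_mask.sum() == 0:
        warnings.warn(f"assay {target_assay!r} is fully observed; nothing to impute")
    exclude = {target_assay} if exclude_target_expert else None
    n = dataset.n_cells
    pred = np.empty((n, model.assay_features[target_assay]))
    rows_all = np.arange(n)
    fam = FAMILIES[model.config.families[target_assay]]
    for start in range(0, n, batch_size):
        rows = rows_all[start:start + batch_size]
        mu, _ = model.joint_posterior(dataset, factors, rows, dropout_rng=None,
                                      exclude=exclude)
        cov = model._covariates(factors, rows)
        params = model.decode_assay(target_assay, mu, cov)
        pred[rows] = fam.mean(params)
    return pred, eval_mask


def imputation_metrics(predicted: np.ndarray, truth: np.ndarray,
                       eval_mask: np.ndarray) -> tuple[float, float]:
    """Pearson r and RMSE over the held-out (eval_mask == 1) entries."""
    predicted = np.asarray(predicted, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if predicted.shape != truth.shape or predicted.shape != eval_mask.shape:
        raise ValueError("predicted, truth and eval_mask shapes must match")
    sel = np.asarray(eval_mask) > 0
    if sel.sum() < 2:
        raise ValueError("need at least 2 held-out entries to evaluate")
    p, t = predicted[sel], truth[sel]
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    if np.std(p) == 0 or np.std(t) == 0:
        r = 0.0
    else:
        r = float(pearsonr(p, t)[0])
    return r, rmse
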