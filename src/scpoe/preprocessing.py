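"""Per-assay preprocessing: depth normalisation, CLR, coverage filters,
variable-feature selection and genomic-region filtering.

Count assays (RNA, ATAC) are depth-normalised by median-library-size scaling
and log1p-transformed; antibody-derived tags get the centred log-ratio
transform standard for compositional abundance data.  Sparse assays are
filtered by the fraction or absolute number of cells in which a feature is
observed, then reduced to the top-K most variable features.  Methylation and
accessibility features can additionally be restricted to user-supplied
genomic regions (promoters/enhancers) given as BED intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_and_data import AssayMatrix

__all__ = [
    "PreprocessRecipe",
    "size_factor_log1p",
    "clr_transform",
    "filter_low_coverage",
    "filter_min_cells",
    "select_top_variable",
    "filter_by_regions",
    "read_bed",
    "apply_recipe",
]


@dataclass
class PreprocessRecipe:
    """Declarative per-assay preprocessing plan, applied in the order:
    region filter -> coverage/min-cell filters -> normalisation -> top-K."""

    normalisation: str = "none"  # none | size_factor_log1p | clr
    min_cell_fraction: float = 0.0
    min_cells: int = 0
    top_k_features: int | float | None = None
    region_bed: str | None = None
    clr_pseudocount: float = 1.0

    def __post_init__(self):
        if self.normalisation not in ("none", "size_factor_log1p", "clr"):
            raise ValueError(f"unknown normalisation {self.normalisation!r}")
        if not 0.0 <= self.min_cell_fraction <= 1.0:
            raise ValueError("min_cell_fraction must lie in [0, 1]")


def size_factor_log1p(counts: np.ndarray | sp.spmatrix) -> np.ndarray:
    """Scale each cell to the median library size, then log(1+x).

    x_cf -> log1p(x_cf * median(L) / L_c) with L_c the cell's total count.
    A depth correction of the same intent as pooled-deconvolution size
    factors, but fully specified and dependency-free.
    """
    X = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=np.float64)
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    lib = X.sum(axis=1)
    zero = np.where(lib == 0)[0]
    if len(zero):
        raise ValueError(f"all-zero cells at rows {zero.tolist()[:20]}")
    factors = np.median(lib) / lib
    return np.log1p(X * factors[:, None])


def clr_transform(values: np.ndarray | sp.spmatrix, pseudocount: float = 1.0) -> np.ndarray:
    """Centred log-ratio per cell: y_f = log(x_f + c) - mean_f log(x_f + c)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    X = values.toarray() if sp.issparse(values) else np.asarray(values, dtype=np.float64)
    if np.any(X < 0):
        raise ValueError("CLR input must be non-negative")
    logged = np.log(X + pseudocount)
    return logged - logged.mean(axis=1, keepdims=True)


def _nonzero_cells_per_feature(assay: AssayMatrix) -> np.ndarray:
    if sp.issparse(assay.values):
        return np.asarray((assay.values != 0).sum(axis=0)).ravel()
    return (np.asarray(assay.values) != 0).sum(axis=0)


def filter_low_coverage(assay: AssayMatrix, min_cell_fraction: float) -> AssayMatrix:
    """Drop features observed in fewer than ceil(fraction * n_cells) cells.

    Features at exactly the threshold are kept ("fewer than" are excluded).
    """
    if not 0.0 <= min_cell_fraction <= 1.0:
        raise ValueError("min_cell_fraction must lie in [0, 1]")
    threshold = int(np.ceil(min_cell_fraction * assay.n_cells))
    keep = np.where(_nonzero_cells_per_feature(assay) >= threshold)[0]
    return assay.subset_features(keep)


def filter_min_cells(assay: AssayMatrix, min_cells: int) -> AssayMatrix:
    """Drop features observed in fewer than `min_cells` cells (>= kept)."""
    keep = np.where(_nonzero_cells_per_feature(assay) >= min_cells)[0]
    return assay.subset_features(keep)


def select_top_variable(assay: AssayMatrix, k: int | float) -> AssayMatrix:
    """Keep the k features of largest variance (population 1/n denominator).

    Fractional k in (0, 1] selects floor(k * n_features) features.  Ties are
    broken by original feature order so the selection is reproducible.
    """
    n_feat = assay.n_features
    if isinstance(k, float) and 0 < k <= 1:
        k = int(np.floor(k * n_feat))
    k = int(k)
    if k < 1 or k > n_feat:
        raise ValueError(f"k={k} outside [1, {n_feat}]")
    X = assay.dense()
    variances = X.var(axis=0)  # population denominator
    # stable sort on -variance keeps original order among ties
    order = np.argsort(-variances, kind="stable")[:k]
    keep = np.sort(order)  # preserve original feature order in the output
    return assay.subset_features(keep)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (>=3 columns, 0-based half-open)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    bed.columns = ["chrom", "start", "end"]
    return bed


def filter_by_regions(assay: AssayMatrix, regions: pd.DataFrame) -> AssayMatrix:
    """Keep features whose interval overlaps at least one region.

    Both feature coordinates and regions are 0-based half-open; touching
    endpoints do not overlap.
    """
    from intervaltree import IntervalTree

    if assay.feature_coords is None:
        raise ValueError(
            f"assay {assay.name!r} has no feature_coords; supply genomic "
            "intervals to use region filtering"
        )
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in regions.groupby("chrom"):
        t = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            if e > s:
                t[int(s):int(e)] = True
        trees[str(chrom)] = t
    coords = assay.feature_coords
    keep = [
        i
        for i in range(assay.n_features)
        if str(coords["chrom"].iloc[i]) in trees
        and trees[str(coords["chrom"].iloc[i])].overlap(
            int(coords["start"].iloc[i]), int(coords["end"].iloc[i])
        )
    ]
    return assay.subset_features(np.array(keep, dtype=int))


def apply_recipe(assay: AssayMatrix, recipe: PreprocessRecipe) -> tuple[AssayMatrix, dict]:
    """Run a full recipe; returns the processed assay and a drop report."""
    report = {"initial": assay.n_features}
    if recipe.region_bed is not None:
        assay = filter_by_regions(assay, read_bed(recipe.region_bed))
        report["after_region_filter"] = assay.n_features
    if recipe.min_cell_fraction > 0:
        assay = filter_low_coverage(assay, recipe.min_cell_fraction)
        report["after_coverage_filter"] = assay.n_features
    if recipe.min_cells > 0:
        assay = filter_min_cells(assay, recipe.min_cells)
        report["after_min_cells_filter"] = assay.n_features
    if recipe.normalisation == "size_factor_log1p":
        values = size_factor_log1p(assay.values)
        assay = AssayMatrix(assay.name, values, assay.feature_ids, assay.cell_ids, assay.feature_coords)
    elif recipe.normalisation == "clr":
        values = clr_transform(assay.values, recipe.clr_pseudocount)
        assay = AssayMatrix(assay.name, values, assay.feature_ids, assay.cell_ids, assay.feature_coords)
    if recipe.top_k_features is not None:
        assay = select_top_variable(assay, recipe.top_k_features)
        report["after_top_k"] = assay.n_features
    report["final"] = assay.n_features
    return assay, report
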