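"""Data containers and readers for multi-assay single-cell experiments.

An experiment is a set of per-assay cell x feature matrices (RNA counts, ATAC
counts, antibody-derived-tag abundances, methylation beta values, ...) sharing
a cell population, a per-cell metadata table carrying batch factors and
optional population labels, and per-assay binary masks marking missing
measurements.  The metadata table defines the canonical cell order; assays are
reindexed to it and cells an assay never measured become all-zero mask rows,
so downstream code sees a single mask code path for both entrywise and
whole-modality missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

__all__ = [
    "AssayMatrix",
    "MultiomicsDataset",
    "BatchFactorDesign",
    "load_assay",
    "assemble_dataset",
    "encode_batch_factors",
    "save_dataset",
    "load_dataset",
]

@dataclass
class AssayMatrix:
    """One assay: a cell x feature matrix plus identifiers.

    `values` may be dense or scipy-sparse; sparsity is preserved until the
    model densifies per minibatch.  `feature_coords` optionally holds genomic
    intervals (chrom, start, end) per feature for region filtering.
    """

    name: str
    values: np.ndarray | sp.spmatrix
    feature_ids: list[str]
    cell_ids: list[str] | None = None
    feature_coords: pd.DataFrame | None = None  # columns chrom, start, end

    def __post_init__(self):
        if len(set(self.feature_ids)) != len(self.feature_ids):
            from collections import Counter

            dups = sorted(f for f, c in Counter(self.feature_ids).items() if c > 1)
            raise ValueError(f"duplicate feature ids in assay {self.name!r}: {dups}")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"assay {self.name!r}: {self.values.shape[1]} columns but "
                f"{len(self.feature_ids)} feature ids"
            )
        if (sp.issparse(self.values) and (self.values < 0).nnz > 0) or (
            not sp.issparse(self.values) and np.any(np.asarray(self.values) < 0)
        ):
            # negative entries are only legal for real-valued families; callers
            # declare the family later, so just record the fact here
            self.has_negative = True
        else:
            self.has_negative = False

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    def subset_features(self, index: np.ndarray) -> "AssayMatrix":
        """Column subset preserving order; index is positional."""
        coords = None
        if self.feature_coords is not None:
            coords = self.feature_coords.iloc[index].reset_index(drop=True)
        vals = self.values.tocsc()[:, index].tocsr() if sp.issparse(self.values) else self.values[:, index]
        return AssayMatrix(
            name=self.name,
            values=vals,
            feature_ids=[self.feature_ids[i] for i in index],
            cell_ids=self.cell_ids,
            feature_coords=coords,
        )


@dataclass
class MultiomicsDataset:
    """Aligned multi-assay container: the unit every stage consumes."""

    cell_ids: list[str]
    assays: list[AssayMatrix]
    masks: dict[str, np.ndarray]  # assay name -> cell x feature 0/1
    metadata: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self):
        n = len(self.cell_ids)
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids are not unique")
        for a in self.assays:
            if a.n_cells != n:
                raise ValueError(f"assay {a.name!r} has {a.n_cells} cells, dataset has {n}")
            m = self.masks[a.name]
            if m.shape != (n, a.n_features):
                raise ValueError(
                    f"mask for assay {a.name!r} has shape {m.shape}, "
                    f"expected {(n, a.n_features)}"
                )
            vals = np.unique(m)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError(f"mask for assay {a.name!r} is not binary")
        if len(self.metadata) != n:
            raise ValueError("metadata row count does not match cell count")
        observed = np.zeros(n, dtype=bool)
        for a in self.assays:
            observed |= self.masks[a.name].any(axis=1)
        if not observed.all():
            bad = [self.cell_ids[i] for i in np.where(~observed)[0][:10]]
            raise ValueError(f"no observed modality for cells {bad}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def assay(self, name: str) -> AssayMatrix:
        for a in self.assays:
            if a.name == name:
                return a
        raise KeyError(f"no assay named {name!r}")

    def modality_present(self, name: str) -> np.ndarray:
        """Per-cell 0/1: does the assay have any observed entry for the cell."""
        return self.masks[name].any(axis=1).astype(np.float64)


@dataclass
class BatchFactorDesign:
    """Encoded batch factor: one-hot (categorical) or z-scored column (continuous)."""

    name: str
    kind: str  # "categorical" | "continuous"
    encoded: np.ndarray  # cell x width
    levels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown batch factor kind {self.kind!r}")
        if self.kind == "categorical":
            sums = self.encoded.sum(axis=1)
            if not np.allclose(sums, 1.0):
                raise ValueError(f"one-hot rows of factor {self.name!r} do not sum to 1")
        if not np.all(np.isfinite(self.encoded)):
            raise ValueError(f"non-finite values in design for factor {self.name!r}")

    @property
    def width(self) -> int:
        return self.encoded.shape[1]


# ---------------------------------------------------------------------------
# readers


def load_assay(path, format: str, assay_name: str) -> AssayMatrix:
    """Read one assay from disk.

    Formats: ``mtx`` (Matrix Market with ``features.tsv``/``barcodes.tsv``
    sidecars next to the .mtx, cells as rows), ``delimited`` (comma or tab,
    header row, first column = cell id), ``hdf5`` (an .h5ad file or a
    container written by :func:`save_dataset`).
    """
    from pathlib import Path

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        try:
            mat = mmread(str(path))
        except Exception as e:  # noqa: BLE001 - surface as format error
            raise ValueError(f"cannot parse {path} as Matrix Market: {e}") from e
        features = path.parent / "features.tsv"
        barcodes = path.parent / "barcodes.tsv"
        feature_ids = (
            pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
            if features.exists()
            else [f"f{i}" for i in range(mat.shape[1])]
        )
        cell_ids = (
            pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
            if barcodes.exists()
            else None
        )
        return AssayMatrix(assay_name, sp.csr_matrix(mat), feature_ids, cell_ids)
    if format == "delimited":
        sep = "\t" if path.suffix in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return AssayMatrix(
            assay_name,
            df.to_numpy(dtype=np.float64),
            [str(c) for c in df.columns],
            [str(i) for i in df.index],
        )
    if format == "hdf5":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if sp.issparse(X):
            X = sp.csr_matrix(X)
        coords = None
        if {"chrom", "start", "end"}.issubset(adata.var.columns):
            coords = adata.var[["chrom", "start", "end"]].reset_index(drop=True)
        return AssayMatrix(
            assay_name,
            X,
            [str(v) for v in adata.var_names],
            [str(o) for o in adata.obs_names],
            feature_coords=coords,
        )
    raise ValueError(f"unknown format {format!r}")


def assemble_dataset(
    assays: list[AssayMatrix],
    metadata: pd.DataFrame,
    masks: dict[str, np.ndarray] | None = None,
) -> MultiomicsDataset:
    """Align assays to the metadata's cell order and build the container.

    Metadata's index is the canonical cell order.  Cells an assay lacks get
    zero-filled rows with an all-zero mask; absent masks default to all ones.
    Assay cells absent from metadata are dropped.
    """
    cell_ids = [str(c) for c in metadata.index]
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("metadata index has duplicate cell ids")
    masks = dict(masks or {})
    aligned_assays, aligned_masks = [], {}
    for a in assays:
        if a.cell_ids is None:
            if a.n_cells != len(cell_ids):
                raise ValueError(
                    f"assay {a.name!r} has no cell ids and its row count "
                    f"differs from metadata"
                )
            pos = np.arange(len(cell_ids))
            covered = np.ones(len(cell_ids), dtype=bool)
        else:
            lookup = {c: i for i, c in enumerate(a.cell_ids)}
            if not any(c in lookup for c in cell_ids):
                raise ValueError(f"assay {a.name!r} shares no cells with metadata")
            covered = np.array([c in lookup for c in cell_ids])
            pos = np.array([lookup.get(c, 0) for c in cell_ids])
        dense_or_sparse = a.values
        if sp.issparse(dense_or_sparse):
            vals = dense_or_sparse.tocsr()[pos]
            zero_rows = np.where(~covered)[0]
            if len(zero_rows):
                keep = sp.diags(covered.astype(np.float64))
                vals = (keep @ vals).tocsr()
        else:
            vals = np.asarray(dense_or_sparse)[pos].copy()
            vals[~covered] = 0
        m = masks.get(a.name)
        if m is None:
            m = np.ones((len(cell_ids), a.n_features))
        else:
            m = np.asarray(m, dtype=np.float64)
            if m.ndim == 1 or m.shape[1] == 1:  # per-cell whole-modality flag
                m = np.broadcast_to(m.reshape(-1, 1), (len(cell_ids), a.n_features)).copy()
            if m.shape[0] == len(a.cell_ids or cell_ids) and a.cell_ids is not None:
                m = m[pos]
            if m.shape != (len(cell_ids), a.n_features):
                raise ValueError(f"mask shape mismatch for assay {a.name!r}")
        m = m * covered[:, None]
        aligned_assays.append(
            AssayMatrix(a.name, vals, list(a.feature_ids), cell_ids, a.feature_coords)
        )
        aligned_masks[a.name] = m
    return MultiomicsDataset(cell_ids, aligned_assays, aligned_masks, metadata.copy())


def encode_batch_factors(
    metadata: pd.DataFrame, factor_specs: list[tuple[str, str]]
) -> list[BatchFactorDesign]:
    """Encode each declared batch factor independently.

    Categorical columns become one-hot designs over lexicographically ordered
    observed levels; continuous columns become a single z-scored column
    (population standard deviation).  Factors are never merged into a
    cross-product: each is corrected on its own.
    """
    designs = []
    for column, kind in factor_specs:
        if column not in metadata.columns:
            raise KeyError(f"metadata has no column {column!r}")
        col = metadata[column]
        if kind == "categorical":
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(
                    f"factor {column!r} has a single level: no variation to correct"
                )
            enc = np.zeros((len(col), len(levels)))
            idx = {lv: i for i, lv in enumerate(levels)}
            for r, v in enumerate(col.astype(str)):
                enc[r, idx[v]] = 1.0
            designs.append(BatchFactorDesign(column, "categorical", enc, levels))
        elif kind == "continuous":
            vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=np.float64)
            if np.any(np.isnan(vals)):
                raise ValueError(f"continuous factor {column!r} is not numeric")
            sd = vals.std()  # population sd
            z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
            designs.append(BatchFactorDesign(column, "continuous", z.reshape(-1, 1)))
        else:
            raise ValueError(f"unknown factor kind {kind!r}")
    return designs


# ---------------------------------------------------------------------------
# HDF5 container (deterministic writes: no HDF5 object timestamps)


def save_dataset(dataset: MultiomicsDataset, path) -> None:
    """Write the container to one HDF5 file with deterministic bytes.

    Layout: per-assay groups holding X (dense) and mask, feature ids and
    optional coordinates; a metadata group of per-column arrays; cell ids at
    the root.  Timestamp tracking is disabled so identical content yields
    identical files.
    """
    import h5py

    str_dt = h5py.string_dtype(encoding="utf-8")

    # disable HDF5 object-header timestamps everywhere (root group, groups,
    # datasets) so identical content always yields identical bytes
    fcpl = h5py.h5p.create(h5py.h5p.FILE_CREATE)
    fcpl.set_obj_track_times(False)
    fid = h5py.h5f.create(str(path).encode(), fcpl=fcpl)

    def make_group(parent, name):
        gcpl = h5py.h5p.create(h5py.h5p.GROUP_CREATE)
        gcpl.set_obj_track_times(False)
        return h5py.Group(h5py.h5g.create(parent.id, name.encode(), gcpl=gcpl))

    with h5py.File(fid) as f:

        def write(group, name, data):
            group.create_dataset(name, data=data, track_times=False)

        write(f, "cell_ids", np.array(dataset.cell_ids, dtype=str_dt))
        write(f, "assay_order", np.array([a.name for a in dataset.assays], dtype=str_dt))
        ag = make_group(f, "assays")
        for a in dataset.assays:
            g = make_group(ag, a.name)
            write(g, "X", a.dense())
            write(g, "mask", dataset.masks[a.name])
            write(g, "feature_ids", np.array(a.feature_ids, dtype=str_dt))
            if a.feature_coords is not None:
                write(g, "chrom", np.array(a.feature_coords["chrom"].astype(str), dtype=str_dt))
                write(g, "start", a.feature_coords["start"].to_numpy(dtype=np.int64))
                write(g, "end", a.feature_coords["end"].to_numpy(dtype=np.int64))
        mg = make_group(f, "metadata")
        for col in dataset.metadata.columns:
            series = dataset.metadata[col]
            if pd.api.types.is_numeric_dtype(series):
                write(mg, col, series.to_numpy(dtype=np.float64))
            else:
                write(mg, col, np.array(series.astype(str), dtype=str_dt))
        write(f, "metadata_columns", np.array(list(dataset.metadata.columns), dtype=str_dt))


def load_dataset(path) -> MultiomicsDataset:
    """Read a container written by :func:`save_dataset`."""
    import h5py

    with h5py.File(path, "r") as f:
        cell_ids = [c.decode() for c in f["cell_ids"][:]]
        assays, masks = [], {}
        order = [n.decode() for n in f["assay_order"][:]] if "assay_order" in f \
            else sorted(f["assays"])
        for name in order:
            g = f["assays"][name]
            coords = None
            if "chrom" in g:
                coords = pd.DataFrame(
                    {
                        "chrom": [c.decode() for c in g["chrom"][:]],
                        "start": g["start"][:],
                        "end": g["end"][:],
                    }
                )
            assays.append(
                AssayMatrix(
                    name,
                    g["X"][:],
                    [x.decode() for x in g["feature_ids"][:]],
                    cell_ids,
                    feature_coords=coords,
                )
            )
            masks[name] = g["mask"][:]
        cols = [c.decode() for c in f["metadata_columns"][:]]
        meta = {}
        for col in cols:
            arr = f["metadata"][col][:]
            if arr.dtype.kind in ("S", "O"):
                arr = np.array([x.decode() for x in arr])
            meta[col] = arr
        metadata = pd.DataFrame(meta, index=pd.Index(cell_ids))
    return MultiomicsDataset(cell_ids, assays, masks, metadata)
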