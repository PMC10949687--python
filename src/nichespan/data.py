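"""Core data containers and tabular I/O for multi-slice spatial data.

A *slice* is one spatially resolved tissue section: per-observation 2-D
coordinates plus a cell-type annotation.  At single-cell resolution the
annotation is a one-hot matrix (one categorical label per cell); at spot
resolution it is a per-spot cell-type proportion matrix, typically produced
upstream by a deconvolution tool.  Multiple slices are analysed jointly and
must share one ordered cell-type vocabulary; the union of types across
slices is taken in lexicographic order and missing types are zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationMatrix",
    "SpatialSlice",
    "MultiSliceSet",
    "read_slices",
    "read_h5ad_slices",
    "write_assignment",
    "read_assignment",
    "log_normalize",
]

#: tolerance for "rows sum to one" checks on annotation / embedding rows
SIMPLEX_ATOL = 1e-8
#: proportion rows whose sum deviates from 1 by no more than this are
#: silently renormalized; larger deviations are treated as data errors
RENORM_TOL = 1e-3


def _as_float_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class AnnotationMatrix:
    """Per-observation cell-type composition (rows on the probability simplex).

    Parameters
    ----------
    values
        ``(n, T)`` nonnegative matrix; every row sums to 1.
    cell_types
        Ordered list of the ``T`` cell-type names (unique).
    """

    values: np.ndarray
    cell_types: tuple[str, ...]

    def __post_init__(self):
        values = _as_float_matrix(self.values, "annotation values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_types", tuple(str(c) for c in self.cell_types))
        if values.shape[1] != len(self.cell_types):
            raise ValueError(
                f"annotation has {values.shape[1]} columns but "
                f"{len(self.cell_types)} cell types"
            )
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell type names must be unique")
        if np.any(values < 0):
            raise ValueError("annotation proportions must be nonnegative")
        sums = values.sum(axis=1)
        if values.shape[0] and not np.allclose(sums, 1.0, atol=SIMPLEX_ATOL, rtol=0):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"annotation row {bad} sums to {sums[bad]:.6g}, expected 1"
            )

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def is_one_hot(self) -> bool:
        v = self.values
        return bool(np.all((v == 0) | (v == 1)) and np.all(v.sum(axis=1) == 1))

    @classmethod
    def from_labels(
        cls, labels: Sequence[str], cell_types: Sequence[str] | None = None
    ) -> "AnnotationMatrix":
        """One-hot encode categorical labels.

        When ``cell_types`` is omitted the lexicographically sorted set of
        observed labels is used.
        """
        labels = [str(x) for x in labels]
        if cell_types is None:
            cell_types = sorted(set(labels))
        cell_types = [str(c) for c in cell_types]
        index = {c: j for j, c in enumerate(cell_types)}
        values = np.zeros((len(labels), len(cell_types)))
        for i, lab in enumerate(labels):
            if lab not in index:
                raise ValueError(f"label {lab!r} not in cell_types")
            values[i, index[lab]] = 1.0
        return cls(values, tuple(cell_types))

    def labels(self) -> np.ndarray:
        """Categorical labels (argmax per row); meant for one-hot matrices."""
        idx = np.argmax(self.values, axis=1)
        return np.array([self.cell_types[j] for j in idx], dtype=object)

    def reindexed(self, cell_types: Sequence[str]) -> "AnnotationMatrix":
        """Reorder columns to ``cell_types``, zero-filling missing types.

        Types present in ``self`` but absent from ``cell_types`` are not
        allowed (mass would be lost).
        """
        cell_types = [str(c) for c in cell_types]
        missing = set(self.cell_types) - set(cell_types)
        if missing:
            raise ValueError(f"cell types {sorted(missing)} absent from target ordering")
        out = np.zeros((self.n_obs, len(cell_types)))
        pos = {c: j for j, c in enumerate(cell_types)}
        for j, c in enumerate(self.cell_types):
            out[:, pos[c]] = self.values[:, j]
        return AnnotationMatrix(out, tuple(cell_types))


@dataclass(frozen=True)
class SpatialSlice:
    """One tissue slice: coordinates plus a cell-type annotation.

    ``resolution`` is ``"single_cell"`` (one-hot annotation rows) or
    ``"spot"`` (proportion rows).  ``expression`` optionally carries a raw
    ``(n, g)`` count matrix used only by perturbation utilities.
    """

    slice_id: str
    obs_ids: tuple[str, ...]
    coords: np.ndarray
    annotation: AnnotationMatrix
    resolution: str
    expression: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "slice_id", str(self.slice_id))
        object.__setattr__(self, "obs_ids", tuple(str(o) for o in self.obs_ids))
        coords = _as_float_matrix(self.coords, "coords")
        if coords.shape[1] != 2:
            raise ValueError("coords must have exactly two columns (x, y)")
        object.__setattr__(self, "coords", coords)
        n = coords.shape[0]
        if len(self.obs_ids) != n or self.annotation.n_obs != n:
            raise ValueError(
                f"inconsistent lengths in slice {self.slice_id!r}: "
                f"{len(self.obs_ids)} obs ids, {n} coordinate rows, "
                f"{self.annotation.n_obs} annotation rows"
            )
        if len(set(self.obs_ids)) != n:
            raise ValueError(f"duplicate observation ids in slice {self.slice_id!r}")
        if self.resolution not in ("single_cell", "spot"):
            raise ValueError("resolution must be 'single_cell' or 'spot'")
        if self.resolution == "single_cell" and not self.annotation.is_one_hot():
            raise ValueError(
                "single-cell resolution requires one-hot annotation rows"
            )
        if self.expression is not None:
            expr = np.asarray(self.expression, dtype=float)
            if expr.shape[0] != n:
                raise ValueError("expression row count does not match observations")
            if np.any(expr < 0):
                raise ValueError("expression must be nonnegative")
            object.__setattr__(self, "expression", expr)

    @property
    def n_obs(self) -> int:
        return self.coords.shape[0]

    @property
    def cell_types(self) -> tuple[str, ...]:
        return self.annotation.cell_types


@dataclass(frozen=True)
class MultiSliceSet:
    """An ordered collection of slices sharing one cell-type vocabulary."""

    slices: tuple[SpatialSlice, ...]

    def __post_init__(self):
        slices = tuple(self.slices)
        object.__setattr__(self, "slices", slices)
        if not slices:
            raise ValueError("MultiSliceSet requires at least one slice")
        ids = [s.slice_id for s in slices]
        if len(set(ids)) != len(ids):
            raise ValueError("slice ids must be unique")
        ref = slices[0].cell_types
        for s in slices[1:]:
            if s.cell_types != ref:
                raise ValueError(
                    f"slice {s.slice_id!r} has cell types {s.cell_types}, "
                    f"expected {ref}; use MultiSliceSet.harmonized()"
                )

    @classmethod
    def harmonized(cls, slices: Iterable[SpatialSlice]) -> "MultiSliceSet":
        """Build a set after aligning all slices to the lexicographic union
        of their cell types (missing types zero-filled)."""
        slices = list(slices)
        union = sorted(set().union(*(s.cell_types for s in slices)))
        aligned = [
            SpatialSlice(
                s.slice_id,
                s.obs_ids,
                s.coords,
                s.annotation.reindexed(union),
                s.resolution,
                s.expression,
            )
            for s in slices
        ]
        return cls(tuple(aligned))

    @property
    def cell_types(self) -> tuple[str, ...]:
        return self.slices[0].cell_types

    @property
    def slice_ids(self) -> tuple[str, ...]:
        return tuple(s.slice_id for s in self.slices)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.slices)

    @property
    def obs_ids(self) -> np.ndarray:
        return np.concatenate([np.array(s.obs_ids, dtype=object) for s in self.slices])

    @property
    def slice_of(self) -> np.ndarray:
        """Per-observation slice id, in concatenation order."""
        return np.concatenate(
            [np.full(s.n_obs, s.slice_id, dtype=object) for s in self.slices]
        )

    def __iter__(self):
        return iter(self.slices)

    def __len__(self) -> int:
        return len(self.slices)


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_slices(coords_table, annotation_table, resolution: str) -> MultiSliceSet:
    """Read a multi-slice data set from two delimited tables.

    ``coords_table`` must provide columns ``obs_id, x, y, slice_id``.
    ``annotation_table`` is keyed by ``obs_id`` and carries either a single
    categorical label column (single-cell resolution) or one proportion
    column per cell type (spot resolution; rows are renormalized when their
    sum is within ``1e-3`` of 1, otherwise an error is raised).

    Observation order follows ``coords_table``; slices are emitted in order
    of first appearance.  CSV vs TSV is chosen by file extension.
    """
    coords = _read_table(coords_table)
    ann = _read_table(annotation_table)
    for col in ("obs_id", "x", "y", "slice_id"):
        if col not in coords.columns:
            raise ValueError(f"coordinate table is missing column {col!r}")
    if "obs_id" not in ann.columns:
        raise ValueError("annotation table is missing column 'obs_id'")
    coords = coords.assign(
        obs_id=coords["obs_id"].astype(str), slice_id=coords["slice_id"].astype(str)
    )
    ann = ann.assign(obs_id=ann["obs_id"].astype(str))
    dup = coords["obs_id"][coords["obs_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate obs_id in coordinate table: {dup.iloc[0]!r}")
    if ann["obs_id"].duplicated().any():
        bad = ann["obs_id"][ann["obs_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate obs_id in annotation table: {bad!r}")
    ann = ann.set_index("obs_id")
    missing = coords.loc[~coords["obs_id"].isin(ann.index), "obs_id"]
    if len(missing):
        raise ValueError(
            f"obs_id {missing.iloc[0]!r} from the coordinate table has no "
            "annotation row"
        )
    ann = ann.loc[coords["obs_id"]]

    value_cols = [c for c in ann.columns]
    numeric = all(pd.api.types.is_numeric_dtype(ann[c]) for c in value_cols)
    label_mode = len(value_cols) == 1 and (resolution == "single_cell" or not numeric)

    if label_mode:
        labels_all = ann[value_cols[0]].astype(str).to_numpy()
        union = sorted(set(labels_all))

        def build(mask) -> AnnotationMatrix:
            return AnnotationMatrix.from_labels(labels_all[mask], union)

    else:
        cols = sorted(value_cols)
        props = ann[cols].to_numpy(dtype=float)
        if np.any(props < 0):
            raise ValueError("negative cell-type proportions in annotation table")
        sums = props.sum(axis=1)
        off = np.abs(sums - 1.0)
        if np.any(off > RENORM_TOL + 1e-12):
            bad = int(np.argmax(off))
            raise ValueError(
                f"annotation row for obs_id {ann.index[bad]!r} sums to "
                f"{sums[bad]:.6g}; at most {RENORM_TOL} deviation from 1 is "
                "renormalized silently"
            )
        props = props / sums[:, None]

        def build(mask) -> AnnotationMatrix:
            return AnnotationMatrix(props[mask], tuple(cols))

    slices = []
    for sid in coords["slice_id"].drop_duplicates():
        mask = (coords["slice_id"] == sid).to_numpy()
        sub = coords.loc[mask]
        slices.append(
            SpatialSlice(
                slice_id=sid,
                obs_ids=tuple(sub["obs_id"]),
                coords=sub[["x", "y"]].to_numpy(dtype=float),
                annotation=build(mask),
                resolution=resolution,
            )
        )
    return MultiSliceSet(tuple(slices))


def read_h5ad_slices(
    path,
    resolution: str,
    annotation_key: str = "cell_type",
    slice_key: str = "slice_id",
    spatial_key: str = "spatial",
) -> MultiSliceSet:
    """Read slices from an AnnData (.h5ad) container.

    Coordinates are taken from ``obsm[spatial_key]`` (first two columns),
    the slice membership from ``obs[slice_key]``, and the annotation either
    from the categorical ``obs[annotation_key]`` column (single-cell) or
    from the ``obsm[annotation_key]`` proportion matrix (spot resolution,
    with ``uns[annotation_key + "_columns"]`` naming the cell types).
    """
    import anndata as ad

    adata = ad.read_h5ad(path)
    if spatial_key not in adata.obsm:
        raise ValueError(f"obsm[{spatial_key!r}] not found")
    coords = np.asarray(adata.obsm[spatial_key])[:, :2].astype(float)
    if slice_key not in adata.obs:
        raise ValueError(f"obs[{slice_key!r}] not found")
    slice_ids = adata.obs[slice_key].astype(str).to_numpy()
    obs_ids = adata.obs_names.astype(str).to_numpy()

    if annotation_key in adata.obs:
        labels = adata.obs[annotation_key].astype(str).to_numpy()
        union = sorted(set(labels))
        get_ann = lambda m: AnnotationMatrix.from_labels(labels[m], union)
    elif annotation_key in adata.obsm:
        props = np.asarray(adata.obsm[annotation_key], dtype=float)
        cols = list(adata.uns.get(annotation_key + "_columns", []))
        if len(cols) != props.shape[1]:
            cols = [f"type_{j}" for j in range(props.shape[1])]
        props = props / props.sum(axis=1, keepdims=True)
        get_ann = lambda m: AnnotationMatrix(props[m], tuple(cols))
    else:
        raise ValueError(f"annotation {annotation_key!r} not found in obs or obsm")

    slices = []
    for sid in pd.unique(slice_ids):
        m = slice_ids == sid
        slices.append(
            SpatialSlice(sid, tuple(obs_ids[m]), coords[m], get_ann(m), resolution)
        )
    return MultiSliceSet(tuple(slices))


def write_assignment(assignment, mset: MultiSliceSet, path) -> None:
    """Write a per-observation domain assignment table.

    Columns: ``obs_id, slice_id, domain_label, domain_name``; rows follow
    the concatenated observation order of ``mset``.
    """
    if len(assignment.labels) != mset.n_obs:
        raise ValueError(
            f"assignment covers {len(assignment.labels)} observations but the "
            f"slice set has {mset.n_obs}"
        )
    df = pd.DataFrame(
        {
            "obs_id": mset.obs_ids,
            "slice_id": mset.slice_of,
            "domain_label": assignment.labels,
            "domain_name": assignment.names,
        }
    )
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def read_assignment(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_assignment`."""
    df = _read_table(path)
    for col in ("obs_id", "slice_id", "domain_label", "domain_name"):
        if col not in df.columns:
            raise ValueError(f"assignment table is missing column {col!r}")
    return df.assign(
        obs_id=df["obs_id"].astype(str),
        slice_id=df["slice_id"].astype(str),
        domain_label=df["domain_label"].astype(int),
        domain_name=df["domain_name"].astype(str),
    )


def log_normalize(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Library-size normalize and log-transform a count matrix.

    Each row is divided by its total, multiplied by ``scale`` and mapped
    through ``log1p``.  Provided as an optional preprocessing utility; the
    domain-analysis pipeline itself consumes annotations, not expression.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * scale)
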