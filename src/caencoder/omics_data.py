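"""Multi-omics data model: loading, categorical encoding, z-scoring, CV folds.

The canonical containers are :class:`OmicsModality` (one samples × features
matrix) and :class:`MultiOmicsDataset` (several modalities aligned on the same
samples, plus class labels).  Preprocessing is deliberately leakage-free:
categorical mappings and z-score statistics are fitted on training rows only
and carried in small records so held-out rows can be transformed identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


class OmicsDataError(ValueError):
    """Raised for malformed tables, duplicate ids, or leakage-unsafe requests."""


@dataclass
class OmicsModality:
    """One omics layer: a (n_samples × n_features) matrix with names attached.

    ``values`` may hold strings (object dtype) before categorical encoding;
    after preprocessing it is always float64 with no missing entries.
    """

    name: str
    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise OmicsDataError(f"modality {self.name!r}: values must be 2-D")
        n, p = self.values.shape
        if p < 1:
            raise OmicsDataError(f"modality {self.name!r}: needs at least one feature")
        if len(self.feature_names) != p:
            raise OmicsDataError(
                f"modality {self.name!r}: {len(self.feature_names)} feature names for {p} columns"
            )
        if len(self.sample_ids) != n:
            raise OmicsDataError(
                f"modality {self.name!r}: {len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(set(self.sample_ids)) != n:
            raise OmicsDataError(f"modality {self.name!r}: duplicate sample id")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, indices: Sequence[int]) -> "OmicsModality":
        idx = np.asarray(indices)
        return OmicsModality(
            name=self.name,
            values=self.values[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class MultiOmicsDataset:
    """M modalities sharing one sample axis, plus per-sample class labels."""

    modalities: list[OmicsModality]
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.modalities:
            raise OmicsDataError("dataset needs at least one modality")
        ids = self.modalities[0].sample_ids
        for m in self.modalities[1:]:
            if m.sample_ids != ids:
                raise OmicsDataError(
                    f"modality {m.name!r} sample ids differ from {self.modalities[0].name!r}"
                )
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(ids):
            raise OmicsDataError("labels length must equal sample count")
        if not self.class_names:
            self.class_names = sorted({str(y) for y in self.labels})

    @property
    def n_samples(self) -> int:
        return self.modalities[0].n_samples

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def sample_ids(self) -> list[str]:
        return self.modalities[0].sample_ids

    @property
    def modality_dims(self) -> list[int]:
        return [m.n_features for m in self.modalities]

    @property
    def n_features_total(self) -> int:
        return int(sum(self.modality_dims))

    def modality_names(self) -> list[str]:
        return [m.name for m in self.modalities]

    def subset_rows(self, indices: Sequence[int]) -> "MultiOmicsDataset":
        idx = np.asarray(indices)
        return MultiOmicsDataset(
            modalities=[m.subset_rows(idx) for m in self.modalities],
            labels=self.labels[idx],
            class_names=list(self.class_names),
        )

    def subset_modalities(self, names: Sequence[str]) -> "MultiOmicsDataset":
        by_name = {m.name: m for m in self.modalities}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise OmicsDataError(f"unknown modalities: {missing}")
        return MultiOmicsDataset(
            modalities=[by_name[n] for n in names],
            labels=self.labels,
            class_names=list(self.class_names),
        )


@dataclass(frozen=True)
class FoldSplit:
    """One train/test partition of the sample axis."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fold_id: int
    seed: int

    def __post_init__(self) -> None:
        tr, te = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if tr & te:
            raise OmicsDataError("train and test indices overlap")


def load_modality(path: str, id_column: str, name: str | None = None,
                  delimiter: str | None = None) -> OmicsModality:
    """Read one modality table (CSV/TSV with a header row and a sample-id column).

    Row order is preserved.  Non-numeric columns are kept as strings for
    :func:`encode_categoricals` to handle.
    """
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=delimiter)
    except FileNotFoundError:
        raise OmicsDataError(f"modality file not found: {path}")
    if id_column not in df.columns:
        raise OmicsDataError(f"id column {id_column!r} not in {path}: have {list(df.columns)}")
    ids = df[id_column].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise OmicsDataError(f"duplicate sample id in {path}")
    feats = df.drop(columns=[id_column])
    if feats.shape[1] == 0:
        raise OmicsDataError(f"{path}: no feature columns besides {id_column!r}")
    if feats.isna().any().any():
        raise OmicsDataError(f"{path}: missing values are not supported")
    numeric = all(pd.api.types.is_numeric_dtype(feats[c]) for c in feats.columns)
    values = feats.to_numpy(dtype=float if numeric else object)
    return OmicsModality(
        name=name if name is not None else str(path),
        values=values,
        feature_names=[str(c) for c in feats.columns],
        sample_ids=ids,
    )


def load_labels(path: str, id_column: str = "sample_id",
                label_column: str = "label") -> tuple[list[str], np.ndarray]:
    """Read the two-column labels table; returns (sample_ids, labels)."""
    df = pd.read_csv(path)
    for col in (id_column, label_column):
        if col not in df.columns:
            raise OmicsDataError(f"column {col!r} not in {path}")
    return df[id_column].astype(str).tolist(), df[label_column].astype(str).to_numpy()


def assemble_dataset(modalities: Sequence[OmicsModality], sample_ids: Sequence[str],
                     labels: np.ndarray) -> MultiOmicsDataset:
    """Align modalities to the label table's sample order and build the dataset."""
    aligned = []
    for m in modalities:
        pos = {s: i for i, s in enumerate(m.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise OmicsDataError(f"modality {m.name!r} lacks samples {missing[:5]}")
        aligned.append(m.subset_rows([pos[s] for s in sample_ids]))
    return MultiOmicsDataset(modalities=aligned, labels=np.asarray(labels))


@dataclass
class CategoricalEncoding:
    """Fitted ordinal mapping per categorical column (levels sorted, coded 0..K-1)."""

    modality_name: str
    column_levels: dict[str, dict[str, int]]


def _is_categorical_column(col: np.ndarray) -> bool:
    return not np.issubdtype(np.asarray(col.tolist()).dtype, np.number)


def encode_categoricals(modality: OmicsModality,
                        encoding: CategoricalEncoding | None = None,
                        ) -> tuple[OmicsModality, CategoricalEncoding]:
    """Convert categorical columns to sorted-level ordinal codes.

    With ``encoding=None`` the mapping is fitted on this modality (category
    levels sorted lexicographically, coded 0..K−1) and returned for reuse on
    held-out rows.  With a fitted encoding, the stored mapping is applied and
    an unseen level raises, naming the column and level.
    """
    if modality.values.dtype != object and encoding is None:
        return modality, CategoricalEncoding(modality.name, {})

    cols = []
    fitted: dict[str, dict[str, int]] = {}
    for j, fname in enumerate(modality.feature_names):
        col = modality.values[:, j]
        if encoding is not None:
            mapping = encoding.column_levels.get(fname)
        else:
            mapping = None
            if _is_categorical_column(col):
                levels = sorted({str(v) for v in col})
                mapping = {lev: k for k, lev in enumerate(levels)}
        if mapping is None:
            cols.append(col.astype(float))
        else:
            out = np.empty(len(col), dtype=float)
            for i, v in enumerate(col):
                key = str(v)
                if key not in mapping:
                    raise OmicsDataError(
                        f"unseen category {key!r} in column {fname!r} of modality {modality.name!r}"
                    )
                out[i] = mapping[key]
            cols.append(out)
            fitted[fname] = mapping
    values = np.column_stack(cols)
    used = encoding if encoding is not None else CategoricalEncoding(modality.name, fitted)
    return replace(modality, values=values), used


@dataclass
class Standardizer:
    """Per-feature mean/sd record; sd stored as 0 flags a constant feature."""

    modality_name: str
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        safe = np.where(self.sd > 0, self.sd, 1.0)
        out = (np.asarray(values, dtype=float) - self.mean) / safe
        out[:, self.sd == 0] = 0.0
        return out


def zscore_fit_transform(modality: OmicsModality, fit_indices: Sequence[int],
                         ) -> tuple[OmicsModality, Standardizer]:
    """Standardize all columns to mean 0 / sd 1 using fit rows only.

    Uses the population (1/n) standard deviation.  Zero-variance features map
    to all-zeros rather than being dropped, keeping the concatenated dimension
    stable across folds.
    """
    idx = np.asarray(fit_indices)
    if idx.size == 0:
        raise OmicsDataError("fit_indices is empty")
    vals = np.asarray(modality.values, dtype=float)
    mean = vals[idx].mean(axis=0)
    sd = vals[idx].std(axis=0, ddof=0)
    rec = Standardizer(modality.name, mean=mean, sd=sd)
    return replace(modality, values=rec.transform(vals)), rec


def preprocess_fold(dataset: MultiOmicsDataset, fold: FoldSplit,
                    ) -> tuple[MultiOmicsDataset, list[CategoricalEncoding], list[Standardizer]]:
    """Categorical-encode and z-score every modality, fitting on the train fold only."""
    mods, encs, stds = [], [], []
    for m in dataset.modalities:
        m_num, enc = encode_categoricals(m)
        m_std, rec = zscore_fit_transform(m_num, fold.train_indices)
        mods.append(m_std)
        encs.append(enc)
        stds.append(rec)
    return (
        MultiOmicsDataset(modalities=mods, labels=dataset.labels,
                          class_names=list(dataset.class_names)),
        encs,
        stds,
    )


def make_folds(dataset: MultiOmicsDataset, k: int, repeats: int, seed: int) -> list[FoldSplit]:
    """Stratified k-fold partitions, one per repeat, seeded by seed+r.

    Returns k×repeats :class:`FoldSplit` objects with ``fold_id`` numbering
    folds within a repeat and ``seed`` recording the repeat's seed.
    """
    if k < 2:
        raise OmicsDataError("k must be >= 2")
    if dataset.n_samples < k:
        raise OmicsDataError("fewer samples than folds")
    labels = dataset.labels
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise OmicsDataError(f"class {small[0]!r} has fewer than k={k} members")
    splits: list[FoldSplit] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for fold_id, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            splits.append(FoldSplit(train_indices=tr, test_indices=te,
                                    fold_id=fold_id, seed=seed + r))
    return splits


def concat_features(dataset: MultiOmicsDataset, sources: Sequence[int]) -> np.ndarray:
    """Concatenate one row per modality, in fixed modality order.

    ``sources[m]`` is the sample index supplying modality m; the result has
    length Σ n_m.  Composite triplet roles are built this way.
    """
    if len(sources) != dataset.n_modalities:
        raise OmicsDataError(
            f"need {dataset.n_modalities} source indices, got {len(sources)}"
        )
    parts = []
    n = dataset.n_samples
    for m, src in zip(dataset.modalities, sources):
        if not (0 <= int(src) < n):
            raise OmicsDataError(f"source index {src} out of range for {n} samples")
        parts.append(np.asarray(m.values[int(src)], dtype=float))
    return np.concatenate(parts)
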