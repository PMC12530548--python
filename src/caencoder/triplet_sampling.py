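"""Anchor / positive / negative triplet construction across patients and modalities.

An anchor concatenates all modalities of one patient.  A positive concatenates
modalities drawn (with replacement, uniformly) from patients of the same class
— possibly a different patient per modality, which makes positives deliberately
hard.  A negative sources at least one modality from a patient of a different
class; by default exactly one modality is swapped and the rest come from the
anchor's patient, with harder negatives available via ``n_swap``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .omics_data import MultiOmicsDataset, concat_features


class TripletError(ValueError):
    pass


@dataclass(frozen=True)
class RoleVector:
    """One triplet role: the concatenated vector plus per-modality provenance."""

    vector: np.ndarray
    sources: tuple[int, ...]          # sample index supplying each modality
    label: object                     # the role's reference class label


@dataclass(frozen=True)
class Triplet:
    anchor: RoleVector
    positive: RoleVector
    negative: RoleVector

    def __post_init__(self) -> None:
        n = len(self.anchor.vector)
        if len(self.positive.vector) != n or len(self.negative.vector) != n:
            raise TripletError("triplet roles have mismatched lengths")


@dataclass
class TripletBatch:
    """Stacked role matrices (each N × n_x) with per-triplet provenance."""

    triplets: list[Triplet]

    def __post_init__(self) -> None:
        if not self.triplets:
            raise TripletError("empty triplet batch")
        self.anchors = np.stack([t.anchor.vector for t in self.triplets])
        self.positives = np.stack([t.positive.vector for t in self.triplets])
        self.negatives = np.stack([t.negative.vector for t in self.triplets])

    def __len__(self) -> int:
        return len(self.triplets)


def _class_members(dataset: MultiOmicsDataset) -> dict[object, np.ndarray]:
    return {c: np.flatnonzero(dataset.labels == c) for c in np.unique(dataset.labels)}


def make_anchor(dataset: MultiOmicsDataset, i: int) -> RoleVector:
    """All M modalities sourced from patient i; label y^i."""
    sources = tuple([int(i)] * dataset.n_modalities)
    return RoleVector(vector=concat_features(dataset, sources), sources=sources,
                      label=dataset.labels[int(i)])


def make_positive(dataset: MultiOmicsDataset, anchor_label: object,
                  rng: np.random.Generator) -> RoleVector:
    """Each modality drawn uniformly from patients sharing the anchor's class."""
    pool = np.flatnonzero(dataset.labels == anchor_label)
    if pool.size == 0:
        raise TripletError(f"no samples of class {anchor_label!r}")
    sources = tuple(int(rng.choice(pool)) for _ in range(dataset.n_modalities))
    return RoleVector(vector=concat_features(dataset, sources), sources=sources,
                      label=anchor_label)


def make_negative(dataset: MultiOmicsDataset, anchor_label: object,
                  rng: np.random.Generator, anchor_index: int | None = None,
                  n_swap: int = 1) -> RoleVector:
    """Source ``n_swap`` modalities from a different class, the rest from the anchor.

    With a single modality the whole vector necessarily comes from a foreign
    class.  Raises on a single-class dataset.
    """
    foreign = np.flatnonzero(dataset.labels != anchor_label)
    if foreign.size == 0:
        raise TripletError("no negative source available: dataset has a single class")
    M = dataset.n_modalities
    n_swap = max(1, min(int(n_swap), M))
    same = np.flatnonzero(dataset.labels == anchor_label)
    base = int(anchor_index) if anchor_index is not None else int(rng.choice(same))
    sources = [base] * M
    for m in rng.choice(M, size=n_swap, replace=False):
        sources[int(m)] = int(rng.choice(foreign))
    return RoleVector(vector=concat_features(dataset, tuple(sources)),
                      sources=tuple(sources), label=anchor_label)


def make_triplet(dataset: MultiOmicsDataset, anchor_index: int,
                 rng: np.random.Generator, n_swap: int = 1) -> Triplet:
    a = make_anchor(dataset, anchor_index)
    p = make_positive(dataset, a.label, rng)
    n = make_negative(dataset, a.label, rng, anchor_index=anchor_index, n_swap=n_swap)
    return Triplet(anchor=a, positive=p, negative=n)


def sample_batch(dataset: MultiOmicsDataset, batch_size: int,
                 rng: np.random.Generator, n_swap: int = 1) -> TripletBatch:
    """Draw a batch of triplets with anchor classes proportional to class sizes.

    Class frequencies in the anchors mirror the dataset's imbalance, so the
    contrastive objective sees each subtype in proportion to its prevalence.
    """
    if batch_size < 1:
        raise TripletError("batch_size must be >= 1")
    if np.unique(dataset.labels).size < 2:
        raise TripletError("need at least 2 classes to form triplets")
    anchors = rng.integers(0, dataset.n_samples, size=batch_size)
    return TripletBatch([make_triplet(dataset, int(i), rng, n_swap=n_swap)
                         for i in anchors])


def epoch_batches(dataset: MultiOmicsDataset, batch_size: int,
                  rng: np.random.Generator, n_swap: int = 1) -> list[TripletBatch]:
    """One epoch: every sample anchors exactly one triplet, in shuffled order."""
    order = rng.permutation(dataset.n_samples)
    batches = []
    for start in range(0, len(order), batch_size):
        chunk = order[start:start + batch_size]
        batches.append(TripletBatch([make_triplet(dataset, int(i), rng, n_swap=n_swap)
                                     for i in chunk]))
    return batches


def audit_sources(batches: list[TripletBatch]) -> set[int]:
    """Every sample index that supplied any modality of any role — the CV-hygiene audit."""
    used: set[int] = set()
    for b in batches:
        for t in b.triplets:
            for role in (t.anchor, t.positive, t.negative):
                used.update(role.sources)
    return used
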