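"""Core dataset containers and preprocessing.

Expression data enter the pipeline as a features x samples matrix with a
binary disease/control label per sample and a feature -> gene map (several
transcript-level features may measure the same gene).  Preprocessing is
quantile normalization across samples followed by per-feature
standardization to mean 0 / sd 1; cross-validation folds are stratified by
class so that every evaluable fold contains at least one case.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "CLASS_NODE",
    "ExpressionDataset",
    "FoldPlan",
    "GeneSetSpec",
    "quantile_normalize",
    "standardize",
    "make_folds",
    "supplement_random_genes",
]

#: Name of the single discrete node carrying the disease/control state.
#: Feature and gene identifiers must not collide with it.
CLASS_NODE = "CLASS"

# Sample-sd convention (ddof=1) is used everywhere in this package.
_SD_DDOF = 1


@dataclasses.dataclass
class ExpressionDataset:
    """Samples x features expression matrix with class labels.

    Parameters
    ----------
    species_id:
        Label of the organism the samples come from.
    values:
        ``(n_samples, n_features)`` float array.
    sample_ids, feature_ids:
        Row / column identifiers.
    class_labels:
        Per-sample binary state; disease = 1, control = 0.
    feature_to_gene:
        Maps every feature id to exactly one gene id.  Several features may
        share a gene only at transcript level.
    level:
        ``"transcript"`` or ``"gene"``.
    """

    species_id: str
    values: np.ndarray
    sample_ids: list[str]
    class_labels: np.ndarray
    feature_ids: list[str]
    feature_to_gene: dict[str, str]
    level: str = "transcript"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.class_labels = np.asarray(self.class_labels, dtype=int)
        n_s, n_f = self.values.shape
        if len(self.sample_ids) != n_s:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_s} rows"
            )
        if len(self.feature_ids) != n_f:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {n_f} columns"
            )
        if self.class_labels.shape != (n_s,):
            raise ValueError("class_labels must be one label per sample")
        if not set(np.unique(self.class_labels)) <= {0, 1}:
            raise ValueError("class labels must be binary (0=control, 1=disease)")
        if self.level not in ("transcript", "gene"):
            raise ValueError(f"unknown level {self.level!r}")
        if len(set(self.feature_ids)) != n_f:
            raise ValueError("duplicate feature ids")
        missing = [f for f in self.feature_ids if f not in self.feature_to_gene]
        if missing:
            raise ValueError(f"features without gene mapping: {missing[:5]}")
        if CLASS_NODE in self.feature_ids:
            raise ValueError(f"feature id collides with class node {CLASS_NODE!r}")
        if self.level == "gene":
            genes = [self.feature_to_gene[f] for f in self.feature_ids]
            if len(set(genes)) != n_f:
                raise ValueError("gene-level dataset maps several features to one gene")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.feature_ids:
            seen.setdefault(self.feature_to_gene[f], None)
        return list(seen)

    def column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)]

    def require_both_classes(self) -> None:
        if len(np.unique(self.class_labels)) < 2:
            raise ValueError("dataset must contain both disease and control samples")

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        return dataclasses.replace(
            self,
            values=self.values[index],
            sample_ids=[self.sample_ids[i] for i in index],
            class_labels=self.class_labels[index],
        )

    def restrict_features(self, feature_ids: Sequence[str]) -> "ExpressionDataset":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        unknown = [f for f in feature_ids if f not in pos]
        if unknown:
            raise KeyError(f"unknown features: {unknown[:5]}")
        cols = [pos[f] for f in feature_ids]
        return dataclasses.replace(
            self,
            values=self.values[:, cols],
            feature_ids=list(feature_ids),
            feature_to_gene={f: self.feature_to_gene[f] for f in feature_ids},
        )

    def restrict_genes(self, gene_ids: Iterable[str]) -> "ExpressionDataset":
        keep = set(gene_ids)
        feats = [f for f in self.feature_ids if self.feature_to_gene[f] in keep]
        return self.restrict_features(feats)


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    """Cross-validation fold assignment: per-sample fold index in [0, k)."""

    k: int
    assignment: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", np.asarray(self.assignment, dtype=int))
        if self.k < 2:
            raise ValueError("k must be >= 2")
        counts = np.bincount(self.assignment, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every fold must be non-empty")
        if self.assignment.min() < 0 or self.assignment.max() >= self.k:
            raise ValueError("fold indices out of range")

    def train_index(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)

    def test_index(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


@dataclasses.dataclass(frozen=True)
class GeneSetSpec:
    """Disease-module genes plus the random supplement used as an
    overfitting control; the two sets are disjoint."""

    module_genes: frozenset[str]
    random_genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_genes", frozenset(self.module_genes))
        object.__setattr__(self, "random_genes", frozenset(self.random_genes))
        if self.module_genes & self.random_genes:
            raise ValueError("module and random gene sets must be disjoint")


def quantile_normalize(raw: np.ndarray) -> np.ndarray:
    """Quantile-normalize a features x samples matrix.

    Each sample column is forced onto the common reference distribution
    (the per-rank mean over columns); ties within a column receive the mean
    of the tied ranks' reference values.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    if np.isnan(raw).any():
        raise ValueError("missing values are not supported at this layer")
    n = raw.shape[0]
    reference = np.sort(raw, axis=0).mean(axis=1)
    out = np.empty_like(raw)
    grid = np.arange(n, dtype=float)
    for j in range(raw.shape[1]):
        ranks = rankdata(raw[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return out


def standardize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Scale every feature to mean 0 and (sample) standard deviation 1."""
    mean = dataset.values.mean(axis=0)
    sd = dataset.values.std(axis=0, ddof=_SD_DDOF)
    bad = np.flatnonzero(~(sd > 1e-12))
    if bad.size:
        names = [dataset.feature_ids[i] for i in bad[:5]]
        raise ValueError(f"constant feature(s) cannot be standardized: {names}")
    return dataclasses.replace(dataset, values=(dataset.values - mean) / sd)


def make_folds(dataset: ExpressionDataset, k: int, seed: int) -> FoldPlan:
    """Class-stratified k-fold assignment, deterministic given the seed.

    The minority class must hold at least ``k`` samples so that every fold
    contains at least one case and one control.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    dataset.require_both_classes()
    rng = np.random.default_rng(seed)
    assignment = np.empty(dataset.n_samples, dtype=int)
    for label in (0, 1):
        idx = np.flatnonzero(dataset.class_labels == label)
        if idx.size < k:
            raise ValueError(
                f"class {label} has {idx.size} samples, fewer than k={k}; "
                "every fold needs a sample of each class"
            )
        perm = rng.permutation(idx)
        assignment[perm] = np.arange(perm.size) % k
    return FoldPlan(k=k, assignment=assignment)


def supplement_random_genes(
    dataset: ExpressionDataset,
    module_genes: Iterable[str],
    n_random: int,
    seed: int,
) -> tuple[ExpressionDataset, GeneSetSpec]:
    """Restrict to the disease module plus ``n_random`` random control genes."""
    module = set(module_genes)
    unknown = module - set(dataset.genes)
    if unknown:
        raise KeyError(f"module genes absent from dataset: {sorted(unknown)[:5]}")
    pool = sorted(set(dataset.genes) - module)
    if n_random < 0:
        raise ValueError("n_random must be >= 0")
    if n_random > len(pool):
        raise ValueError(
            f"requested {n_random} random genes but only {len(pool)} non-module genes exist"
        )
    rng = np.random.default_rng(seed)
    random_genes = set(rng.choice(pool, size=n_random, replace=False)) if n_random else set()
    restricted = dataset.restrict_genes(module | random_genes)
    return restricted, GeneSetSpec(frozenset(module), frozenset(random_genes))
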