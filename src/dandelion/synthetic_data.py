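"""Ground-truth generator for multi-species transcript-level datasets.

Several species share one true disease network: a linear Gaussian system
over genes with a binary class root shifting a subset of genes (effect
sizes in sd units).  Each species then adds its own obstacles — sample
size and class balance, transcript-isoform expansion with per-isoform
fidelity (an equicorrelated Gaussian noise model), measurement noise,
species-private spurious edges (model-system artifacts), and ortholog
dropout — so that every pipeline stage is testable without real data.

Species are tied together through explicit ortholog groups rather than
gene-name equality, so one-to-many and missing orthologs are exercisable.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, GeneSetSpec, quantile_normalize, standardize
from .translation import OrthologyMap

__all__ = ["SpeciesSpec", "TruthSpec", "Truth", "generate_truth", "sample_species", "sample_all"]


@dataclasses.dataclass(frozen=True)
class SpeciesSpec:
    """Per-species sampling conditions.

    ``fidelities[i]`` is the correlation of a gene's i-th transcript with
    the underlying gene signal (the last entry repeats for further
    isoforms); ``noise_sd`` adds measurement noise on top.
    """

    n_samples: int
    class_balance: float = 0.5
    transcripts_per_gene: int | Mapping[int, int] = 1
    fidelities: tuple[float, ...] = (0.95,)
    noise_sd: float = 0.2
    ortholog_dropout: float = 0.0
    n_spurious_edges: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples per species")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class balance must lie in (0, 1)")
        if not (0.0 <= self.ortholog_dropout < 1.0):
            raise ValueError("ortholog dropout must lie in [0, 1)")
        if not self.fidelities or any(not (0.0 <= f <= 1.0) for f in self.fidelities):
            raise ValueError("fidelities must lie in [0, 1]")

    def n_transcripts(self, gene_index: int) -> int:
        if isinstance(self.transcripts_per_gene, int):
            return self.transcripts_per_gene
        return int(self.transcripts_per_gene.get(gene_index, 1))

    def fidelity(self, transcript_index: int) -> float:
        i = min(transcript_index, len(self.fidelities) - 1)
        return self.fidelities[i]


@dataclasses.dataclass(frozen=True)
class TruthSpec:
    """The shared ground truth: genes, true edges, class effects, species."""

    n_genes: int
    edges: tuple[tuple[int, int, float], ...]
    class_children: Mapping[int, float]
    species: Mapping[str, SpeciesSpec]
    seed: int = 0
    n_module_genes: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple((int(u), int(v), float(w)) for u, v, w in self.edges))
        object.__setattr__(self, "class_children", dict(self.class_children))
        object.__setattr__(self, "species", dict(self.species))
        for u, v, _ in self.edges:
            if not (0 <= u < self.n_genes and 0 <= v < self.n_genes) or u == v:
                raise ValueError(f"bad edge ({u}, {v})")
        for g, eff in self.class_children.items():
            if not (0 <= g < self.n_genes):
                raise ValueError(f"class child {g} out of range")
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")
        _toposort_indices(self.n_genes, [(u, v) for u, v, _ in self.edges])


def _toposort_indices(n: int, edges: Sequence[tuple[int, int]]) -> list[int]:
    children = {i: [] for i in range(n)}
    indeg = {i: 0 for i in range(n)}
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    stack = [i for i in range(n) if indeg[i] == 0]
    order = []
    while stack:
        i = stack.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) != n:
        raise ValueError("requested edges contain a cycle")
    return order


@dataclasses.dataclass
class Truth:
    """A realized ground truth: spec plus per-species generative extras."""

    spec: TruthSpec
    spurious: dict[str, tuple[tuple[int, int, float], ...]]
    dropped: dict[str, frozenset[int]]

    # -- naming ----------------------------------------------------------
    def group_id(self, gene_index: int) -> str:
        return f"OG{gene_index:04d}"

    def gene_id(self, species_id: str, gene_index: int) -> str:
        return f"{species_id}:g{gene_index}"

    # -- truth in various namespaces -------------------------------------
    def _name(self, gene_index: int, namespace: str) -> str:
        return (
            self.group_id(gene_index)
            if namespace == "group"
            else self.gene_id(namespace, gene_index)
        )

    def true_gene_links(self, namespace: str = "group") -> frozenset[frozenset[str]]:
        return frozenset(
            frozenset((self._name(u, namespace), self._name(v, namespace)))
            for u, v, _ in self.spec.edges
        )

    def true_class_links(self, namespace: str = "group") -> frozenset[frozenset[str]]:
        from .data_model import CLASS_NODE

        return frozenset(
            frozenset((CLASS_NODE, self._name(g, namespace)))
            for g in self.spec.class_children
        )

    def true_links(self, namespace: str = "group") -> frozenset[frozenset[str]]:
        return self.true_gene_links(namespace) | self.true_class_links(namespace)

    def gene_sets(self, namespace: str = "group") -> GeneSetSpec:
        n_mod = self.spec.n_module_genes
        if n_mod is None:
            in_truth = {u for u, _, _ in self.spec.edges} | {
                v for _, v, _ in self.spec.edges
            } | set(self.spec.class_children)
            module = sorted(in_truth)
        else:
            module = list(range(n_mod))
        random_set = [i for i in range(self.spec.n_genes) if i not in set(module)]
        return GeneSetSpec(
            frozenset(self._name(i, namespace) for i in module),
            frozenset(self._name(i, namespace) for i in random_set),
        )

    # -- generative maths -------------------------------------------------
    def _system(self, species_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(W, s): weight matrix and class-shift vector of the species'
        structural system x = W x + s z + eps, eps ~ N(0, I)."""
        n = self.spec.n_genes
        W = np.zeros((n, n))
        for u, v, w in self.spec.edges + self.spurious.get(species_id, ()):
            W[v, u] = w
        s = np.zeros(n)
        for g, eff in self.spec.class_children.items():
            s[g] = eff
        return W, s

    def implied_standardized_shift(self, species_id: str, gene_index: int) -> float:
        """Model-implied between-class mean difference in within-class sd units."""
        W, s = self._system(species_id)
        A = np.eye(self.spec.n_genes) - W
        diff = np.linalg.solve(A, s)
        M = np.linalg.inv(A)
        cov = M @ M.T
        return float(diff[gene_index] / np.sqrt(cov[gene_index, gene_index]))


def generate_truth(spec: TruthSpec) -> Truth:
    """Realize species-private spurious edges and ortholog dropout.

    Deterministic given ``spec.seed``; the same seed yields a bit-identical
    truth.  Spurious edges are drawn among pairs that keep the per-species
    system acyclic, with weights of magnitude 0.4-0.8 and random sign.
    """
    spurious: dict[str, tuple[tuple[int, int, float], ...]] = {}
    dropped: dict[str, frozenset[int]] = {}
    base_edges = [(u, v) for u, v, _ in spec.edges]
    for idx, (sp, sp_spec) in enumerate(spec.species.items()):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 500 + idx]))
        edges: list[tuple[int, int, float]] = []
        current = list(base_edges)
        attempts = 0
        while len(edges) < sp_spec.n_spurious_edges and attempts < 1000:
            attempts += 1
            u = int(rng.integers(spec.n_genes))
            v = int(rng.integers(spec.n_genes))
            if u == v or (u, v) in current or (v, u) in current:
                continue
            try:
                _toposort_indices(spec.n_genes, current + [(u, v)])
            except ValueError:
                continue
            w = float(rng.uniform(0.4, 0.8) * rng.choice([-1.0, 1.0]))
            edges.append((u, v, w))
            current.append((u, v))
        if len(edges) < sp_spec.n_spurious_edges:
            raise RuntimeError("could not place the requested spurious edges")
        spurious[sp] = tuple(edges)
        keep = rng.random(spec.n_genes) >= sp_spec.ortholog_dropout
        dropped[sp] = frozenset(int(i) for i in np.flatnonzero(~keep))
    return Truth(spec=spec, spurious=spurious, dropped=dropped)


def sample_species(
    truth: Truth,
    species_id: str,
    quantile_norm: bool = True,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Draw one species' transcript-level dataset plus its orthology rows.

    Gene signals follow the species' structural system; each gene then
    expands to its transcripts, transcript i being
    ``fidelity * gene + sqrt(1 - fidelity^2) * isoform_noise`` plus
    measurement noise.  The matrix is quantile-normalized (optional) and
    standardized.  Genes hit by ortholog dropout stay in the matrix but
    vanish from the orthology rows.
    """
    spec = truth.spec
    if species_id not in spec.species:
        raise KeyError(f"unknown species {species_id!r}")
    sp_spec = spec.species[species_id]
    idx = list(spec.species).index(species_id)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 1000 + idx]))

    n = sp_spec.n_samples
    z = rng.binomial(1, sp_spec.class_balance, size=n)
    redraws = 0
    while len(np.unique(z)) < 2:
        z = rng.binomial(1, sp_spec.class_balance, size=n)
        redraws += 1
        if redraws > 100:
            raise RuntimeError("could not draw both classes; adjust balance or n")

    W, s = truth._system(species_id)
    all_edges = [(u, v) for u, v, _ in spec.edges + truth.spurious.get(species_id, ())]
    order = _toposort_indices(spec.n_genes, all_edges)
    G = np.zeros((n, spec.n_genes))
    for g in order:
        mean = s[g] * z + G @ W[g]
        G[:, g] = mean + rng.standard_normal(n)

    feature_ids: list[str] = []
    feature_to_gene: dict[str, str] = {}
    columns: list[np.ndarray] = []
    for g in range(spec.n_genes):
        gene_name = truth.gene_id(species_id, g)
        sig = G[:, g]
        sig = (sig - sig.mean()) / sig.std(ddof=1)
        for t in range(sp_spec.n_transcripts(g)):
            fid = sp_spec.fidelity(t)
            col = fid * sig + np.sqrt(max(1.0 - fid**2, 0.0)) * rng.standard_normal(n)
            if sp_spec.noise_sd > 0:
                col = col + sp_spec.noise_sd * rng.standard_normal(n)
            feat = f"{gene_name}:t{t}"
            feature_ids.append(feat)
            feature_to_gene[feat] = gene_name
            columns.append(col)
    raw = np.column_stack(columns).T  # features x samples
    if quantile_norm:
        raw = quantile_normalize(raw)
    dataset = ExpressionDataset(
        species_id=species_id,
        values=raw.T,
        sample_ids=[f"{species_id}:s{i}" for i in range(n)],
        class_labels=z,
        feature_ids=feature_ids,
        feature_to_gene=feature_to_gene,
        level="transcript",
    )
    dataset = standardize(dataset)
    rows = [
        (species_id, truth.gene_id(species_id, g), truth.group_id(g))
        for g in range(spec.n_genes)
        if g not in truth.dropped[species_id]
    ]
    orthology_rows = pd.DataFrame(rows, columns=list(OrthologyMap.COLUMNS))
    return dataset, orthology_rows


def sample_all(
    truth: Truth, quantile_norm: bool = True
) -> tuple[dict[str, ExpressionDataset], OrthologyMap]:
    """All species' datasets plus the combined orthology map."""
    datasets = {}
    frames = []
    for sp in truth.spec.species:
        ds, rows = sample_species(truth, sp, quantile_norm=quantile_norm)
        datasets[sp] = ds
        frames.append(rows)
    return datasets, OrthologyMap(pd.concat(frames, ignore_index=True))
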