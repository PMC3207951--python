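"""Interspecies translation of disease networks.

A transcript-level structure learned in one species is collapsed to a
gene-level *network map* (unordered gene-gene and class-gene links), mapped
through ortholog groups into a target species, and used as the candidate
set for a constrained re-learning run there.  Two variants exist:

* **naive** — transcript profiles are averaged per gene before any
  learning, so maps translate gene-to-gene directly;
* **exhaustive** — learning and translation stay at transcript level and
  the constrained search itself picks which transcript pair instantiates
  each allowed gene-gene link (model-driven transcript selection).

Network maps are undirected: re-learning in the target species re-orients
every edge, and confidence counting operates on relationships, not arrows.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .bn_core import DAGStructure
from .config import RunConfig
from .data_model import CLASS_NODE, ExpressionDataset, FoldPlan, standardize
from .structure_search import AnnealConfig, CandidateEdgeSet, anneal

__all__ = [
    "NetworkMap",
    "OrthologyMap",
    "collapse_to_gene_map",
    "map_via_orthology",
    "naive_summarize",
    "translate_and_test",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class NetworkMap:
    """Gene-level, direction-free link set distilled from a structure.

    ``links`` maps each unordered pair (gene-gene or class-gene) to the
    number of transcript-level edges supporting it.
    """

    links: dict[frozenset[str], int]
    source_species: str = ""

    def __post_init__(self) -> None:
        for link in self.links:
            if len(link) != 2:
                raise ValueError(f"link must join two distinct endpoints: {set(link)}")

    @property
    def link_set(self) -> frozenset[frozenset[str]]:
        return frozenset(self.links)

    def __len__(self) -> int:
        return len(self.links)

    def class_links(self) -> frozenset[frozenset[str]]:
        return frozenset(l for l in self.links if CLASS_NODE in l)


class OrthologyMap:
    """Cross-species gene -> ortholog-group table with two-way lookup.

    A (species, gene) pair may belong to zero or several groups; groups may
    be one-to-many within a species.
    """

    COLUMNS = ("species_id", "gene_id", "group_id")

    def __init__(self, rows: pd.DataFrame | Iterable[tuple[str, str, str]]):
        if not isinstance(rows, pd.DataFrame):
            rows = pd.DataFrame(list(rows), columns=list(self.COLUMNS))
        missing = set(self.COLUMNS) - set(rows.columns)
        if missing:
            raise ValueError(f"orthology table lacks columns: {sorted(missing)}")
        self.frame = rows.loc[:, list(self.COLUMNS)].astype(str).drop_duplicates()
        self._groups_of: dict[tuple[str, str], set[str]] = {}
        self._genes_in: dict[tuple[str, str], set[str]] = {}
        for sp, gene, group in self.frame.itertuples(index=False):
            self._groups_of.setdefault((sp, gene), set()).add(group)
            self._genes_in.setdefault((sp, group), set()).add(gene)

    def groups_of(self, species: str, gene: str) -> frozenset[str]:
        return frozenset(self._groups_of.get((species, gene), ()))

    def genes_in(self, species: str, group: str) -> frozenset[str]:
        return frozenset(self._genes_in.get((species, group), ()))

    def target_genes(self, source_species: str, gene: str, target_species: str) -> frozenset[str]:
        out: set[str] = set()
        for group in self.groups_of(source_species, gene):
            out |= self.genes_in(target_species, group)
        return frozenset(out)

    def canonical_map(self, species: str, feature_to_gene: Mapping[str, str]) -> dict[str, str]:
        """Feature -> ortholog-group projection (smallest group id when a
        gene sits in several groups); unmapped features are omitted."""
        out = {}
        for feat, gene in feature_to_gene.items():
            groups = self.groups_of(species, gene)
            if groups:
                out[feat] = min(groups)
        return out


def collapse_to_gene_map(
    structure: DAGStructure,
    feature_to_gene: Mapping[str, str],
    source_species: str = "",
) -> NetworkMap:
    """Project a transcript-level structure onto gene-gene relationships.

    Each directed transcript edge contributes the unordered pair of its
    endpoints' genes; duplicates merge with a provenance count and edges
    between transcripts of the same gene are dropped (they have no
    gene-level expression).
    """
    links: dict[frozenset[str], int] = {}
    for u, v in structure.edges:
        try:
            gu = CLASS_NODE if u == CLASS_NODE else feature_to_gene[u]
            gv = feature_to_gene[v]
        except KeyError as exc:
            raise KeyError(f"feature without gene mapping: {exc.args[0]}") from exc
        if gu == gv:
            continue
        pair = frozenset((gu, gv))
        links[pair] = links.get(pair, 0) + 1
    return NetworkMap(links=links, source_species=source_species)


def map_via_orthology(
    network_map: NetworkMap,
    orthology: OrthologyMap,
    target_species: str,
) -> tuple[CandidateEdgeSet, list[frozenset[str]]]:
    """Expand a source-species map into target-species candidate pairs.

    One-to-many ortholog groups expand to every combination; links touching
    a gene with no target ortholog are dropped and returned as the loss
    report.  Class-gene links map the gene side only.
    """
    pairs: set[frozenset[str]] = set()
    dropped: list[frozenset[str]] = []
    source = network_map.source_species
    for link in sorted(network_map.links, key=sorted):
        genes = sorted(g for g in link if g != CLASS_NODE)
        targets = [orthology.target_genes(source, g, target_species) for g in genes]
        if any(not t for t in targets):
            dropped.append(link)
            continue
        if CLASS_NODE in link:
            for g in targets[0]:
                pairs.add(frozenset((CLASS_NODE, g)))
        else:
            for a in targets[0]:
                for b in targets[1]:
                    if a != b:
                        pairs.add(frozenset((a, b)))
    if dropped:
        log.info(
            "orthology mapping to %s dropped %d/%d links",
            target_species,
            len(dropped),
            len(network_map.links),
        )
    return CandidateEdgeSet(allowed=frozenset(pairs)), dropped


def naive_summarize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Average transcript profiles per gene, then re-standardize.

    This is the naive variant's preprocessing; genes whose isoforms cancel
    (e.g. perfectly anti-correlated pairs) become constant and surface as a
    standardization error, which is exactly the information loss the
    exhaustive variant avoids.
    """
    if dataset.level != "transcript":
        raise ValueError("naive_summarize expects a transcript-level dataset")
    genes = dataset.genes
    cols = np.empty((dataset.n_samples, len(genes)))
    by_gene: dict[str, list[int]] = {}
    for i, f in enumerate(dataset.feature_ids):
        by_gene.setdefault(dataset.feature_to_gene[f], []).append(i)
    for j, g in enumerate(genes):
        cols[:, j] = dataset.values[:, by_gene[g]].mean(axis=1)
    summarized = dataclasses.replace(
        dataset,
        values=cols,
        feature_ids=list(genes),
        feature_to_gene={g: g for g in genes},
        level="gene",
    )
    return standardize(summarized)


def translate_and_test(
    network_map: NetworkMap,
    target_data: ExpressionDataset,
    target_folds: FoldPlan,
    orthology: OrthologyMap,
    config: RunConfig,
    variant: str = "exhaustive",
):
    """Re-learn a translated network on every fold of the target species.

    For each target fold the training portion is searched in test mode
    (``maxfc_test`` proposals) constrained to the orthology-mapped
    candidate set, then the held-out portion is scored (per-node SSE and
    class confusion).  In the exhaustive variant the candidates are
    gene-level but may be instantiated by any transcript pair of the
    allowed genes.  Returns ``[(fold_id, structure, MetricsReport), ...]``.
    """
    from .evaluation import evaluate_network  # local import: avoids a cycle

    if variant not in ("naive", "exhaustive"):
        raise ValueError(f"unknown variant {variant!r}")
    data = target_data
    if variant == "naive" and data.level == "transcript":
        data = naive_summarize(data)
    candidates, dropped = map_via_orthology(network_map, orthology, data.species_id)
    empty_candidates = len(candidates.allowed or ()) == 0
    results = []
    for fold in range(target_folds.k):
        train = data.subset_samples(target_folds.train_index(fold))
        test = data.subset_samples(target_folds.test_index(fold))
        if empty_candidates:
            structure = DAGStructure(tuple(data.feature_ids), ())
        else:
            cfg = AnnealConfig(
                t0=config.t0,
                tn=config.tn,
                maxfc=config.maxfc_test,
                mode="test",
                seed=derive_seed(config.seed, "translate", data.species_id, fold),
            )
            structure, _, _ = anneal(train, cfg, candidates)
        metrics = evaluate_network(
            structure, train, test, condition_on_class=config.condition_on_class
        )
        if empty_candidates:
            metrics.flagged = True
        results.append((fold, structure, metrics))
    return results
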