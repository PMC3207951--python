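"""Link confidence across fold-networks and the consensus network.

A gene-level link's confidence in a species is the fraction of that
species' networks (cross-validation fold networks for the training
species, translated fold networks for test species) in which it appears,
counted at most once per network and ignoring edge direction.  The
consensus keeps the links whose confidence clears the threshold in *every*
species in scope, which is what makes the thresholds restrained: a link
must be reproducible across all organisms simultaneously.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bn_core import DAGStructure
from .data_model import CLASS_NODE, GeneSetSpec
from .translation import NetworkMap

__all__ = [
    "ConfidenceTable",
    "count_links",
    "consensus",
    "translatability",
    "robustness_profile",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """A ratio whose denominator is empty (e.g. no trained links)."""


@dataclasses.dataclass
class ConfidenceTable:
    """Per-link, per-species occurrence counts and confidence ratios."""

    species: tuple[str, ...]
    max_count: dict[str, int]
    found: dict[frozenset[str], dict[str, int]]

    def __post_init__(self) -> None:
        for sp in self.species:
            if self.max_count.get(sp, 0) <= 0:
                raise ValueError(f"max_count for {sp!r} must be positive")
        for link, counts in self.found.items():
            for sp, c in counts.items():
                if not (0 <= c <= self.max_count[sp]):
                    raise ValueError(
                        f"count {c} outside [0, {self.max_count[sp]}] for {set(link)} in {sp}"
                    )

    @property
    def links(self) -> list[frozenset[str]]:
        return sorted(self.found, key=sorted)

    def confidence(self, link: frozenset[str], species: str) -> float:
        return self.found.get(link, {}).get(species, 0) / self.max_count[species]

    def min_confidence(self, link: frozenset[str], scope: Sequence[str] | None = None) -> float:
        scope = tuple(scope) if scope is not None else self.species
        return min(self.confidence(link, sp) for sp in scope)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for link in self.links:
            a, b = sorted(link)
            row: dict[str, object] = {"gene_a": a, "gene_b": b}
            for sp in self.species:
                row[f"{sp}_found"] = self.found[link].get(sp, 0)
                row[f"{sp}_max"] = self.max_count[sp]
                row[f"{sp}_confidence"] = self.confidence(link, sp)
            rows.append(row)
        cols = ["gene_a", "gene_b"] + [
            f"{sp}_{k}" for sp in self.species for k in ("found", "max", "confidence")
        ]
        return pd.DataFrame(rows, columns=cols)


def _structure_links(
    structure: DAGStructure, feature_to_gene: Mapping[str, str] | None
) -> frozenset[frozenset[str]]:
    """Gene-level projection of a structure's edges, deduplicated.

    Features absent from the projection map (e.g. genes without an ortholog
    group) and within-gene transcript edges contribute nothing.
    """
    links = set()
    for u, v in structure.edges:
        if feature_to_gene is None:
            gu, gv = u, v
        else:
            gu = CLASS_NODE if u == CLASS_NODE else feature_to_gene.get(u)
            gv = feature_to_gene.get(v)
            if gu is None or gv is None:
                continue
        if gu != gv:
            links.add(frozenset((gu, gv)))
    return frozenset(links)


def count_links(
    structures: Mapping[str, Sequence[tuple[DAGStructure, Mapping[str, str] | None]]],
    max_counts: Mapping[str, int] | None = None,
) -> ConfidenceTable:
    """Tabulate link occurrences per species.

    ``structures`` maps each species to its list of ``(structure,
    projection)`` pairs, where the projection maps features into the common
    gene namespace (identity when ``None``).  A link is found in a
    structure when any edge in either direction projects onto it; parallel
    transcript instantiations count once.  ``max_counts`` defaults to the
    number of structures supplied per species and should follow the run
    plan when a species' networks are enumerated elsewhere.
    """
    species = tuple(structures)
    max_count = {
        sp: (max_counts[sp] if max_counts else len(structures[sp])) for sp in species
    }
    found: dict[frozenset[str], dict[str, int]] = {}
    for sp in species:
        for structure, f2g in structures[sp]:
            for link in _structure_links(structure, f2g):
                found.setdefault(link, {sp_: 0 for sp_ in species})
                found[link][sp] += 1
    return ConfidenceTable(species=species, max_count=max_count, found=found)


def consensus(
    table: ConfidenceTable,
    threshold: float,
    species_scope: Sequence[str] | None = None,
) -> NetworkMap:
    """Links whose confidence reaches ``threshold`` in every species in scope."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    scope = tuple(species_scope) if species_scope is not None else table.species
    unknown = set(scope) - set(table.species)
    if unknown:
        raise KeyError(f"species not in table: {sorted(unknown)}")
    links = {}
    for link in table.links:
        if all(table.confidence(link, sp) >= threshold for sp in scope):
            links[link] = sum(table.found[link].get(sp, 0) for sp in scope)
    return NetworkMap(links=links, source_species="consensus")


def translatability(
    trained_links: NetworkMap,
    table: ConfidenceTable,
    threshold: float,
) -> dict[str, float]:
    """Per-species fraction of trained links found above threshold there."""
    if len(trained_links) == 0:
        raise UndefinedMetricError("no trained links; translatability is undefined")
    out = {}
    for sp in table.species:
        passing = sum(
            1 for link in trained_links.links if table.confidence(link, sp) >= threshold
        )
        out[sp] = passing / len(trained_links)
    return out


def robustness_profile(
    table: ConfidenceTable,
    gene_sets: GeneSetSpec,
    thresholds: Iterable[float],
    species_scope: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Surviving-link counts per threshold, split by gene set.

    For each threshold, counts consensus-surviving links incident to at
    least one disease-module gene versus links incident only to random
    control genes.  Class-gene links are attributed by their gene side.
    """
    rows = []
    for tau in thresholds:
        net = consensus(table, tau, species_scope)
        module = 0
        random_only = 0
        for link in net.links:
            genes = {g for g in link if g != CLASS_NODE}
            if genes & set(gene_sets.module_genes):
                module += 1
            elif genes and genes <= set(gene_sets.random_genes):
                random_only += 1
        rows.append({"threshold": tau, "module": module, "random": random_only})
    return pd.DataFrame(rows).set_index("threshold")
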