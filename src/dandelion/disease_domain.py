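"""Disease-domain extraction: the Markov blanket of the class node.

Under the CLG restriction the class node is a root, so its blanket reduces
to its children plus the co-parents of those children.  The domain keeps
only the blanket relationships that survive the all-species confidence
threshold in the consensus network — unstable interactions are pruned.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

from .bn_core import DAGStructure
from .confidence_consensus import ConfidenceTable
from .data_model import CLASS_NODE
from .translation import NetworkMap

__all__ = ["DiseaseDomain", "markov_blanket", "extract_domain"]


@dataclasses.dataclass
class DiseaseDomain:
    """Genes in the class node's blanket with their surviving links.

    ``link_confidence`` carries the per-species confidence of each kept
    link when a table is supplied; ``deregulation`` is a pass-through of
    user-supplied per-species differential-expression flags.
    """

    genes: frozenset[str]
    links: dict[frozenset[str], int]
    link_confidence: dict[frozenset[str], dict[str, float]] = dataclasses.field(
        default_factory=dict
    )
    deregulation: dict[str, dict[str, bool]] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def is_empty(self) -> bool:
        return not self.genes


def markov_blanket(structure: DAGStructure, node: str) -> frozenset[str]:
    """Parents, children, and children's other parents of ``node``."""
    if node != CLASS_NODE and node not in structure.gene_nodes:
        raise KeyError(f"unknown node {node!r}")
    blanket = set(structure.parents(node)) | set(structure.children(node))
    for child in structure.children(node):
        blanket |= set(structure.parents(child))
    blanket.discard(node)
    return frozenset(blanket)


def _gene_level_blanket(
    edges: Sequence[tuple[str, str]],
    feature_to_gene: Mapping[str, str] | None,
    node: str,
) -> frozenset[str]:
    """Blanket of ``node`` on the gene-level projection of a directed edge set.

    The projection of a transcript DAG need not be acyclic, so this works
    directly on the projected directed edges rather than via DAGStructure.
    """

    def proj(n: str) -> str | None:
        if n == CLASS_NODE or feature_to_gene is None:
            return n
        return feature_to_gene.get(n)

    directed = set()
    for u, v in edges:
        gu, gv = proj(u), proj(v)
        if gu is None or gv is None or gu == gv:
            continue
        directed.add((gu, gv))
    children = {v for u, v in directed if u == node}
    parents = {u for u, v in directed if v == node}
    spouses = {u for u, v in directed if v in children}
    blanket = (children | parents | spouses) - {node}
    return frozenset(blanket)


def extract_domain(
    consensus: NetworkMap,
    representative: DAGStructure,
    threshold: float,
    feature_to_gene: Mapping[str, str] | None = None,
    table: ConfidenceTable | None = None,
    deregulation: Mapping[str, Mapping[str, bool]] | None = None,
) -> DiseaseDomain:
    """Markov-blanket disease domain at a confidence threshold.

    Directions come from ``representative`` (by convention the highest-BIC
    training fold-network, projected to gene level); membership is then
    intersected with the thresholded consensus links, so a blanket gene
    whose connection is not reproducible across species drops out.  If no
    consensus link touches the class node the domain is empty (the
    collapse mode of the naive variant) and a warning is issued.
    """
    blanket = _gene_level_blanket(sorted(representative.edges), feature_to_gene, CLASS_NODE)
    keep = blanket | {CLASS_NODE}
    links = {
        link: prov
        for link, prov in consensus.links.items()
        if set(link) <= keep
    }
    if not any(CLASS_NODE in link for link in links):
        warnings.warn(
            f"class node isolated in consensus at threshold {threshold}; empty disease domain",
            RuntimeWarning,
        )
        return DiseaseDomain(genes=frozenset(), links={})
    genes = frozenset(g for link in links for g in link if g != CLASS_NODE)
    confidence = {}
    if table is not None:
        confidence = {
            link: {sp: table.confidence(link, sp) for sp in table.species}
            for link in links
        }
    dereg = {g: dict(flags) for g, flags in (deregulation or {}).items() if g in genes}
    return DiseaseDomain(
        genes=genes, links=links, link_confidence=confidence, deregulation=dereg
    )
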