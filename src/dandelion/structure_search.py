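"""Simulated-annealing search over DAG structures maximizing the BIC.

The search starts from the empty graph and proposes single-edge changes
(add, remove, or swap = reversal), cooling geometrically from ``t0`` to
``tn`` over ``maxfc`` proposals.  Improving moves are always accepted;
worsening moves with probability ``exp(delta / t)``; score ties are broken
toward the incumbent.  In translation ("test") mode every edge's gene-level
projection must lie in a candidate set derived from the training species'
network map, which is how cross-species constraints enter the search.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping

import numpy as np

from .bn_core import DAGStructure, FamilyScorer, ScoreReport
from .data_model import CLASS_NODE, ExpressionDataset

__all__ = ["AnnealConfig", "CandidateEdgeSet", "propose_move", "anneal"]

_MAX_ATTEMPTS = 50


@dataclasses.dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule: defaults follow the published run constants
    (t0=10, tn=0.001, 1000 proposals for training, 500 for translation)."""

    t0: float = 10.0
    tn: float = 0.001
    maxfc: int = 1000
    mode: str = "train"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t0 > self.tn > 0):
            raise ValueError("need t0 > tn > 0")
        if self.maxfc < 1:
            raise ValueError("maxfc must be >= 1")
        if self.mode not in ("train", "test"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def cooling_ratio(self) -> float:
        return (self.tn / self.t0) ** (1.0 / self.maxfc)

    def temperature(self, step: int) -> float:
        return self.t0 * self.cooling_ratio ** step


@dataclasses.dataclass(frozen=True)
class CandidateEdgeSet:
    """Gene-level pairs the search may instantiate.

    ``allowed`` is a set of unordered pairs (frozensets) of gene ids, with
    the class node as a possible member; ``None`` means unconstrained
    (training mode).  An *empty* set forbids every edge.
    """

    allowed: frozenset[frozenset[str]] | None

    @classmethod
    def unconstrained(cls) -> "CandidateEdgeSet":
        return cls(allowed=None)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Iterable[str]]) -> "CandidateEdgeSet":
        out = set()
        for p in pairs:
            p = frozenset(p)
            if len(p) != 2:
                raise ValueError(f"candidate pair must have two distinct members: {set(p)}")
            out.add(p)
        return cls(allowed=frozenset(out))

    @property
    def is_unconstrained(self) -> bool:
        return self.allowed is None

    def allows(self, gene_u: str, gene_v: str) -> bool:
        if self.allowed is None:
            return True
        return frozenset((gene_u, gene_v)) in self.allowed


def _project(node: str, feature_to_gene: Mapping[str, str] | None) -> str:
    if node == CLASS_NODE or feature_to_gene is None:
        return node
    return feature_to_gene[node]


def _allowed_directed_edges(
    gene_nodes: tuple[str, ...],
    candidates: CandidateEdgeSet,
    feature_to_gene: Mapping[str, str] | None,
) -> list[tuple[str, str]]:
    """All directed edges whose gene-level projection is a candidate pair.

    Within-gene transcript edges project to a singleton pair and therefore
    never appear under a constraint.
    """
    out = []
    for v in gene_nodes:
        gv = _project(v, feature_to_gene)
        if candidates.allows(CLASS_NODE, gv):
            out.append((CLASS_NODE, v))
        for u in gene_nodes:
            if u == v:
                continue
            if candidates.allows(_project(u, feature_to_gene), gv):
                out.append((u, v))
    return out


def propose_move(
    structure: DAGStructure,
    candidates: CandidateEdgeSet,
    rng: np.random.Generator,
    feature_to_gene: Mapping[str, str] | None = None,
    max_attempts: int = _MAX_ATTEMPTS,
    _allowed_edges: list[tuple[str, str]] | None = None,
) -> DAGStructure | None:
    """One neighbor of ``structure``: a single add, remove, or edge reversal.

    The operator is drawn uniformly, then an instance of it uniformly;
    illegal draws (cycle, duplicate, constraint violation, class-node
    parent) are re-drawn up to ``max_attempts`` times, after which ``None``
    signals an exhausted neighborhood.
    """
    genes = structure.gene_nodes
    all_parents = (CLASS_NODE,) + genes
    # order by node position, not name, so sampling paths depend only on the
    # dataset layout (keeps naive/gene-level and transcript-level runs aligned)
    pos = {n: i for i, n in enumerate(genes)}
    pos[CLASS_NODE] = -1
    edge_list = sorted(structure.edges, key=lambda e: (pos[e[0]], pos[e[1]]))
    if not candidates.is_unconstrained and _allowed_edges is None:
        _allowed_edges = _allowed_directed_edges(genes, candidates, feature_to_gene)
    for _ in range(max_attempts):
        op = int(rng.integers(3))
        try:
            if op == 0:  # add
                if candidates.is_unconstrained:
                    u = all_parents[int(rng.integers(len(all_parents)))]
                    v = genes[int(rng.integers(len(genes)))]
                else:
                    if not _allowed_edges:
                        continue
                    u, v = _allowed_edges[int(rng.integers(len(_allowed_edges)))]
                if u == v or (u, v) in structure.edges or (v, u) in structure.edges:
                    continue
                return structure.with_edge(u, v)
            if not edge_list:
                continue
            u, v = edge_list[int(rng.integers(len(edge_list)))]
            if op == 1:  # remove
                return structure.without_edge(u, v)
            # swap (reversal)
            if u == CLASS_NODE:
                continue
            return structure.with_reversed_edge(u, v)
        except ValueError:
            continue  # cycle introduced; re-draw
    return None


def anneal(
    data: ExpressionDataset,
    config: AnnealConfig,
    candidates: CandidateEdgeSet | None = None,
) -> tuple[DAGStructure, ScoreReport, list[tuple[int, float, float]]]:
    """Search for a high-BIC structure on ``data``.

    Returns the best structure ever visited, its decomposed score, and a
    per-proposal trace of ``(step, current_score, best_score)``.
    Deterministic given ``config.seed``.
    """
    if candidates is None:
        candidates = CandidateEdgeSet.unconstrained()
    if config.mode == "train" and not candidates.is_unconstrained:
        raise ValueError("training mode is unconstrained; use mode='test' with candidates")
    scorer = FamilyScorer(data)
    rng = np.random.default_rng(config.seed)
    f2g = data.feature_to_gene
    current = DAGStructure(tuple(data.feature_ids), ())
    fam_scores = {n: scorer.family_score(n, ()) for n in current.gene_nodes}
    total = scorer.class_family_score + sum(fam_scores.values())
    best, best_score = current, total
    allowed_edges = (
        None
        if candidates.is_unconstrained
        else _allowed_directed_edges(current.gene_nodes, candidates, f2g)
    )
    trace: list[tuple[int, float, float]] = []

    for step in range(config.maxfc):
        t = config.temperature(step)
        proposal = propose_move(
            current, candidates, rng, f2g, _allowed_edges=allowed_edges
        )
        if proposal is not None:
            changed = {
                v
                for _, v in (current.edges ^ proposal.edges)
            }
            delta = 0.0
            new_scores = {}
            for child in changed:
                s = scorer.family_score(child, proposal.parents(child))
                new_scores[child] = s
                delta += s - fam_scores[child]
            if delta > 0:
                accept = True
            elif delta == 0:
                accept = False  # ties favor the incumbent
            else:
                ratio = delta / t
                accept = ratio > -700 and rng.random() < math.exp(ratio)
            if accept:
                current = proposal
                fam_scores.update(new_scores)
                total += delta
                if total > best_score:
                    best, best_score = current, total
        trace.append((step, total, best_score))
    return best, scorer.structure_score(best), trace
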