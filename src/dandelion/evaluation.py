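"""Cross-validation driver, per-network metrics, and the run-plan grid.

Each fold-network is scored on its held-out samples two ways: prediction of
every gene node's expression from the remaining nodes (sum of squared
error), and prediction of the class node from the full expression profile
(confusion counts, sensitivity/specificity/accuracy, and a Brier-style
class SSE, the squared shortfall of the posterior on the true state).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .bn_core import DAGStructure, fit_parameters, predict_class_batch, predict_expression
from .config import RunConfig
from .data_model import CLASS_NODE, ExpressionDataset, FoldPlan
from .structure_search import AnnealConfig, anneal

__all__ = [
    "MetricsReport",
    "RunPlan",
    "class_metrics",
    "evaluate_network",
    "run_intraspecies",
    "enumerate_run_plan",
    "run_plan_grid",
    "run_interspecies",
    "InterspeciesResult",
    "compare_gene_sets",
]


@dataclasses.dataclass
class MetricsReport:
    """Per-network evaluation on held-out samples.

    Sensitivity/specificity/accuracy return ``None`` when their denominator
    is zero rather than a misleading 0.
    """

    node_sse: dict[str, float] = dataclasses.field(default_factory=dict)
    class_sse: float = 0.0
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    flagged: bool = False

    @property
    def total_sse(self) -> float:
        return float(sum(self.node_sse.values()))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        d = self.total
        return (self.tp + self.tn) / d if d else None

    @property
    def roc_point(self) -> tuple[float, float] | None:
        sp, se = self.specificity, self.sensitivity
        if sp is None or se is None:
            return None
        return (1.0 - sp, se)


def class_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Metrics slice from confusion counts alone."""
    if tp + fp + tn + fn <= 0:
        raise ValueError("confusion counts must total > 0")
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_network(
    structure: DAGStructure,
    train_data: ExpressionDataset,
    test_data: ExpressionDataset,
    condition_on_class: bool = False,
) -> MetricsReport:
    """Fit parameters on the training portion, score on the held-out one.

    The classification rule is argmax posterior with ties broken toward
    control (the majority class in these designs).
    """
    network = fit_parameters(structure, train_data)
    node_sse = {}
    for node in structure.gene_nodes:
        _, sse = predict_expression(
            network, test_data, node, condition_on_class=condition_on_class
        )
        node_sse[node] = sse
    post = predict_class_batch(network, test_data)
    pred = (post[:, 1] > post[:, 0]).astype(int)
    truth = test_data.class_labels
    class_sse = float(((1.0 - post[np.arange(len(truth)), truth]) ** 2).sum())
    return MetricsReport(
        node_sse=node_sse,
        class_sse=class_sse,
        tp=int(((pred == 1) & (truth == 1)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )


def run_intraspecies(
    dataset: ExpressionDataset,
    folds: FoldPlan,
    config: RunConfig,
) -> list[tuple[int, DAGStructure, MetricsReport]]:
    """Unconstrained structure learning per cross-validation fold.

    Every fold's network is learned on the training portion only
    (``maxfc_train`` proposals) and evaluated on the held-out portion, so
    test samples are unseen by construction.
    """
    if dataset.n_samples != folds.assignment.size:
        raise ValueError("fold plan does not match dataset size")
    results = []
    for fold in range(folds.k):
        train = dataset.subset_samples(folds.train_index(fold))
        test = dataset.subset_samples(folds.test_index(fold))
        cfg = AnnealConfig(
            t0=config.t0,
            tn=config.tn,
            maxfc=config.maxfc_train,
            mode="train",
            seed=derive_seed(config.seed, "intra", dataset.species_id, fold),
        )
        structure, _, _ = anneal(train, cfg)
        metrics = evaluate_network(
            structure, train, test, condition_on_class=config.condition_on_class
        )
        results.append((fold, structure, metrics))
    return results


@dataclasses.dataclass(frozen=True)
class RunPlan:
    """Network counts implied by the fold design.

    Training yields one intraspecies network per training fold; each of
    those maps is re-learned on every fold of every test species, giving
    ``k_train * k_test`` interspecies networks per test species.
    """

    k_train: int
    k_tests: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.k_train < 2 or any(k < 2 for k in self.k_tests):
            raise ValueError("all fold counts must be >= 2")

    @property
    def intraspecies_networks(self) -> int:
        return self.k_train

    @property
    def interspecies_networks(self) -> tuple[int, ...]:
        return tuple(self.k_train * k for k in self.k_tests)


def enumerate_run_plan(k_train: int, k_tests: Sequence[int]) -> RunPlan:
    return RunPlan(k_train=k_train, k_tests=tuple(k_tests))


def run_plan_grid(folds: Mapping[str, int]) -> pd.DataFrame:
    """Species x species table of network counts.

    Row = species the networks are evaluated on; column = training species.
    The diagonal holds the intraspecies (cross-validation) counts, the
    off-diagonal cells ``k_row * k_col`` translated networks.
    """
    species = list(folds)
    data = {
        b: [folds[a] if a == b else folds[a] * folds[b] for a in species]
        for b in species
    }
    return pd.DataFrame(data, index=species, dtype=int)


# ---------------------------------------------------------------------------
# full train -> translate -> count pipeline
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class InterspeciesResult:
    """Everything one training-species run produces."""

    train_species: str
    variant: str
    intraspecies: list[tuple[int, DAGStructure, MetricsReport]]
    network_maps: list  # one NetworkMap per training fold
    translated: dict[str, list[tuple[int, int, DAGStructure, MetricsReport]]]
    table: object  # ConfidenceTable over the common (ortholog-group) namespace
    trained_links: object  # NetworkMap: union of training-fold links, group namespace

    def all_metrics(self) -> list[MetricsReport]:
        out = [m for _, _, m in self.intraspecies]
        for rows in self.translated.values():
            out.extend(m for _, _, _, m in rows)
        return out


def run_interspecies(
    datasets: Mapping[str, ExpressionDataset],
    folds: Mapping[str, FoldPlan],
    train_species: str,
    orthology,
    config: RunConfig,
    variant: str | None = None,
) -> InterspeciesResult:
    """Train on one species, translate to the rest, and tabulate confidence.

    Link counting happens in the shared ortholog-group namespace so that
    occurrences of one biological relationship can be accumulated across
    species.  The training species contributes ``k_train`` networks, each
    test species ``k_train * k_test``.
    """
    from .confidence_consensus import count_links
    from .translation import collapse_to_gene_map, naive_summarize, translate_and_test

    variant = variant or config.variant
    if train_species not in datasets:
        raise KeyError(f"unknown training species {train_species!r}")
    train_ds = datasets[train_species]
    if variant == "naive" and train_ds.level == "transcript":
        train_ds = naive_summarize(train_ds)
    intraspecies = run_intraspecies(train_ds, folds[train_species], config)
    maps = [
        collapse_to_gene_map(structure, train_ds.feature_to_gene, train_species)
        for _, structure, _ in intraspecies
    ]
    translated: dict[str, list] = {}
    for sp, ds in datasets.items():
        if sp == train_species:
            continue
        rows = []
        for map_idx, net_map in enumerate(maps):
            sub = dataclasses.replace(config, seed=derive_seed(config.seed, "map", sp, map_idx))
            for fold, structure, metrics in translate_and_test(
                net_map, ds, folds[sp], orthology, sub, variant
            ):
                rows.append((map_idx, fold, structure, metrics))
        translated[sp] = rows

    # confidence counting in the ortholog-group namespace
    structures = {
        train_species: [
            (s, orthology.canonical_map(train_species, train_ds.feature_to_gene))
            for _, s, _ in intraspecies
        ]
    }
    for sp, rows in translated.items():
        ds = datasets[sp]
        f2g = ds.feature_to_gene
        if variant == "naive" and ds.level == "transcript":
            f2g = {g: g for g in ds.genes}
        proj = orthology.canonical_map(sp, f2g)
        structures[sp] = [(s, proj) for _, _, s, _ in rows]
    k_train = folds[train_species].k
    max_counts = {train_species: k_train}
    for sp in translated:
        max_counts[sp] = k_train * folds[sp].k
    table = count_links(structures, max_counts=max_counts)

    trained_links: dict[frozenset, int] = {}
    train_proj = orthology.canonical_map(train_species, train_ds.feature_to_gene)
    from .confidence_consensus import _structure_links
    from .translation import NetworkMap

    for _, s, _ in intraspecies:
        for link in _structure_links(s, train_proj):
            trained_links[link] = trained_links.get(link, 0) + 1
    return InterspeciesResult(
        train_species=train_species,
        variant=variant,
        intraspecies=intraspecies,
        network_maps=maps,
        translated=translated,
        table=table,
        trained_links=NetworkMap(links=trained_links, source_species=train_species),
    )


def pooled_class_metrics(reports: Iterable[MetricsReport]) -> MetricsReport:
    """Pool confusion counts and class SSE over networks (primary summary)."""
    out = MetricsReport()
    for r in reports:
        out.tp += r.tp
        out.fp += r.fp
        out.tn += r.tn
        out.fn += r.fn
        out.class_sse += r.class_sse
    return out


def compare_gene_sets(
    datasets: Mapping[str, ExpressionDataset],
    folds: Mapping[str, FoldPlan],
    train_species: str,
    orthology,
    gene_set_variants: Mapping[str, Iterable[str]],
    config: RunConfig,
) -> dict[str, MetricsReport]:
    """Run the full train/translate/evaluate loop per candidate gene set.

    Each variant is a list of training-species gene ids; test species are
    restricted to the orthologs of those genes.  Returns pooled class
    metrics per variant, the comparative design used to ask whether a
    module is specifically predictive of the disease state.
    """
    results = {}
    for name, genes in gene_set_variants.items():
        genes = list(genes)
        sub_data = {}
        for sp, ds in datasets.items():
            if sp == train_species:
                sub_data[sp] = ds.restrict_genes(genes)
            else:
                target = set()
                for g in genes:
                    target |= orthology.target_genes(train_species, g, sp)
                sub_data[sp] = ds.restrict_genes(target & set(ds.genes))
        res = run_interspecies(sub_data, folds, train_species, orthology, config)
        pooled = pooled_class_metrics(res.all_metrics())
        mean_class_sse = float(
            np.mean([m.class_sse for m in res.all_metrics()])
        )
        pooled.node_sse = {"mean_class_sse_per_network": mean_class_sse}
        results[name] = pooled
    return results
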