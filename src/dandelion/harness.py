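"""Desk-scale recovery experiments on synthetic multi-species data.

These are the package's benchmark harnesses: a shared ground-truth network
is sampled into several species and the full pipeline is run against it,
measuring how much of the truth the consensus recovers compared to
single-species learning, how the exhaustive variant survives low-fidelity
isoforms where the naive variant collapses, and that label-permuted data
carries no signal through the cross-validation plumbing.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from ._utils import derive_seed
from .config import RunConfig
from .confidence_consensus import consensus, count_links
from .data_model import CLASS_NODE, make_folds
from .evaluation import pooled_class_metrics, run_interspecies, run_intraspecies
from .synthetic_data import SpeciesSpec, Truth, TruthSpec, generate_truth, sample_all

__all__ = [
    "demo_truth_spec",
    "edge_recovery_experiment",
    "isoform_collapse_experiment",
    "null_label_experiment",
]


def demo_truth_spec(
    seed: int,
    n_species: int = 3,
    n_samples: int = 40,
    n_module: int = 15,
    n_random: int = 10,
    n_edges: int = 8,
    n_class_children: int = 4,
    effect: float = 1.5,
    edge_weight: float = 0.9,
    second_fidelity: float = 0.8,
    class_child_transcripts: int = 2,
    n_spurious: int = 2,
    noise_sd: float = 0.2,
    dropout: float = 0.0,
) -> TruthSpec:
    """Standard study conditions for the recovery experiments.

    Three species of 40 samples share a truth over 15 disease-module genes
    (8 strong chain edges, 4 class children shifted by 1.5 sd) plus 10
    unconnected random control genes; every species carries a couple of
    private spurious edges emulating model-system artifacts, and class
    children have a second, lower-fidelity isoform.  Class children carry
    no outgoing edges, so they are the only class-associated genes and the
    recovered class links are interpretable against the truth.
    """
    n_genes = n_module + n_random
    class_children = {g: effect for g in range(n_class_children)}
    edges = []
    for g in range(n_class_children, n_module - 1):
        if len(edges) >= n_edges:
            break
        edges.append((g, g + 1, edge_weight))
    transcripts = {g: class_child_transcripts for g in class_children}
    species = {
        f"sp{i}": SpeciesSpec(
            n_samples=n_samples,
            transcripts_per_gene=transcripts,
            fidelities=(0.95, second_fidelity),
            noise_sd=noise_sd,
            ortholog_dropout=dropout,
            n_spurious_edges=n_spurious,
        )
        for i in range(n_species)
    }
    return TruthSpec(
        n_genes=n_genes,
        edges=tuple(edges),
        class_children=class_children,
        species=species,
        seed=seed,
        n_module_genes=n_module,
    )


def _precision(links, truth: Truth) -> float:
    """Fraction of discovered links that are true (gene-gene or class-gene);
    an empty discovery scores 0."""
    links = set(links)
    if not links:
        return 0.0
    return len(links & truth.true_links("group")) / len(links)


def edge_recovery_experiment(
    seed: int,
    k_folds: int = 4,
    threshold: float = 0.1,
    config: RunConfig | None = None,
    spec: TruthSpec | None = None,
) -> dict:
    """Interspecies consensus precision versus single-species precision.

    Trains on the first species, translates to the others (exhaustive
    variant), and compares the edge precision of the consensus at the
    confidence threshold with the mean precision of each species' own
    intraspecies networks (links found in any cross-validation fold).
    """
    config = config or RunConfig(seed=seed)
    spec = spec or demo_truth_spec(seed=seed)
    truth = generate_truth(spec)
    datasets, orthology = sample_all(truth, quantile_norm=False)
    folds = {
        sp: make_folds(ds, k_folds, derive_seed(seed, "folds", sp))
        for sp, ds in datasets.items()
    }
    species = list(datasets)

    # single-species precision: links found across a species' own folds
    intraspecies_precisions = {}
    for sp in species:
        runs = run_intraspecies(
            datasets[sp], folds[sp], dataclasses.replace(config, seed=derive_seed(seed, "solo", sp))
        )
        proj = orthology.canonical_map(sp, datasets[sp].feature_to_gene)
        table = count_links({sp: [(s, proj) for _, s, _ in runs]})
        links = consensus(table, min(threshold, 1.0 / folds[sp].k)).link_set
        intraspecies_precisions[sp] = _precision(links, truth)

    result = run_interspecies(
        datasets, folds, species[0], orthology, config, variant="exhaustive"
    )
    consensus_links = consensus(result.table, threshold).link_set
    return {
        "consensus_precision": _precision(consensus_links, truth),
        "mean_intraspecies_precision": float(
            np.mean(list(intraspecies_precisions.values()))
        ),
        "intraspecies_precisions": intraspecies_precisions,
        "n_consensus_links": len(consensus_links),
        "result": result,
        "truth": truth,
    }


def _true_class_links_found(links, truth: Truth) -> int:
    return len(set(links) & truth.true_class_links("group"))


def isoform_collapse_experiment(
    seed: int,
    k_folds: int = 4,
    threshold: float = 0.1,
    noise_isoform_fidelity: float = 0.3,
    config: RunConfig | None = None,
) -> dict:
    """Naive versus exhaustive consensus when class children carry a
    low-fidelity second isoform.

    Gene-averaging dilutes the informative isoform with the noisy one, so
    the naive consensus should retain fewer of the true class links than
    the exhaustive consensus, which can pick the clean transcript.
    """
    config = config or RunConfig(seed=seed)
    spec = demo_truth_spec(seed=seed, second_fidelity=noise_isoform_fidelity)
    truth = generate_truth(spec)
    datasets, orthology = sample_all(truth, quantile_norm=False)
    folds = {
        sp: make_folds(ds, k_folds, derive_seed(seed, "folds", sp))
        for sp, ds in datasets.items()
    }
    train = list(datasets)[0]
    out = {}
    for variant in ("exhaustive", "naive"):
        res = run_interspecies(datasets, folds, train, orthology, config, variant=variant)
        links = consensus(res.table, threshold).link_set
        out[variant] = _true_class_links_found(links, truth)
        out[f"{variant}_links"] = len(links)
    out["truth"] = truth
    return out


def null_label_experiment(
    seed: int,
    n_genes: int = 12,
    n_samples: int = 40,
    k_folds: int = 3,
    config: RunConfig | None = None,
) -> float:
    """Pooled class accuracy on label-permuted data (should hover near 0.5).

    Labels are shuffled after sampling, severing every gene-class
    association; any accuracy structurally above chance would indicate an
    information leak through the cross-validation plumbing.
    """
    config = config or RunConfig(seed=seed)
    spec = TruthSpec(
        n_genes=n_genes,
        edges=((0, 1, 0.8), (1, 2, 0.8)),
        class_children={0: 1.5, 3: 1.5},
        species={"solo": SpeciesSpec(n_samples=n_samples, noise_sd=0.2)},
        seed=seed,
    )
    truth = generate_truth(spec)
    datasets, _ = sample_all(truth)
    ds = datasets["solo"]
    rng = np.random.default_rng(derive_seed(seed, "permute"))
    ds = dataclasses.replace(ds, class_labels=rng.permutation(ds.class_labels))
    folds = make_folds(ds, k_folds, derive_seed(seed, "folds"))
    runs = run_intraspecies(ds, folds, config)
    pooled = pooled_class_metrics([m for _, _, m in runs])
    return float(pooled.accuracy)
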