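"""Gene-level network maps, orthology mapping, and the two variants."""

import numpy as np
import pandas as pd
import pytest

from dandelion.bn_core import DAGStructure
from dandelion.config import RunConfig
from dandelion.data_model import CLASS_NODE, make_folds
from dandelion.synthetic_data import SpeciesSpec, TruthSpec, generate_truth, sample_all
from dandelion.translation import (
    NetworkMap,
    OrthologyMap,
    collapse_to_gene_map,
    map_via_orthology,
    naive_summarize,
    translate_and_test,
)

from .conftest import make_dataset


F2G = {"t1": "A", "t2": "B", "t3": "A", "t4": "B", "t5": "C"}


class TestCollapse:
    def test_single_edge(self):
        s = DAGStructure(tuple(F2G), [("t1", "t2")])
        m = collapse_to_gene_map(s, F2G)
        assert m.links == {frozenset(("A", "B")): 1}

    def test_parallel_edges_merge_with_provenance(self):
        s = DAGStructure(tuple(F2G), [("t1", "t2"), ("t3", "t4")])
        m = collapse_to_gene_map(s, F2G)
        assert m.links == {frozenset(("A", "B")): 2}

    def test_within_gene_edge_dropped(self):
        s = DAGStructure(tuple(F2G), [("t1", "t3")])
        assert not collapse_to_gene_map(s, F2G).links

    def test_class_edge_projects_to_class_link(self):
        s = DAGStructure(tuple(F2G), [(CLASS_NODE, "t5")])
        m = collapse_to_gene_map(s, F2G)
        assert m.links == {frozenset((CLASS_NODE, "C")): 1}

    def test_direction_invariance(self):
        fwd = DAGStructure(tuple(F2G), [("t1", "t2"), ("t2", "t5")])
        rev = DAGStructure(tuple(F2G), [("t2", "t1"), ("t5", "t2")])
        assert collapse_to_gene_map(fwd, F2G).links == collapse_to_gene_map(rev, F2G).links

    def test_unmapped_feature_is_error(self):
        s = DAGStructure(("t1", "zz"), [("t1", "zz")])
        with pytest.raises(KeyError, match="zz"):
            collapse_to_gene_map(s, {"t1": "A"})


def _orthology():
    return OrthologyMap(
        pd.DataFrame(
            [
                ("src", "A", "OG1"),
                ("src", "B", "OG2"),
                ("src", "C", "OG3"),
                ("tgt", "A'", "OG1"),
                ("tgt", "B'1", "OG2"),
                ("tgt", "B'2", "OG2"),
                # OG3 has no target member: C drops
            ],
            columns=["species_id", "gene_id", "group_id"],
        )
    )


class TestOrthologyMapping:
    def test_one_to_one(self):
        m = NetworkMap({frozenset(("A", "B")): 1}, "src")
        cands, dropped = map_via_orthology(m, _orthology(), "tgt")
        assert frozenset(("A'", "B'1")) in cands.allowed
        assert not dropped

    def test_missing_target_ortholog_dropped_and_reported(self):
        m = NetworkMap({frozenset(("A", "C")): 1}, "src")
        cands, dropped = map_via_orthology(m, _orthology(), "tgt")
        assert cands.allowed == frozenset()
        assert dropped == [frozenset(("A", "C"))]

    def test_one_to_many_expands_to_all_combinations(self):
        m = NetworkMap({frozenset(("A", "B")): 1}, "src")
        cands, _ = map_via_orthology(m, _orthology(), "tgt")
        assert cands.allowed == frozenset(
            [frozenset(("A'", "B'1")), frozenset(("A'", "B'2"))]
        )

    def test_class_link_maps_gene_side_only(self):
        m = NetworkMap({frozenset((CLASS_NODE, "B")): 1}, "src")
        cands, _ = map_via_orthology(m, _orthology(), "tgt")
        assert cands.allowed == frozenset(
            [frozenset((CLASS_NODE, "B'1")), frozenset((CLASS_NODE, "B'2"))]
        )


class TestNaiveSummarize:
    def test_arithmetic_mean_then_standardize(self):
        vals = np.array([[1.0, 3.0], [-1.0, 1.0], [0.0, 2.0], [2.0, 0.0]])
        ds = make_dataset(
            vals, [0, 1, 0, 1], feature_ids=["t1", "t2"],
            feature_to_gene={"t1": "G", "t2": "G"},
        )
        out = naive_summarize(ds)
        mean_profile = vals.mean(axis=1)  # (2, 0, 1, 1)
        expected = (mean_profile - mean_profile.mean()) / mean_profile.std(ddof=1)
        assert out.level == "gene"
        assert out.feature_ids == ["G"]
        assert np.allclose(out.values[:, 0], expected)

    def test_single_transcript_gene_unchanged_after_standardization(self, rng):
        v = rng.standard_normal((10, 1))
        v = (v - v.mean(0)) / v.std(0, ddof=1)
        ds = make_dataset(v, [0, 1] * 5, feature_ids=["t1"], feature_to_gene={"t1": "G"})
        out = naive_summarize(ds)
        assert np.allclose(out.values, ds.values, atol=1e-12)

    def test_anticorrelated_isoforms_collapse_to_error(self):
        t1 = np.array([1.0, -1.0, 0.5, -0.5])
        ds = make_dataset(
            np.column_stack([t1, -t1]), [0, 1, 0, 1],
            feature_ids=["t1", "t2"], feature_to_gene={"t1": "G", "t2": "G"},
        )
        with pytest.raises(ValueError, match="constant"):
            naive_summarize(ds)

    def test_gene_level_input_rejected(self, rng):
        ds = make_dataset(rng.standard_normal((6, 2)), [0, 1] * 3, level="gene")
        with pytest.raises(ValueError, match="transcript"):
            naive_summarize(ds)


def _tiny_truth(seed, transcripts=1, fidelities=(1.0,), noise=0.0):
    return TruthSpec(
        n_genes=6,
        edges=((0, 1, 0.9), (1, 2, 0.9)),
        class_children={3: 1.5},
        species={
            "alpha": SpeciesSpec(
                n_samples=24, transcripts_per_gene=transcripts,
                fidelities=fidelities, noise_sd=noise,
            ),
            "beta": SpeciesSpec(
                n_samples=24, transcripts_per_gene=transcripts,
                fidelities=fidelities, noise_sd=noise,
            ),
        },
        seed=seed,
    )


def _fast_config(seed):
    return RunConfig(seed=seed, maxfc_train=150, maxfc_test=100)


class TestTranslateAndTest:
    def test_empty_network_map_yields_flagged_prior_predictions(self):
        truth = generate_truth(_tiny_truth(0))
        datasets, orth = sample_all(truth)
        ds = datasets["beta"]
        folds = make_folds(ds, 2, seed=1)
        results = translate_and_test(
            NetworkMap({}, "alpha"), ds, folds, orth, _fast_config(0), "exhaustive"
        )
        assert len(results) == 2
        for _, structure, metrics in results:
            assert not structure.edges
            assert metrics.flagged

    def test_one_result_per_target_fold_and_constraint_soundness(self):
        truth = generate_truth(_tiny_truth(1))
        datasets, orth = sample_all(truth)
        src, tgt = datasets["alpha"], datasets["beta"]
        net_map = NetworkMap(
            {
                frozenset(("alpha:g0", "alpha:g1")): 1,
                frozenset(("alpha:g1", "alpha:g2")): 1,
                frozenset((CLASS_NODE, "alpha:g3")): 1,
            },
            "alpha",
        )
        folds = make_folds(tgt, 3, seed=2)
        results = translate_and_test(
            net_map, tgt, folds, orth, _fast_config(1), "exhaustive"
        )
        assert [f for f, _, _ in results] == [0, 1, 2]
        allowed = {
            frozenset(("beta:g0", "beta:g1")),
            frozenset(("beta:g1", "beta:g2")),
            frozenset((CLASS_NODE, "beta:g3")),
        }
        for _, structure, _ in results:
            for u, v in structure.edges:
                gu = CLASS_NODE if u == CLASS_NODE else tgt.feature_to_gene[u]
                assert frozenset((gu, tgt.feature_to_gene[v])) in allowed

    def test_naive_and_exhaustive_agree_with_single_transcripts(self):
        """With one perfect-fidelity transcript per gene the two variants
        are the same algorithm and must produce identical gene-level runs."""
        from dandelion.evaluation import run_interspecies

        truth = generate_truth(_tiny_truth(2))
        datasets, orth = sample_all(truth, quantile_norm=False)
        folds = {sp: make_folds(ds, 2, seed=3) for sp, ds in datasets.items()}
        cfg = _fast_config(2)
        res_ex = run_interspecies(datasets, folds, "alpha", orth, cfg, "exhaustive")
        res_na = run_interspecies(datasets, folds, "alpha", orth, cfg, "naive")
        assert res_ex.table.found == res_na.table.found

    def test_exhaustive_selects_informative_transcript(self):
        """Gene A has an informative isoform a0 and a pure-noise isoform a1;
        the constrained search should instantiate the A-B link through a0."""
        hits = trials = noise_only = 0
        for seed in range(20):
            spec = TruthSpec(
                n_genes=3,
                edges=((0, 1, 0.9),),
                class_children={},
                species={
                    "alpha": SpeciesSpec(n_samples=60, noise_sd=0.0, fidelities=(1.0,)),
                    "beta": SpeciesSpec(
                        n_samples=60,
                        transcripts_per_gene={0: 2},
                        fidelities=(0.95, 0.0),  # second isoform pure noise
                        noise_sd=0.0,
                    ),
                },
                seed=seed,
            )
            truth = generate_truth(spec)
            datasets, orth = sample_all(truth, quantile_norm=False)
            tgt = datasets["beta"]
            net_map = NetworkMap({frozenset(("alpha:g0", "alpha:g1")): 1}, "alpha")
            folds = make_folds(tgt, 2, seed=seed)
            results = translate_and_test(
                net_map, tgt, folds, orth, RunConfig(seed=seed, maxfc_test=500), "exhaustive"
            )
            for _, structure, _ in results:
                inst = {
                    u if tgt.feature_to_gene.get(u) == "beta:g0" else v
                    for u, v in structure.edges
                }
                if inst:
                    trials += 1
                    if "beta:g0:t0" in inst:
                        hits += 1
                    elif "beta:g0:t1" in inst:
                        noise_only += 1
        assert trials >= 20
        assert hits / trials >= 0.9
        assert noise_only / trials <= 0.1
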