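"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (brute force,
closed form, enumeration) kept independent of the package's code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from dandelion.data_model import CLASS_NODE, ExpressionDataset


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def quantile_normalize_oracle(raw: np.ndarray) -> np.ndarray:
    """Sort / average-by-rank / unsort, assuming no ties within a column."""
    raw = np.asarray(raw, dtype=float)
    reference = np.sort(raw, axis=0).mean(axis=1)
    out = np.empty_like(raw)
    for j in range(raw.shape[1]):
        order = np.argsort(raw[:, j])
        out[order, j] = reference
    return out


def enumerate_dags(nodes: tuple[str, ...]):
    """Every DAG (as a frozenset of directed edges) over the given nodes.

    Enumerates all subsets of ordered pairs and keeps the acyclic ones;
    for 3 nodes this yields the classical 25 DAGs.
    """
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    dags = []
    for r in range(len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            if _is_acyclic(nodes, combo):
                dags.append(frozenset(combo))
    return dags


def _is_acyclic(nodes, edges) -> bool:
    children = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    stack = [n for n in nodes if indeg[n] == 0]
    seen = 0
    while stack:
        n = stack.pop()
        seen += 1
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    return seen == len(nodes)


def gaussian_family_bic_oracle(y, X, n_params_extra=2) -> float:
    """Penalized max log-likelihood of one linear Gaussian family."""
    n = y.size
    D = np.column_stack([np.ones(n)] + ([X] if X is not None and X.size else []))
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    var = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi * var) + 1.0)
    k = D.shape[1] + 1
    return ll - 0.5 * k * np.log(n)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_dataset(
    values: np.ndarray,
    labels,
    feature_ids=None,
    species="test",
    feature_to_gene=None,
    level="transcript",
) -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    n_s, n_f = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n_f)]
    feature_to_gene = feature_to_gene or {f: f.upper() for f in feature_ids}
    return ExpressionDataset(
        species_id=species,
        values=values,
        sample_ids=[f"s{i}" for i in range(n_s)],
        class_labels=np.asarray(labels, dtype=int),
        feature_ids=list(feature_ids),
        feature_to_gene=feature_to_gene,
        level=level,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def chain_dataset(rng):
    """Standardized 3-gene chain a -> b -> c with strong weights, n=300."""
    n = 300
    z = rng.binomial(1, 0.5, n)
    a = 1.0 * z + rng.standard_normal(n)
    b = 0.9 * a + rng.standard_normal(n)
    c = 0.9 * b + rng.standard_normal(n)
    vals = np.column_stack([a, b, c])
    vals = (vals - vals.mean(0)) / vals.std(0, ddof=1)
    return make_dataset(vals, z, feature_ids=["a", "b", "c"])


@pytest.fixture
def small_labeled_dataset(rng):
    """20 samples x 4 independent standardized features, balanced classes."""
    n = 20
    z = np.array([0, 1] * 10)
    vals = rng.standard_normal((n, 4))
    vals = (vals - vals.mean(0)) / vals.std(0, ddof=1)
    return make_dataset(vals, z)
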