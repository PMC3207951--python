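"""Conditional linear Gaussian (CLG) Bayesian networks over expression data.

The model has one discrete root — the class node carrying the disease state —
and one continuous node per expression feature.  Each continuous node is
Gaussian with a linear regression on its continuous parents; when the class
node is a parent, the regression (intercept, weights, residual variance) is
fitted separately per class state.  Because a discrete node may not have
continuous parents in a CLG, every link between the class node and a gene is
oriented class -> gene.

Structures are scored with the BIC (penalized maximum log-likelihood,
higher is better), which decomposes over node families; the
:class:`FamilyScorer` exploits that decomposability so a structure search
only rescores the families a move touched.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .data_model import CLASS_NODE, ExpressionDataset

__all__ = [
    "DAGStructure",
    "Family",
    "FittedNetwork",
    "ScoreReport",
    "FamilyScorer",
    "fit_parameters",
    "log_likelihood",
    "bic_score",
    "predict_expression",
    "predict_class",
    "network_to_dict",
    "network_from_dict",
]

_VAR_FLOOR = 1e-6
_RIDGE = 1e-6


def _toposort(nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> list[str]:
    """Topological order of ``nodes``; raises ValueError on a cycle."""
    children: dict[str, list[str]] = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    stack = [n for n in nodes if indeg[n] == 0]
    order: list[str] = []
    while stack:
        n = stack.pop()
        order.append(n)
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) != len(nodes):
        raise ValueError("graph contains a cycle")
    return order


@dataclasses.dataclass(frozen=True)
class DAGStructure:
    """Directed acyclic graph over gene nodes plus the distinguished class node.

    The class node is always present, may only appear as a parent, and the
    whole graph must be acyclic with no self-loops or duplicate edges.
    """

    gene_nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, gene_nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        object.__setattr__(self, "gene_nodes", tuple(gene_nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in edges))
        self._validate()

    def _validate(self) -> None:
        nodes = set(self.gene_nodes) | {CLASS_NODE}
        if len(set(self.gene_nodes)) != len(self.gene_nodes):
            raise ValueError("duplicate gene nodes")
        if CLASS_NODE in self.gene_nodes:
            raise ValueError("class node listed among gene nodes")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if u not in nodes or v not in nodes:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
            if v == CLASS_NODE:
                raise ValueError("the class node may not have parents")
        _toposort(sorted(nodes), self.edges)

    # -- accessors -------------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self.gene_nodes + (CLASS_NODE,)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(v for u, v in self.edges if u == node))

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    # -- edits (return new structures) -----------------------------------
    def with_edge(self, u: str, v: str) -> "DAGStructure":
        return DAGStructure(self.gene_nodes, self.edges | {(u, v)})

    def without_edge(self, u: str, v: str) -> "DAGStructure":
        if (u, v) not in self.edges:
            raise KeyError(f"no edge ({u}, {v})")
        return DAGStructure(self.gene_nodes, self.edges - {(u, v)})

    def with_reversed_edge(self, u: str, v: str) -> "DAGStructure":
        if (u, v) not in self.edges:
            raise KeyError(f"no edge ({u}, {v})")
        return DAGStructure(self.gene_nodes, (self.edges - {(u, v)}) | {(v, u)})

    def topological_gene_order(self) -> list[str]:
        order = _toposort(sorted(self.nodes), self.edges)
        return [n for n in order if n != CLASS_NODE]


@dataclasses.dataclass
class Family:
    """Fitted conditional distribution of one gene node.

    ``class_dependent`` marks per-class parameter sets (the class node is a
    parent and both strata were large enough); ``pooled`` marks a family
    whose class parent had to be ignored because a stratum was too small.
    Arrays are indexed by class configuration (length 1 when not
    class-dependent).
    """

    child: str
    cont_parents: tuple[str, ...]
    class_dependent: bool
    intercept: np.ndarray
    weights: np.ndarray
    variance: np.ndarray
    pooled: bool = False

    @property
    def n_configs(self) -> int:
        return 2 if self.class_dependent else 1

    @property
    def n_params(self) -> int:
        return self.n_configs * (len(self.cont_parents) + 2)

    def config_for_class(self, label: int) -> int:
        return int(label) if self.class_dependent else 0


@dataclasses.dataclass
class FittedNetwork:
    structure: DAGStructure
    class_prior: np.ndarray
    families: dict[str, Family]

    def __post_init__(self) -> None:
        self.class_prior = np.asarray(self.class_prior, dtype=float)
        if not math.isclose(float(self.class_prior.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("class prior must sum to 1")
        if (self.class_prior < 0).any():
            raise ValueError("class prior must be non-negative")
        for fam in self.families.values():
            if (fam.variance <= 0).any():
                raise ValueError(f"non-positive residual variance at {fam.child}")

    @property
    def n_params(self) -> int:
        return sum(f.n_params for f in self.families.values()) + (len(self.class_prior) - 1)

    # -- per-class joint Gaussian over the gene nodes --------------------
    def joint_gaussians(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Mean vectors and covariance matrices of the gene nodes per class.

        Solves the linear structural system x = W x + b_c + eps, so returns
        ``(node_order, means (2, d), covs (2, d, d))``.
        """
        order = list(self.structure.gene_nodes)
        idx = {n: i for i, n in enumerate(order)}
        d = len(order)
        n_classes = len(self.class_prior)
        means = np.zeros((n_classes, d))
        covs = np.zeros((n_classes, d, d))
        for c in range(n_classes):
            W = np.zeros((d, d))
            b = np.zeros(d)
            sd = np.zeros(d)
            for n in order:
                fam = self.families[n]
                cfg = fam.config_for_class(c)
                i = idx[n]
                b[i] = fam.intercept[cfg]
                sd[i] = math.sqrt(fam.variance[cfg])
                for j, p in enumerate(fam.cont_parents):
                    W[i, idx[p]] = fam.weights[cfg, j]
            A = np.eye(d) - W
            means[c] = np.linalg.solve(A, b)
            M = np.linalg.solve(A, np.diag(sd))
            covs[c] = M @ M.T
        return order, means, covs


@dataclasses.dataclass(frozen=True)
class ScoreReport:
    """Decomposed BIC: ``total_bic`` equals the sum of per-family scores."""

    total_bic: float
    family_scores: dict[str, float]
    n_params: int
    n_samples: int


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Least-squares fit of y on [1, X]; returns (intercept, weights, mle_var).

    Falls back to a small ridge penalty when the design is singular.
    """
    n = y.size
    D = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    G = D.T @ D
    try:
        coef = np.linalg.solve(G, D.T @ y)
        if not np.all(np.isfinite(coef)):
            raise np.linalg.LinAlgError
        # guard against a numerically singular but formally solvable system
        if np.linalg.cond(G) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular design matrix; using ridge fallback", RuntimeWarning)
        coef = np.linalg.solve(G + _RIDGE * np.eye(G.shape[0]), D.T @ y)
    resid = y - D @ coef
    var = max(float(resid @ resid) / n, _VAR_FLOOR)
    return float(coef[0]), coef[1:], var


def _gauss_ll(y: np.ndarray, mean: np.ndarray, var: float) -> float:
    r = y - mean
    return float(-0.5 * (y.size * math.log(2.0 * math.pi * var) + (r @ r) / var))


class FamilyScorer:
    """Caches per-family penalized log-likelihood contributions for one dataset.

    Scores are keyed by (child, continuous parents, class-parent flag), which
    is exactly the information a family's BIC contribution depends on.
    """

    def __init__(self, data: ExpressionDataset):
        data.require_both_classes()
        self.data = data
        self.n = data.n_samples
        self._log_n = math.log(self.n)
        self._col = {f: data.values[:, i] for i, f in enumerate(data.feature_ids)}
        self._masks = {c: data.class_labels == c for c in (0, 1)}
        self._counts = {c: int(m.sum()) for c, m in self._masks.items()}
        self._cache: dict[tuple, tuple[float, Family]] = {}
        prior = np.array([self._counts[0], self._counts[1]], dtype=float) / self.n
        self.class_prior = prior
        # class-node family: empirical multinomial, |classes|-1 parameters
        ll = sum(self._counts[c] * math.log(prior[c]) for c in (0, 1))
        self.class_family_score = ll - 0.5 * self._log_n

    def _fit_family(self, child: str, cont: tuple[str, ...], has_class: bool) -> tuple[float, Family]:
        y = self._col[child]
        X = (
            np.column_stack([self._col[p] for p in cont])
            if cont
            else np.empty((self.n, 0))
        )
        p = len(cont)
        per_class = has_class and min(self._counts.values()) >= p + 2
        if has_class and not per_class:
            warnings.warn(
                f"family {child}: class stratum too small for per-class fit; pooling",
                RuntimeWarning,
            )
        if per_class:
            icpt = np.zeros(2)
            w = np.zeros((2, p))
            var = np.zeros(2)
            ll = 0.0
            for c in (0, 1):
                m = self._masks[c]
                icpt[c], w[c], var[c] = _ols(y[m], X[m])
                ll += _gauss_ll(y[m], icpt[c] + (X[m] @ w[c] if p else 0.0), var[c])
            fam = Family(child, cont, True, icpt, w, var)
        else:
            b0, wv, v = _ols(y, X)
            ll = _gauss_ll(y, b0 + (X @ wv if p else 0.0), v)
            fam = Family(
                child,
                cont,
                False,
                np.array([b0]),
                wv.reshape(1, p),
                np.array([v]),
                pooled=has_class,
            )
        score = ll - 0.5 * fam.n_params * self._log_n
        return score, fam

    def family(self, child: str, parents: Iterable[str]) -> tuple[float, Family]:
        parents = tuple(parents)
        has_class = CLASS_NODE in parents
        cont = tuple(sorted(p for p in parents if p != CLASS_NODE))
        key = (child, cont, has_class)
        if key not in self._cache:
            self._cache[key] = self._fit_family(child, cont, has_class)
        return self._cache[key]

    def family_score(self, child: str, parents: Iterable[str]) -> float:
        return self.family(child, parents)[0]

    def structure_score(self, structure: DAGStructure) -> ScoreReport:
        scores = {CLASS_NODE: self.class_family_score}
        n_params = len(self.class_prior) - 1
        for node in structure.gene_nodes:
            s, fam = self.family(node, structure.parents(node))
            scores[node] = s
            n_params += fam.n_params
        return ScoreReport(
            total_bic=float(sum(scores.values())),
            family_scores=scores,
            n_params=n_params,
            n_samples=self.n,
        )

    def fit(self, structure: DAGStructure) -> FittedNetwork:
        families = {
            node: self.family(node, structure.parents(node))[1]
            for node in structure.gene_nodes
        }
        return FittedNetwork(structure, self.class_prior.copy(), families)


def fit_parameters(structure: DAGStructure, data: ExpressionDataset) -> FittedNetwork:
    """Maximum-likelihood CLG parameters for ``structure`` on ``data``.

    Per gene node: an OLS regression on its continuous parents, fitted per
    class state when the class node is a parent and both strata hold at
    least ``n_parents + 2`` samples (otherwise pooled across classes, with
    a warning).  The class prior is the empirical class frequency.
    """
    unknown = set(structure.gene_nodes) - set(data.feature_ids)
    if unknown:
        raise KeyError(f"structure nodes missing from data: {sorted(unknown)[:5]}")
    return FamilyScorer(data).fit(structure)


def log_likelihood(network: FittedNetwork, data: ExpressionDataset) -> float:
    """Joint log-likelihood of samples with observed class labels."""
    unknown = set(network.structure.gene_nodes) - set(data.feature_ids)
    if unknown:
        raise KeyError(f"network nodes missing from data: {sorted(unknown)[:5]}")
    col = {f: data.values[:, i] for i, f in enumerate(data.feature_ids)}
    labels = data.class_labels
    total = float(np.log(network.class_prior[labels]).sum())
    for node in network.structure.gene_nodes:
        fam = network.families[node]
        y = col[node]
        X = (
            np.column_stack([col[p] for p in fam.cont_parents])
            if fam.cont_parents
            else None
        )
        for c in np.unique(labels):
            m = labels == c
            cfg = fam.config_for_class(int(c))
            mean = fam.intercept[cfg] + (X[m] @ fam.weights[cfg] if X is not None else 0.0)
            total += _gauss_ll(y[m], mean, float(fam.variance[cfg]))
    return total


def bic_score(structure: DAGStructure, data: ExpressionDataset) -> ScoreReport:
    """BIC of a structure: max log-likelihood minus (n_params/2) ln(n)."""
    unknown = set(structure.gene_nodes) - set(data.feature_ids)
    if unknown:
        raise KeyError(f"structure nodes missing from data: {sorted(unknown)[:5]}")
    return FamilyScorer(data).structure_score(structure)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def _class_log_posterior(
    network: FittedNetwork,
    X_obs: np.ndarray,
    mu: np.ndarray,
    cov: np.ndarray,
    obs_idx: np.ndarray,
) -> np.ndarray:
    """Log posterior over classes per sample given the observed gene subset."""
    n = X_obs.shape[0]
    logp = np.tile(np.log(network.class_prior), (n, 1))
    if obs_idx.size:
        for c in range(len(network.class_prior)):
            sub = cov[c][np.ix_(obs_idx, obs_idx)]
            L = np.linalg.cholesky(sub)
            dev = X_obs - mu[c][obs_idx]
            z = solve_triangular(L, dev.T, lower=True)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            quad = (z ** 2).sum(axis=0)
            logp[:, c] += -0.5 * (obs_idx.size * math.log(2 * math.pi) + logdet + quad)
    logp -= logp.max(axis=1, keepdims=True)
    return logp


def predict_expression(
    network: FittedNetwork,
    data: ExpressionDataset,
    target_node: str,
    condition_on_class: bool = False,
) -> tuple[np.ndarray, float]:
    """Posterior-mean prediction of one gene node from all other gene nodes.

    The class node is marginalized: each class state contributes its joint
    Gaussian conditional mean, weighted by the class posterior given the
    observed nodes.  With ``condition_on_class`` the observed label is used
    instead (the class posterior collapses to the labeled state).
    Returns the per-sample predictions and their sum of squared errors.
    """
    if target_node == CLASS_NODE:
        raise ValueError("use predict_class for the class node")
    if target_node not in network.structure.gene_nodes:
        raise KeyError(f"unknown target node {target_node!r}")
    order, mu, cov = network.joint_gaussians()
    t = order.index(target_node)
    obs_idx = np.array([i for i in range(len(order)) if i != t], dtype=int)
    pos = {f: i for i, f in enumerate(data.feature_ids)}
    missing = [n for n in order if n not in pos]
    if missing:
        raise KeyError(f"data lacks network nodes: {missing[:5]}")
    X = data.values[:, [pos[n] for n in order]]
    X_obs = X[:, obs_idx]
    y = X[:, t]

    n_classes = len(network.class_prior)
    cond_means = np.zeros((X.shape[0], n_classes))
    for c in range(n_classes):
        if obs_idx.size:
            sub = cov[c][np.ix_(obs_idx, obs_idx)]
            cross = cov[c][t, obs_idx]
            w = np.linalg.solve(sub, cross)
            cond_means[:, c] = mu[c][t] + (X_obs - mu[c][obs_idx]) @ w
        else:
            cond_means[:, c] = mu[c][t]

    if condition_on_class:
        post = np.zeros((X.shape[0], n_classes))
        post[np.arange(X.shape[0]), data.class_labels] = 1.0
    else:
        logp = _class_log_posterior(network, X_obs, mu, cov, obs_idx)
        post = np.exp(logp)
        post /= post.sum(axis=1, keepdims=True)
    pred = (post * cond_means).sum(axis=1)
    sse = float(((pred - y) ** 2).sum())
    return pred, sse


def predict_class(
    network: FittedNetwork, evidence: Mapping[str, float] | np.ndarray
) -> np.ndarray:
    """Posterior over class states given (possibly partial) gene evidence.

    ``evidence`` is either a mapping ``node -> value`` or a vector aligned
    with ``structure.gene_nodes``; missing entries (absent keys or NaN) are
    marginalized exactly through the per-class joint Gaussian.
    """
    order, mu, cov = network.joint_gaussians()
    x = np.full(len(order), np.nan)
    if isinstance(evidence, Mapping):
        unknown = set(evidence) - set(order)
        if unknown:
            raise KeyError(f"evidence for unknown nodes: {sorted(unknown)[:5]}")
        for i, n in enumerate(order):
            if n in evidence:
                x[i] = evidence[n]
    else:
        ev = np.asarray(evidence, dtype=float)
        if ev.shape != (len(order),):
            raise ValueError(f"evidence vector must have length {len(order)}")
        x = ev
    obs_idx = np.flatnonzero(~np.isnan(x))
    logp = _class_log_posterior(network, x[obs_idx][None, :], mu, cov, obs_idx)[0]
    post = np.exp(logp)
    return post / post.sum()


def predict_class_batch(network: FittedNetwork, data: ExpressionDataset) -> np.ndarray:
    """Class posterior for every sample (full evidence on the gene nodes)."""
    order, mu, cov = network.joint_gaussians()
    pos = {f: i for i, f in enumerate(data.feature_ids)}
    missing = [n for n in order if n not in pos]
    if missing:
        raise KeyError(f"data lacks network nodes: {missing[:5]}")
    X = data.values[:, [pos[n] for n in order]]
    obs_idx = np.arange(len(order))
    logp = _class_log_posterior(network, X, mu, cov, obs_idx)
    post = np.exp(logp)
    return post / post.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def network_to_dict(network: FittedNetwork) -> dict:
    return {
        "gene_nodes": list(network.structure.gene_nodes),
        "edges": sorted(list(e) for e in network.structure.edges),
        "class_prior": network.class_prior.tolist(),
        "families": {
            n: {
                "cont_parents": list(f.cont_parents),
                "class_dependent": f.class_dependent,
                "pooled": f.pooled,
                "intercept": f.intercept.tolist(),
                "weights": f.weights.tolist(),
                "variance": f.variance.tolist(),
            }
            for n, f in network.families.items()
        },
    }


def network_from_dict(payload: Mapping) -> FittedNetwork:
    structure = DAGStructure(
        payload["gene_nodes"], [tuple(e) for e in payload["edges"]]
    )
    families = {}
    for n, f in payload["families"].items():
        families[n] = Family(
            child=n,
            cont_parents=tuple(f["cont_parents"]),
            class_dependent=bool(f["class_dependent"]),
            intercept=np.asarray(f["intercept"], dtype=float),
            weights=np.asarray(f["weights"], dtype=float),
            variance=np.asarray(f["variance"], dtype=float),
            pooled=bool(f["pooled"]),
        )
    return FittedNetwork(structure, np.asarray(payload["class_prior"]), families)
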