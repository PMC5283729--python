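"""Data-driven network construction and high-scoring subnetwork search.

Networks are built from intensity data (pairwise or shrinkage partial
correlation), from chemical substructure fingerprints (Tanimoto
similarity), or loaded from knowledge-graph queries.  Node p-values from
upstream statistics are converted to additive scores by fitting a
beta-uniform mixture (BUM) to the p-value distribution; a greedy
heuristic then searches for the connected subgraph with maximal total
score — the "active module" of the network.

The BUM density is ``f(p) = lambda + (1 - lambda) * a * p**(a - 1)`` with
``lambda`` the uniform (noise) weight and ``a`` in (0, 1) the beta shape.
For a target false discovery rate the p-value threshold is

    tau = ((pi - FDR * lambda) / (FDR * (1 - lambda))) ** (1 / (a - 1))

with ``pi = lambda + (1 - lambda) * a`` the noise density at p = 1, and
the node score is ``s(p) = (a - 1) * (log p - log tau)`` — positive
exactly for p < tau and monotone decreasing in p.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize

from .core_data import Dataset

__all__ = [
    "WeightedNetwork",
    "Fingerprint",
    "BumFit",
    "correlation_network",
    "partial_correlation_network",
    "tanimoto",
    "tanimoto_network",
    "fit_bum",
    "score_nodes",
    "max_scoring_subnetwork",
]

DEFAULT_CORR_THRESHOLD = 0.7
FINGERPRINT_LENGTH = 881  # PubChem substructure key space


class NetworkError(ValueError):
    pass


@dataclass
class WeightedNetwork:
    """Typed node set plus weighted, typed edge list.

    Data-driven kinds (correlation, partial, tanimoto) are undirected
    with weights in [-1, 1]; knowledge networks are directed with the
    relation type as edge kind.
    """

    graph: nx.Graph
    kind: str = "pearson"
    threshold: float | None = None

    @classmethod
    def from_edges(cls, edges, kind="pearson", threshold=None, directed=False):
        g = nx.DiGraph() if directed else nx.Graph()
        for u, v, w, *rest in edges:
            ek = rest[0] if rest else kind
            g.add_edge(u, v, weight=float(w), kind=ek)
        return cls(g, kind=kind, threshold=threshold)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "relation_type": d.get("kind", self.kind),
             "weight": d.get("weight", np.nan)}
            for u, v, d in self.graph.edges(data=True)
        ]
        t = pd.DataFrame(rows, columns=["source", "target", "relation_type", "weight"])
        return t.sort_values(["source", "target"]).reset_index(drop=True)

    def write(self, path) -> None:
        from .core_data import write_table

        write_table(self.edge_table(), path)


# ---------------------------------------------------------------------------
# correlation networks


def _drop_constant(x: pd.DataFrame) -> pd.DataFrame:
    sd = x.std(axis=1, ddof=1)
    const = (sd == 0) | sd.isna()
    if const.any():
        warnings.warn(
            f"constant feature(s) excluded from correlation: {x.index[const].tolist()}"
        )
    return x.loc[~const]


def correlation_network(
    d: Dataset,
    method: str = "pearson",
    threshold: float = DEFAULT_CORR_THRESHOLD,
    min_pairs: int = 5,
) -> WeightedNetwork:
    """Pairwise correlation network with |r| thresholding.

    Correlations use pairwise-complete observations; pairs with fewer
    than ``min_pairs`` shared samples are left unconnected.  Edge weight
    is the signed coefficient; an edge exists when ``|r| > threshold``.
    """
    if method not in ("pearson", "spearman", "kendall"):
        raise NetworkError(f"unknown correlation method {method!r}")
    x = _drop_constant(d.intensities)
    corr = x.T.corr(method=method, min_periods=min_pairs)
    edges = []
    feats = corr.index.to_list()
    for i, fi in enumerate(feats):
        for fj in feats[i + 1:]:
            r = corr.loc[fi, fj]
            if np.isfinite(r) and abs(r) > threshold:
                edges.append((fi, fj, float(r)))
    net = WeightedNetwork.from_edges(edges, kind=method, threshold=threshold)
    net.graph.add_nodes_from(feats)
    return net


def _shrinkage_correlation(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Correlation matrix shrunk toward the identity.

    Analytic shrinkage intensity (ratio of the summed sampling variances
    of the off-diagonal correlations to their summed squares), clipped to
    [0, 1].
    """
    n, p = x.shape  # samples x features
    xs = (x - x.mean(0)) / x.std(0, ddof=1)
    r = xs.T @ xs / (n - 1)
    w = np.einsum("ki,kj->kij", xs, xs)  # per-sample outer products
    wbar = w.mean(0)
    var_r = n / ((n - 1) ** 3) * ((w - wbar) ** 2).sum(0)
    off = ~np.eye(p, dtype=bool)
    denom = (r[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    r_shrunk = (1 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    return r_shrunk, lam


def partial_correlation_network(
    d: Dataset,
    threshold: float = DEFAULT_CORR_THRESHOLD,
    shrinkage: float | None = None,
) -> WeightedNetwork:
    """Full-order partial correlation network (Gaussian graphical model).

    The correlation matrix is regularized toward the identity (analytic
    shrinkage intensity unless ``shrinkage`` is given), inverted, and the
    precision matrix standardized to partial correlations
    ``-prec_ij / sqrt(prec_ii * prec_jj)``.  Complete-case samples only.
    """
    x = _drop_constant(d.intensities)
    mat = x.to_numpy(dtype=float).T  # samples x features
    mat = mat[~np.isnan(mat).any(axis=1)]
    if x.shape[0] < 3:
        raise NetworkError("partial correlation needs >= 3 features")
    if mat.shape[0] < 4:
        raise NetworkError("partial correlation needs >= 4 complete samples")
    if shrinkage is None:
        r, lam = _shrinkage_correlation(mat)
    else:
        xs = (mat - mat.mean(0)) / mat.std(0, ddof=1)
        r = (1 - shrinkage) * (xs.T @ xs / (mat.shape[0] - 1))
        np.fill_diagonal(r, 1.0)
        lam = shrinkage
    try:
        prec = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise NetworkError(
            "correlation matrix is singular; increase shrinkage"
        ) from exc
    dgg = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(dgg, dgg)
    np.fill_diagonal(pcor, 1.0)
    feats = x.index.to_list()
    edges = [
        (feats[i], feats[j], float(pcor[i, j]))
        for i, j in itertools.combinations(range(len(feats)), 2)
        if abs(pcor[i, j]) > threshold
    ]
    net = WeightedNetwork.from_edges(edges, kind="partial", threshold=threshold)
    net.graph.add_nodes_from(feats)
    net.graph.graph["shrinkage"] = lam
    return net


# ---------------------------------------------------------------------------
# chemical similarity


@dataclass
class Fingerprint:
    """Binary substructure fingerprint as the set of on-bit positions."""

    entity_id: str
    bits: frozenset[int]
    length: int = FINGERPRINT_LENGTH

    def __post_init__(self) -> None:
        self.bits = frozenset(int(b) for b in self.bits)
        if any(not 0 <= b < self.length for b in self.bits):
            raise NetworkError(
                f"fingerprint {self.entity_id!r} has bits outside [0, {self.length})"
            )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient: shared on-bits over union of on-bits."""
    union = len(a.bits | b.bits)
    if union == 0:
        raise NetworkError("Tanimoto undefined for two all-zero fingerprints")
    return len(a.bits & b.bits) / union


def tanimoto_network(fps, threshold: float = DEFAULT_CORR_THRESHOLD) -> WeightedNetwork:
    """Chemical structure similarity network from substructure fingerprints."""
    lengths = {fp.length for fp in fps}
    if len(lengths) > 1:
        raise NetworkError(f"mixed fingerprint lengths: {sorted(lengths)}")
    usable = []
    for fp in fps:
        if not fp.bits:
            warnings.warn(f"all-zero fingerprint {fp.entity_id!r} excluded")
        else:
            usable.append(fp)
    edges = [
        (a.entity_id, b.entity_id, tanimoto(a, b))
        for a, b in itertools.combinations(usable, 2)
        if tanimoto(a, b) > threshold
    ]
    net = WeightedNetwork.from_edges(edges, kind="tanimoto", threshold=threshold)
    net.graph.add_nodes_from(fp.entity_id for fp in usable)
    return net


# ---------------------------------------------------------------------------
# BUM node scoring


@dataclass
class BumFit:
    """Fitted beta-uniform mixture and the FDR-derived p threshold."""

    lam: float
    a: float
    fdr: float
    tau: float
    log_likelihood: float = field(default=np.nan)

    @property
    def pi_upper(self) -> float:
        """Upper bound on the noise proportion (density at p = 1)."""
        return self.lam + (1 - self.lam) * self.a


def _bum_negloglik(params, p):
    lam, a = params
    dens = lam + (1 - lam) * a * np.power(p, a - 1)
    return -np.sum(np.log(np.clip(dens, 1e-300, None)))


def bum_tau(lam: float, a: float, fdr: float) -> float:
    """P-value threshold at which the BUM-estimated FDR equals ``fdr``."""
    pi = lam + (1 - lam) * a
    num = pi - fdr * lam
    den = fdr * (1 - lam)
    if den <= 0 or num <= 0:
        return np.finfo(float).eps
    tau = (num / den) ** (1 / (a - 1))
    return float(np.clip(tau, np.finfo(float).eps, 1 - 1e-12))


def fit_bum(p, fdr: float = 0.05) -> BumFit:
    """Maximum-likelihood fit of the beta-uniform mixture to p-values.

    Multiple starts over a coarse (lambda, a) grid guard against local
    optima.  Zero p-values are clipped to machine epsilon with a warning.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise NetworkError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p-values of 0 clipped to machine epsilon")
        p = np.clip(p, np.finfo(float).eps, None)
    best = None
    bounds = [(1e-6, 1 - 1e-6), (1e-6, 1 - 1e-6)]
    for lam0 in (0.3, 0.6, 0.9):
        for a0 in (0.2, 0.5, 0.8):
            res = optimize.minimize(
                _bum_negloglik, x0=[lam0, a0], args=(p,),
                method="L-BFGS-B", bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
    lam, a = map(float, best.x)
    return BumFit(lam, a, fdr, bum_tau(lam, a, fdr), log_likelihood=-float(best.fun))


def score_nodes(fit: BumFit, p: dict | pd.Series, missing_score: float = -1.0) -> dict:
    """BUM node scores ``(a - 1) * (log p - log tau)``.

    Positive iff p < tau; nodes without a p-value get ``missing_score``
    (a negative constant) with a warning.
    """
    if isinstance(p, pd.Series):
        p = p.to_dict()
    scores = {}
    n_missing = 0
    for node, pv in p.items():
        if pv is None or (isinstance(pv, float) and np.isnan(pv)):
            scores[node] = missing_score
            n_missing += 1
        else:
            pv = max(float(pv), np.finfo(float).eps)
            scores[node] = (fit.a - 1) * (np.log(pv) - np.log(fit.tau))
    if n_missing:
        warnings.warn(f"{n_missing} node(s) without p-value scored {missing_score}")
    return scores


# ---------------------------------------------------------------------------
# maximum-scoring subnetwork


def _greedy_from(g: nx.Graph, scores: dict, start) -> set:
    """Greedy prize-collecting expansion from ``start``.

    Repeatedly attaches the positive-score node with the best net gain,
    where the gain accounts for the cheapest chain of negative bridge
    nodes needed to reach it (shortest path from the current subgraph
    with node cost ``max(-score, 0)``).
    """
    current = {start}

    def entry_cost(u, v, _d):
        return max(-scores[v], 0.0) + 1e-12  # tiny epsilon keeps paths short

    while True:
        costs, paths = nx.multi_source_dijkstra(g, current, weight=entry_cost)
        best_gain, best_path = 0.0, None
        for t, cost in costs.items():
            if t in current or scores[t] <= 0:
                continue
            new_nodes = [n for n in paths[t] if n not in current]
            gain = sum(scores[n] for n in new_nodes)
            if gain > best_gain + 1e-12:
                best_gain, best_path = gain, new_nodes
        if best_path is None:
            return current
        current |= set(best_path)


def _prune(g: nx.Graph, scores: dict, nodes: set) -> set:
    """Iteratively drop negative-score nodes whose removal keeps connectivity."""
    nodes = set(nodes)
    changed = True
    while changed and len(nodes) > 1:
        changed = False
        for v in sorted(nodes, key=lambda n: scores[n]):
            if scores[v] >= 0:
                break
            rest = nodes - {v}
            if nx.is_connected(g.subgraph(rest)):
                nodes = rest
                changed = True
                break
    return nodes


def max_scoring_subnetwork(
    net: WeightedNetwork, scores: dict, n_starts: int | None = None
) -> tuple[WeightedNetwork, float]:
    """Heuristic search for the connected subgraph of maximal total score.

    Greedy expansion (with a lookahead of one across negative bridge
    nodes) is restarted from the highest-scoring nodes; the best pruned
    result wins.  Ties break deterministically on sorted node ids.  When
    every node scores negative, the single best node is returned with a
    warning.
    """
    g = net.graph.to_undirected() if net.graph.is_directed() else net.graph
    missing = set(g.nodes) - set(scores)
    if missing:
        raise NetworkError(f"nodes without scores: {sorted(missing)[:5]}")
    if g.number_of_nodes() == 0:
        raise NetworkError("empty network")
    order = sorted(g.nodes, key=lambda n: (-scores[n], str(n)))
    if all(scores[n] < 0 for n in order):
        warnings.warn("all node scores negative; returning the single best node")
        best = order[0]
        sub = WeightedNetwork(g.subgraph([best]).copy(), kind=net.kind, threshold=net.threshold)
        return sub, scores[best]
    if n_starts is None:
        n_starts = sum(1 for n in order if scores[n] > 0)
    n_starts = max(1, min(n_starts, len(order)))
    best_nodes, best_score = None, -np.inf
    for start in order[:n_starts]:
        nodes = _prune(g, scores, _greedy_from(g, scores, start))
        total = sum(scores[n] for n in nodes)
        if total > best_score + 1e-12:
            best_nodes, best_score = nodes, total
    sub = WeightedNetwork(g.subgraph(sorted(best_nodes)).copy(),
                          kind=net.kind, threshold=net.threshold)
    return sub, float(best_score)
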