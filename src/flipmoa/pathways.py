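"""Pathway enrichment of flip genes, the pathway-overlap network, and K-means grouping.

Enrichment of a pathway for flip genes is summarized by the enrichment
factor EF = observed overlap / expected overlap under random draws from the
universe, with an upper-tail hypergeometric p-value and BH correction across
pathways. Pathways significant at the chosen FDR become network nodes;
two pathways are connected when their flip-gene memberships overlap
significantly (hypergeometric on the flip universe) and share enough of
their union (Jaccard floor). Nodes are grouped by K-means on the
L2-normalized pathway x flip-gene incidence matrix, with the cluster count
picked by mean silhouette when not fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .diffexp import bh_adjust
from .io import GeneSetCollection

__all__ = [
    "hypergeom_tail",
    "enrich_pathways",
    "PathwayNetwork",
    "build_network",
    "cluster_pathways",
]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap of a size-``n`` draw (without replacement) from a
    universe of ``N`` items, ``K`` of which are marked. Evaluated through
    the survival function of the hypergeometric distribution, which works in
    log space internally, so small tails do not underflow.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_pathways(
    flip_genes: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Score every pathway for enrichment of the flip genes.

    Pathways are restricted to the universe before scoring; expected overlap
    is |P| * |flip| / |universe| and EF = observed / expected. Returns a
    DataFrame indexed by pathway with columns ``size``, ``overlap``,
    ``expected``, ``ef``, ``p``, ``fdr``, sorted by p then pathway id.
    """
    uni = set(universe)
    flip = set(flip_genes)
    stray = flip - uni
    if stray:
        raise ValueError(
            f"{len(stray)} flip genes absent from the universe (e.g. {sorted(stray)[:3]})"
        )
    N = len(uni)
    n = len(flip)
    rows = []
    for sid, gs in sets.sets.items():
        members = set(gs.members) & uni
        if not members:
            continue
        K = len(members)
        k = len(members & flip)
        expected = K * n / N
        ef = 0.0 if expected == 0 else k / expected
        p = hypergeom_tail(k, K, n, N)
        rows.append((sid, K, k, expected, ef, p))
    df = pd.DataFrame(
        rows, columns=["pathway", "size", "overlap", "expected", "ef", "p"]
    ).set_index("pathway")
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "pathway"], kind="mergesort")


@dataclass
class PathwayNetwork:
    """Undirected pathway graph; node/edge attributes carry the statistics."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    enr: pd.DataFrame,
    sets: GeneSetCollection,
    flip_genes: Sequence[str],
    alpha: float = 0.05,
    min_jaccard: float = 0.1,
    edge_alpha: float = 0.05,
    flip_class: str | None = None,
) -> PathwayNetwork:
    """Connect significantly enriched pathways by significant flip-gene overlap.

    Nodes: pathways with FDR < ``alpha``. Edge (A, B): the overlap of the
    two pathways' flip-gene memberships is hypergeometrically significant at
    ``edge_alpha`` within the flip universe AND their flip-membership
    Jaccard is at least ``min_jaccard``.
    """
    flip = set(flip_genes)
    N = len(flip)
    g = nx.Graph()
    sig = enr[enr["fdr"] < alpha]
    memberships = {}
    for sid in sig.index:
        mem = set(sets.members(sid)) & flip
        memberships[sid] = mem
        g.add_node(
            sid,
            ef=float(sig.at[sid, "ef"]),
            p=float(sig.at[sid, "p"]),
            fdr=float(sig.at[sid, "fdr"]),
            overlap=int(sig.at[sid, "overlap"]),
            flip_class=flip_class or "",
        )
    for a, b in combinations(sorted(memberships), 2):
        ma, mb = memberships[a], memberships[b]
        shared = ma & mb
        union = ma | mb
        if not union:
            continue
        jac = len(shared) / len(union)
        if N == 0:
            continue
        p = hypergeom_tail(len(shared), len(ma), len(mb), N)
        if p < edge_alpha and jac >= min_jaccard:
            g.add_edge(a, b, shared=len(shared), jaccard=jac, p=float(p))
    return PathwayNetwork(g)


def cluster_pathways(
    net: PathwayNetwork,
    sets: GeneSetCollection,
    flip_genes: Sequence[str],
    k: int | str = "auto",
    seed: int = 0,
) -> dict[str, int]:
    """Group network pathways by K-means on flip-gene incidence rows.

    Rows of the binary pathway x flip-gene matrix are L2-normalized before
    clustering. With ``k='auto'`` the cluster count maximizes the mean
    silhouette over k in [2, min(10, nodes-1)]; degenerate inputs (identical
    rows, or fewer than 3 nodes) fall back to a single cluster. Deterministic
    for a fixed seed. Labels are written onto the graph nodes and returned.
    """
    nodes = sorted(net.graph.nodes)
    if not nodes:
        return {}
    flip = sorted(set(flip_genes))
    idx = {g: j for j, g in enumerate(flip)}
    X = np.zeros((len(nodes), len(flip)))
    for i, sid in enumerate(nodes):
        for g in sets.members(sid):
            j = idx.get(g)
            if j is not None:
                X[i, j] = 1.0
    norms = np.linalg.norm(X, axis=1)
    X = X / np.where(norms > 0, norms, 1.0)[:, None]

    if isinstance(k, int):
        if k > len(nodes):
            raise ValueError(f"k={k} exceeds node count {len(nodes)}")
        labels = _kmeans_labels(X, k, seed)
    else:
        labels = _auto_kmeans(X, len(nodes), seed)
    out = {sid: int(lab) for sid, lab in zip(nodes, labels)}
    nx.set_node_attributes(net.graph, out, "cluster")
    return out


def _kmeans_labels(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    if k == 1:
        return np.zeros(len(X), dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X)


def _auto_kmeans(X: np.ndarray, n_nodes: int, seed: int) -> np.ndarray:
    kmax = min(10, n_nodes - 1)
    if kmax < 2 or np.unique(X, axis=0).shape[0] < 2:
        return np.zeros(n_nodes, dtype=int)
    best_k, best_s, best_labels = None, -np.inf, None
    for k in range(2, kmax + 1):
        labels = _kmeans_labels(X, k, seed)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s:
            best_k, best_s, best_labels = k, s, labels
    if best_labels is None:
        return np.zeros(n_nodes, dtype=int)
    return best_labels
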