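"""Clustering of the significant-association graph and network export.

Significant association pairs form an undirected graph which is
partitioned by Markov clustering (MCL): flow simulation on the
column-stochastic adjacency matrix with self-loops, alternating matrix
expansion (power 2) and entrywise inflation until convergence. Each
multi-member cluster is summarized by a *cluster centre* node; centres of
two clusters A and B are connected when any cross-cluster pair is
significantly associated, with edge attribute

    force = 1 + (significant cross pairs) / (|A| * |B|)

so a force threshold of 1.1 keeps exactly the cluster pairs in which at
least 10% of all possible cross pairs are associated. Significant
dissociation pairs are exported as a distinct edge kind between entity
nodes and never enter the clustering. The network is written as GraphML
(loadable in Cytoscape) plus flat node/edge TSV tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .association import SCORE_ASSOCIATION, SCORE_DISSOCIATION, AssociationResult

logger = logging.getLogger(__name__)

NODE_CLUSTER_CENTRE = "cluster_centre"
EDGE_MEMBERSHIP = "membership"
EDGE_INTER_CLUSTER = "inter_cluster"
EDGE_DISSOCIATION = "dissociation"


def build_association_graph(results: list[AssociationResult]) -> nx.Graph:
    """Graph over entities in >= 1 significant association (edges weight 1)."""
    g = nx.Graph()
    for r in results:
        if r.score_type == SCORE_ASSOCIATION and r.significant:
            g.add_node(r.entity_a, category=r.category_a)
            g.add_node(r.entity_b, category=r.category_b)
            g.add_edge(r.entity_a, r.entity_b, weight=1.0)
    return g


# ---------------------------------------------------------------------------
# Markov clustering core (shared with phage gene family construction)
# ---------------------------------------------------------------------------


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    convergence: float = 1e-6,
) -> list[list]:
    """Partition a simple undirected graph by Markov clustering.

    Returns clusters as lists of nodes, ordered by decreasing size then by
    smallest member; every node of the graph is assigned to exactly one
    cluster (overlap ties resolve to the lowest node id). Disconnected
    components are never merged.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n == 0:
        return []
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    a = a + np.eye(n)  # self-loops
    m = a / a.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        col = m.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        m = m / col
        if np.abs(m - prev).max() < convergence:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; using current state", max_iter)

    # attractors are rows with non-zero diagonal; each attractor row's
    # support is a cluster, overlapping supports are merged
    tol = 1e-9
    attractors = np.flatnonzero(np.diag(m) > tol)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    assigned = np.full(n, -1, dtype=np.int64)
    for i in attractors:
        support = np.flatnonzero(m[i] > tol)
        for j in support:
            union(i, int(j))
    for i in attractors:
        for j in np.flatnonzero(m[i] > tol):
            root = find(int(j))
            if assigned[j] == -1 or root < assigned[j]:  # ties -> lowest id
                assigned[j] = root
    for j in range(n):  # nodes attracted nowhere become singletons
        if assigned[j] == -1:
            assigned[j] = find(j)

    groups: dict[int, list] = {}
    for j in range(n):
        groups.setdefault(int(assigned[j]), []).append(nodes[j])
    clusters = [sorted(v) for v in groups.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


# ---------------------------------------------------------------------------
# cluster-centre network
# ---------------------------------------------------------------------------


@dataclass
class ClusterNetwork:
    """Typed node/edge network of clusters, centres and dissociations.

    ``graph`` nodes carry node_type (entity category or "cluster_centre"),
    cluster_id, centre_kind (centres only) and annotation; edges carry
    kind (membership | inter_cluster | dissociation) and force
    (inter_cluster only).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    clusters: dict[str, list] = field(default_factory=dict)

    def centre_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True)
            if d.get("node_type") == NODE_CLUSTER_CENTRE
        )

    def edges_of_kind(self, kind: str) -> list[tuple]:
        return sorted(
            (u, v) if u <= v else (v, u)
            for u, v, d in self.graph.edges(data=True)
            if d.get("kind") == kind
        )


def _centre_kind(categories: list[str]) -> str:
    distinct = sorted(set(categories))
    if len(distinct) > 1:
        return "mixed"
    return f"pure_{distinct[0]}"


def make_cluster_network(
    clusters: list[list],
    results: list[AssociationResult],
    categories: dict[str, str],
    annotations: dict[str, str] | None = None,
) -> ClusterNetwork:
    """Build the typed cluster-centre network from a clustering.

    One centre node per cluster of size >= 2 (singletons stay bare); the
    force of an inter-cluster edge is 1 + the fraction of significantly
    associated pairs among all |A|*|B| cross pairs, added only when that
    fraction is positive. Significant dissociation pairs become entity-level
    edges of their own kind.
    """
    annotations = annotations or {}
    net = ClusterNetwork()
    g = net.graph
    cluster_of: dict[str, str] = {}
    ordered = sorted(clusters, key=lambda c: (-len(c), sorted(c)[0]))
    for k, members in enumerate(ordered, start=1):
        cid = f"C{k}"
        net.clusters[cid] = sorted(members)
        for e in members:
            cluster_of[e] = cid
    for cid, members in net.clusters.items():
        for e in members:
            g.add_node(
                e,
                node_type=categories[e],
                cluster_id=cid,
                centre_kind="",
                annotation=annotations.get(e, ""),
            )
        if len(members) >= 2:
            centre = f"{cid}_centre"
            g.add_node(
                centre,
                node_type=NODE_CLUSTER_CENTRE,
                cluster_id=cid,
                centre_kind=_centre_kind([categories[e] for e in members]),
                annotation="",
            )
            for e in members:
                g.add_edge(e, centre, kind=EDGE_MEMBERSHIP, force=0.0)

    cross: dict[tuple[str, str], int] = {}
    for r in results:
        if r.score_type != SCORE_ASSOCIATION or not r.significant:
            continue
        ca = cluster_of.get(r.entity_a)
        cb = cluster_of.get(r.entity_b)
        if ca is None or cb is None or ca == cb:
            continue
        key = (ca, cb) if ca <= cb else (cb, ca)
        cross[key] = cross.get(key, 0) + 1
    for (ca, cb), n_pairs in sorted(cross.items()):
        size_a, size_b = len(net.clusters[ca]), len(net.clusters[cb])
        if size_a < 2 or size_b < 2:
            continue  # no centre to connect
        f = n_pairs / (size_a * size_b)
        g.add_edge(
            f"{ca}_centre", f"{cb}_centre", kind=EDGE_INTER_CLUSTER, force=1.0 + f
        )

    for r in results:
        if r.score_type != SCORE_DISSOCIATION or not r.significant:
            continue
        for e, cat in ((r.entity_a, r.category_a), (r.entity_b, r.category_b)):
            if e not in g:
                g.add_node(
                    e,
                    node_type=cat,
                    cluster_id=cluster_of.get(e, ""),
                    centre_kind="",
                    annotation=annotations.get(e, ""),
                )
        g.add_edge(r.entity_a, r.entity_b, kind=EDGE_DISSOCIATION, force=0.0)
    return net


def filter_by_force(
    net: ClusterNetwork, threshold: float = 1.1, mixed_only: bool = False
) -> ClusterNetwork:
    """Keep inter-cluster edges with force >= threshold.

    With ``mixed_only`` the view is restricted to mixed clusters (those
    spanning >= 2 entity categories) plus the clusters connected to them by
    a retained inter-cluster edge — the published network view.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    out = ClusterNetwork(graph=net.graph.copy(), clusters=dict(net.clusters))
    drop = [
        (u, v)
        for u, v, d in out.graph.edges(data=True)
        if d.get("kind") == EDGE_INTER_CLUSTER and d.get("force", 0.0) < threshold
    ]
    out.graph.remove_edges_from(drop)
    if mixed_only:
        mixed = {
            n for n, d in out.graph.nodes(data=True)
            if d.get("node_type") == NODE_CLUSTER_CENTRE and d.get("centre_kind") == "mixed"
        }
        keep_centres = set(mixed)
        for u, v, d in out.graph.edges(data=True):
            if d.get("kind") == EDGE_INTER_CLUSTER and (u in mixed or v in mixed):
                keep_centres.update((u, v))
        keep_clusters = {
            out.graph.nodes[c]["cluster_id"] for c in keep_centres
        }
        keep_nodes = set(keep_centres)
        for cid in keep_clusters:
            keep_nodes.update(out.clusters.get(cid, []))
        out.graph.remove_nodes_from([n for n in list(out.graph) if n not in keep_nodes])
        out.clusters = {c: m for c, m in out.clusters.items() if c in keep_clusters}
    return out


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def _clean(value: str) -> str:
    return str(value).replace("\t", " ").replace("\n", " ").replace("\r", " ")


def export_network(net: ClusterNetwork, prefix: str | Path) -> dict[str, Path]:
    """Write GraphML plus node/edge/cluster TSV tables; deterministic order.

    Returns the written paths keyed by kind (graphml, nodes, edges,
    clusters). The GraphML is importable by Cytoscape; the TSV tables carry
    the same attributes for programmatic use.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ordered = nx.Graph()
    for n in sorted(net.graph.nodes()):
        d = net.graph.nodes[n]
        ordered.add_node(
            n,
            node_type=_clean(d.get("node_type", "")),
            cluster_id=_clean(d.get("cluster_id", "")),
            centre_kind=_clean(d.get("centre_kind", "")),
            annotation=_clean(d.get("annotation", "")),
        )
    for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges()):
        d = net.graph.edges[u, v]
        ordered.add_edge(u, v, kind=_clean(d.get("kind", "")), force=float(d.get("force", 0.0)))

    paths = {
        "graphml": Path(f"{prefix}.graphml"),
        "nodes": Path(f"{prefix}.nodes.tsv"),
        "edges": Path(f"{prefix}.edges.tsv"),
        "clusters": Path(f"{prefix}.clusters.tsv"),
    }
    nx.write_graphml(ordered, paths["graphml"])
    with open(paths["nodes"], "w", encoding="utf-8") as fh:
        fh.write("id\tnode_type\tcluster_id\tcentre_kind\tannotation\n")
        for n in sorted(ordered.nodes()):
            d = ordered.nodes[n]
            fh.write(
                f"{n}\t{d['node_type']}\t{d['cluster_id']}\t"
                f"{d['centre_kind']}\t{d['annotation']}\n"
            )
    with open(paths["edges"], "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tkind\tforce\n")
        for u, v in sorted(tuple(sorted(e)) for e in ordered.edges()):
            d = ordered.edges[u, v]
            fh.write(f"{u}\t{v}\t{d['kind']}\t{d['force']:.10g}\n")
    with open(paths["clusters"], "w", encoding="utf-8") as fh:
        fh.write("cluster_id\tentity_id\n")
        for cid in sorted(net.clusters, key=lambda c: int(c[1:])):
            for e in net.clusters[cid]:
                fh.write(f"{cid}\t{e}\n")
    return paths
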