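"""Median-joining haplotype network construction.

Builds the network of Bandelt, Forster & Roehl (1999): starting from the
epsilon-relaxed minimum spanning network (MSN) over the observed haplotypes,
consensus (majority-per-site) median vectors are proposed from connected
triplets and added when they shorten the network; the process repeats to
fixation and obsolete median vectors are pruned.  With epsilon = 0 (default)
the MSN is the union of all minimum spanning trees.

Only the variable positions enter the computation; node and edge annotations
are written back in terms of the original alignment coordinates (1-based).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import DesignError
from .hapio import BASES, HaplotypeTable

PURINES = {"A", "G"}


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _msn_edges(seqs: list[str], epsilon: int = 0) -> set[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    By the cycle property, an edge belongs to some minimum spanning tree
    exactly when its weight equals the minimax path weight (the smallest
    possible maximum edge weight over paths) between its endpoints; the MSN
    at epsilon = 0 is the union of all MSTs, and relaxation admits edges up
    to epsilon heavier than the minimax weight.
    """
    m = len(seqs)
    g = nx.Graph()
    g.add_nodes_from(range(m))
    for i, j in itertools.combinations(range(m), 2):
        g.add_edge(i, j, weight=_hamming(seqs[i], seqs[j]))
    mst = nx.minimum_spanning_tree(g)
    edges: set[tuple[int, int]] = set()
    for i, j in itertools.combinations(range(m), 2):
        path = nx.shortest_path(mst, i, j)
        minimax = max(mst[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
        if g[i][j]["weight"] <= minimax + epsilon:
            edges.add((i, j))
    return edges


def _mst_length(seqs: list[str]) -> int:
    """Total weight of a minimum spanning tree over the sequences."""
    m = len(seqs)
    if m < 2:
        return 0
    g = nx.Graph()
    for i, j in itertools.combinations(range(m), 2):
        g.add_edge(i, j, weight=_hamming(seqs[i], seqs[j]))
    return int(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
    )


def _consensus(a: str, b: str, c: str) -> str:
    """Majority state per site of three sequences (ties resolved toward a)."""
    out = []
    for x, y, z in zip(a, b, c):
        if y == z:
            out.append(y)
        else:
            out.append(x)  # x equals y, z, or is the tie-break
    return "".join(out)


@dataclass
class NetworkResult:
    """Median-joining network: graph plus bookkeeping."""

    graph: nx.Graph
    variable_positions: list[int]  # 0-based positions in the full alignment
    total_length: int
    mst_length: int  # MST length over observed haplotypes only
    n_medians: int


def median_joining(
    ht: HaplotypeTable,
    epsilon: int = 0,
) -> NetworkResult:
    """Median-joining network over the haplotypes of ``ht``.

    Nodes are haplotype ids (with per-population counts attached) and
    synthetic median vectors ``mv1, mv2, ...``; edges carry the mutational-
    step weight.  Candidate medians are examined in lexicographic order of
    the triplet sequences so runs are bit-stable.
    """
    if ht.K < 2:
        raise DesignError("median-joining needs at least 2 haplotypes")
    full_seqs = ht.sequences
    var_pos = [
        p for p in range(ht.L) if len({s[p] for s in full_seqs}) > 1
    ]
    reduced = ["".join(s[p] for p in var_pos) for s in full_seqs]
    if len(set(reduced)) != len(reduced):
        raise DesignError("haplotypes are not distinct at variable sites")

    seqs = list(reduced)  # observed first, medians appended
    observed = len(seqs)

    # iterate: MSN -> propose medians from connected triplets -> keep those
    # that shorten the MST over the augmented set
    while True:
        edges = _msn_edges(seqs, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(seqs))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        current_len = _mst_length(seqs)
        candidates: set[str] = set()
        for v in range(len(seqs)):
            for u, w in itertools.combinations(sorted(adj[v]), 2):
                med = _consensus(seqs[v], seqs[u], seqs[w])
                if med not in seqs:
                    candidates.add(med)
        best = None
        for med in sorted(candidates):  # lexicographic tie-break
            new_len = _mst_length(seqs + [med])
            if new_len < current_len and (best is None or new_len < best[1]):
                best = (med, new_len)
        if best is None:
            break
        seqs.append(best[0])

    # prune: median vectors of degree <= 2 in the final MSN are obsolete
    while True:
        edges = _msn_edges(seqs, epsilon)
        deg = {i: 0 for i in range(len(seqs))}
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        drop = [
            i for i in range(observed, len(seqs)) if deg[i] <= 2
        ]
        if not drop:
            break
        seqs = [s for i, s in enumerate(seqs) if i not in set(drop)]

    edges = _msn_edges(seqs, epsilon)
    graph = nx.Graph()
    pop_totals = {
        pop: ht.population_counts(pop)
        for pop in ht.counts.columns.get_level_values(0).unique()
    }
    label: dict[int, str] = {}
    n_medians = 0
    for i, s in enumerate(seqs):
        if i < observed:
            hid = ht.ids[reduced.index(s)]
            label[i] = hid
            hidx = ht.ids.index(hid)
            graph.add_node(
                hid,
                kind="haplotype",
                count=int(ht.total_counts()[hidx]),
                counts_by_population={
                    p: int(v[hidx]) for p, v in pop_totals.items() if v[hidx]
                },
                sequence=s,
            )
        else:
            n_medians += 1
            mid = f"mv{n_medians}"
            label[i] = mid
            graph.add_node(mid, kind="median", count=0, sequence=s)
    total = 0
    for i, j in sorted(edges):
        w = _hamming(seqs[i], seqs[j])
        total += w
        graph.add_edge(label[i], label[j], weight=w)
    if not nx.is_connected(graph):
        raise DesignError("median-joining produced a disconnected network")
    return NetworkResult(graph, var_pos, total, _mst_length(reduced), n_medians)


def annotate_edges(net: NetworkResult, ht: HaplotypeTable) -> NetworkResult:
    """Label each edge with its per-site changes and transition/transversion class."""
    graph = net.graph
    for a, b, data in graph.edges(data=True):
        sa = graph.nodes[a]["sequence"]
        sb = graph.nodes[b]["sequence"]
        changes = []
        for rpos, (x, y) in enumerate(zip(sa, sb)):
            if x != y:
                pos1 = net.variable_positions[rpos] + 1  # 1-based report
                if x in BASES and y in BASES:
                    kind = (
                        "transition"
                        if (x in PURINES) == (y in PURINES)
                        else "transversion"
                    )
                else:
                    kind = "indel/ambiguous"
                changes.append({"position": pos1, "from": x, "to": y, "kind": kind})
        data["changes"] = changes
        assert len(changes) == data["weight"]
    return net


def write_network(net: NetworkResult, edge_path, node_path, gml_path=None) -> None:
    """Edge-list and node-table TSVs (plus optional GML)."""
    import pandas as pd

    rows = []
    for a, b, data in net.graph.edges(data=True):
        changes = ";".join(
            f"{c['position']}{c['from']}>{c['to']}({c['kind'][:2]})"
            for c in data.get("changes", [])
        )
        rows.append(
            {"node_a": a, "node_b": b, "weight": data["weight"], "changes": changes}
        )
    pd.DataFrame(rows).to_csv(edge_path, sep="\t", index=False)
    nrows = [
        {
            "node": n,
            "kind": d["kind"],
            "count": d["count"],
            "sequence": d["sequence"],
        }
        for n, d in net.graph.nodes(data=True)
    ]
    pd.DataFrame(nrows).to_csv(node_path, sep="\t", index=False)
    if gml_path is not None:
        g = net.graph.copy()
        for _, _, data in g.edges(data=True):
            data.pop("changes", None)
        for _, data in g.nodes(data=True):
            data.pop("counts_by_population", None)
        nx.write_gml(g, str(gml_path))
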