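"""Median-joining networks for Y-STR haplotypes.

The construction follows the classic three-stage scheme:

1. an epsilon-relaxed minimum spanning network (the union of all minimum
   spanning trees, plus links within ``epsilon`` steps of the threshold at
   each merge of a Kruskal-style sweep; ``epsilon=0`` gives the plain MSN);
2. augmentation with quasi-medians — for ordered STR states the
   quasi-median of three haplotypes is the coordinate-wise median — added
   whenever their inclusion reduces the total cost of connecting the
   current node set (the connection-cost criterion), iterated to a fixed
   point;
3. cleanup of obsolete median vectors (degree <= 2 inferred nodes that lie
   on no shortest path between sampled haplotypes).

Determinism: haplotypes are processed in lexicographic order, and among
equal-cost candidate medians the lexicographically smallest is added
first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .io import HaplotypeTable
from .loci import NETWORK_21

Haplotype = tuple[int, ...]

MAX_ROUNDS = 50


class ConvergenceError(RuntimeError):
    """Median augmentation failed to reach a fixed point."""


@dataclass
class MJNetwork:
    """Undirected network over sampled + inferred haplotype nodes.

    Node attributes: ``haplotype`` (integer tuple), ``multiplicity``
    (0 for inferred median vectors), ``annotations`` (clan/haplogroup
    composition for sampled nodes).  Edge attribute ``steps`` is the
    absolute step distance.
    """

    graph: nx.Graph
    epsilon: int
    loci: tuple[str, ...]

    @property
    def sampled_nodes(self) -> list[Haplotype]:
        return [n for n, m in self.graph.nodes(data="multiplicity") if m > 0]

    @property
    def median_nodes(self) -> list[Haplotype]:
        return [n for n, m in self.graph.nodes(data="multiplicity") if m == 0]

    def total_length(self) -> float:
        return float(sum(w for _, _, w in self.graph.edges(data="steps")))


# -- input preparation -----------------------------------------------------


def prepare_network_input(
    table: HaplotypeTable,
    loci: Sequence[str] | None = None,
    null_policy: str = "drop-sample",
) -> tuple[np.ndarray, np.ndarray, list[dict], list[str]]:
    """Integer haplotype matrix for network building.

    Uses the single-copy panel (DYS385 excluded; 21 loci for the default
    panel); microvariants are rounded half-up; identical rows are
    collapsed with multiplicities and clan/haplogroup composition kept as
    annotations.  Samples with a null or duplicated call at a retained
    locus are dropped (``null_policy='drop-sample'``) or the offending
    loci are dropped table-wide (``'drop-locus'``).
    """
    if loci is None:
        loci = [n for n in NETWORK_21 if n in table.locus_names]
    names = list(loci)
    grid: list[list[int | None]] = []
    for i in range(table.n_samples):
        row: list[int | None] = []
        for n in names:
            c = table.call(i, n)
            if c.is_value:
                row.append(int(np.floor(c.repeats + 0.5)))
            else:
                row.append(None)
        grid.append(row)

    if null_policy == "drop-locus":
        bad = {j for row in grid for j, v in enumerate(row) if v is None}
        keep = [j for j in range(len(names)) if j not in bad]
        names = [names[j] for j in keep]
        grid = [[row[j] for j in keep] for row in grid]
        sample_idx = list(range(table.n_samples))
    elif null_policy == "drop-sample":
        sample_idx = [i for i, row in enumerate(grid) if None not in row]
        grid = [grid[i] for i in sample_idx]
    else:
        raise ValueError(f"unknown null policy {null_policy!r}")
    if not grid or not names:
        raise ValueError("no haplotypes left after filtering")

    collapsed: dict[Haplotype, dict] = {}
    for i, row in zip(sample_idx, grid):
        key = tuple(row)
        info = collapsed.setdefault(
            key, {"multiplicity": 0, "clans": {}, "haplogroups": {}}
        )
        info["multiplicity"] += 1
        clan = str(table.meta["clan"].iloc[i])
        hg = str(table.meta["haplogroup"].iloc[i])
        info["clans"][clan] = info["clans"].get(clan, 0) + 1
        info["haplogroups"][hg] = info["haplogroups"].get(hg, 0) + 1

    keys = sorted(collapsed)  # lexicographic, for deterministic downstream order
    haplos = np.array(keys, dtype=int)
    mult = np.array([collapsed[k]["multiplicity"] for k in keys])
    annot = [collapsed[k] for k in keys]
    return haplos, mult, annot, names


# -- epsilon-MSN -----------------------------------------------------------


def _pairwise_steps(haplos: np.ndarray) -> np.ndarray:
    diff = haplos[:, None, :] - haplos[None, :, :]
    return np.abs(diff).sum(axis=2)


def epsilon_msn(haplos: np.ndarray, epsilon: int = 0) -> set[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    Single-linkage sweep: repeatedly find the minimal inter-component
    distance delta, link every inter-component pair within delta+epsilon,
    and merge.  At epsilon=0 this is the union of all MSTs.
    """
    n = len(haplos)
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    D = _pairwise_steps(haplos)
    comp = list(range(n))
    edges: set[tuple[int, int]] = set()
    while len(set(comp)) > 1:
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if comp[i] != comp[j] and (best is None or D[i, j] < best):
                    best = D[i, j]
        threshold = best + epsilon
        new_links = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if comp[i] != comp[j] and D[i, j] <= threshold
        ]
        edges.update(new_links)
        for i, j in new_links:
            ci, cj = comp[i], comp[j]
            if ci != cj:
                comp = [ci if c == cj else c for c in comp]
    return edges


# -- medians ---------------------------------------------------------------


def quasi_median(a: Sequence[int], b: Sequence[int], c: Sequence[int]) -> Haplotype:
    """Coordinate-wise median of three integer haplotypes."""
    arr = np.array([a, b, c], dtype=int)
    return tuple(int(x) for x in np.sort(arr, axis=0)[1])


def _mst_cost(haplos: np.ndarray) -> float:
    if len(haplos) < 2:
        return 0.0
    D = _pairwise_steps(haplos).astype(float)
    return float(minimum_spanning_tree(D).sum())


def median_joining(
    haplos: np.ndarray,
    multiplicities: Sequence[int] | None = None,
    epsilon: int = 0,
    annotations: Sequence[Mapping] | None = None,
    loci: Sequence[str] | None = None,
    max_rounds: int = MAX_ROUNDS,
) -> MJNetwork:
    """Build a median-joining network from integer haplotypes."""
    haplos = np.asarray(haplos, dtype=int)
    if haplos.ndim != 2 or len(haplos) < 2:
        raise ValueError("need a 2-D array of >= 2 haplotypes")
    if multiplicities is None:
        multiplicities = [1] * len(haplos)

    order = sorted(range(len(haplos)), key=lambda i: tuple(haplos[i]))
    sampled: dict[Haplotype, dict] = {}
    for i in order:
        key = tuple(int(x) for x in haplos[i])
        info = sampled.setdefault(key, {"multiplicity": 0, "annotations": {}})
        info["multiplicity"] += int(multiplicities[i])
        if annotations is not None:
            info["annotations"] = dict(annotations[i])

    nodes: list[Haplotype] = sorted(sampled)
    for round_no in range(max_rounds + 1):
        arr = np.array(nodes, dtype=int)
        edges = epsilon_msn(arr, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        # connected triples: u with two linked partners v, w
        candidates: set[Haplotype] = set()
        existing = set(nodes)
        for u in range(len(nodes)):
            for v in sorted(adj[u]):
                for w in sorted(adj[u]):
                    if v < w:
                        m = quasi_median(nodes[u], nodes[v], nodes[w])
                        if m not in existing:
                            candidates.add(m)
        added = False
        current_cost = _mst_cost(arr)
        for m in sorted(candidates):
            trial = np.vstack([np.array(nodes, dtype=int), np.array(m)[None, :]])
            new_cost = _mst_cost(trial)
            if new_cost < current_cost - 1e-9:
                nodes.append(m)
                nodes.sort()
                current_cost = _mst_cost(np.array(nodes, dtype=int))
                added = True
        if not added:
            break
    else:
        raise ConvergenceError(
            f"median augmentation did not converge in {max_rounds} rounds"
        )

    nodes = _cleanup(nodes, sampled, epsilon)
    arr = np.array(nodes, dtype=int)
    edges = epsilon_msn(arr, epsilon) if len(nodes) > 1 else set()
    D = _pairwise_steps(arr)
    g = nx.Graph()
    for k in nodes:
        info = sampled.get(k)
        g.add_node(
            k,
            haplotype=k,
            multiplicity=info["multiplicity"] if info else 0,
            annotations=info["annotations"] if info else {},
        )
    for i, j in edges:
        g.add_edge(nodes[i], nodes[j], steps=int(D[i, j]))
    locus_names = tuple(loci) if loci is not None else tuple(
        f"L{i}" for i in range(haplos.shape[1])
    )
    return MJNetwork(graph=g, epsilon=epsilon, loci=locus_names)


def _cleanup(
    nodes: list[Haplotype], sampled: Mapping[Haplotype, dict], epsilon: int
) -> list[Haplotype]:
    """Drop degree<=2 median vectors that sit on no shortest path between
    sampled nodes; iterate, since removals change degrees."""
    nodes = list(nodes)
    while True:
        if len(nodes) < 2:
            return nodes
        arr = np.array(nodes, dtype=int)
        edges = epsilon_msn(arr, epsilon)
        g = nx.Graph()
        g.add_nodes_from(range(len(nodes)))
        D = _pairwise_steps(arr)
        for i, j in edges:
            g.add_edge(i, j, weight=int(D[i, j]))
        sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        sampled_idx = [i for i, k in enumerate(nodes) if k in sampled]
        removable = []
        for i, k in enumerate(nodes):
            if k in sampled or g.degree(i) > 2:
                continue
            on_path = any(
                s != i != t and sp[s].get(i, np.inf) + sp[i].get(t, np.inf)
                == sp[s].get(t, np.inf)
                for ai, s in enumerate(sampled_idx)
                for t in sampled_idx[ai + 1:]
            )
            if not on_path:
                removable.append(k)
        if not removable:
            return nodes
        nodes = [k for k in nodes if k not in set(removable)]


def build_network(
    table: HaplotypeTable,
    epsilon: int = 0,
    loci: Sequence[str] | None = None,
    null_policy: str = "drop-sample",
) -> MJNetwork:
    """End-to-end: prepare input from a table and build the MJ network."""
    haplos, mult, annot, names = prepare_network_input(table, loci, null_policy)
    return median_joining(haplos, mult, epsilon, annot, names)


# -- export ----------------------------------------------------------------


def _node_id(h: Haplotype) -> str:
    return "-".join(str(x) for x in h)


def export_network(net: MJNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML, DOT, or a tabular node+edge listing.

    Node size attribute = multiplicity; edge label = mutational steps;
    clan composition serialized into node attributes.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        for n, data in net.graph.nodes(data=True):
            clans = data.get("annotations", {}).get("clans", {})
            g.add_node(
                _node_id(n),
                haplotype=_node_id(n),
                multiplicity=int(data["multiplicity"]),
                clans=";".join(f"{k}:{v}" for k, v in sorted(clans.items())),
            )
        for u, v, w in net.graph.edges(data="steps"):
            g.add_edge(_node_id(u), _node_id(v), steps=int(w))
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = ["graph mjnetwork {"]
        for n, data in net.graph.nodes(data=True):
            m = data["multiplicity"]
            shape = "circle" if m > 0 else "point"
            lines.append(
                f'  "{_node_id(n)}" [shape={shape}, width={max(0.2, 0.2 * m):.2f}];'
            )
        for u, v, w in net.graph.edges(data="steps"):
            lines.append(f'  "{_node_id(u)}" -- "{_node_id(v)}" [label="{w}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "tabular":
        node_lines = ["node\tmultiplicity\tclans"]
        for n, data in sorted(net.graph.nodes(data=True)):
            clans = data.get("annotations", {}).get("clans", {})
            comp = ";".join(f"{k}:{v}" for k, v in sorted(clans.items()))
            node_lines.append(f"{_node_id(n)}\t{data['multiplicity']}\t{comp}")
        edge_lines = ["source\ttarget\tsteps"]
        for u, v, w in sorted(net.graph.edges(data="steps")):
            edge_lines.append(f"{_node_id(u)}\t{_node_id(v)}\t{w}")
        path.write_text("\n".join(node_lines + [""] + edge_lines) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_network_tabular(path: str | Path) -> MJNetwork:
    """Round-trip loader for the tabular export."""
    text = Path(path).read_text().strip("\n")
    node_part, edge_part = text.split("\n\n")
    g = nx.Graph()
    loci_len = None
    for line in node_part.splitlines()[1:]:
        nid, mult, clans = (line.split("\t") + [""])[:3]
        h = tuple(int(x) for x in nid.split("-"))
        loci_len = len(h)
        comp = {}
        if clans:
            for item in clans.split(";"):
                k, v = item.rsplit(":", 1)
                comp[k] = int(v)
        g.add_node(h, haplotype=h, multiplicity=int(mult),
                   annotations={"clans": comp} if comp else {})
    for line in edge_part.splitlines()[1:]:
        u, v, w = line.split("\t")
        g.add_edge(
            tuple(int(x) for x in u.split("-")),
            tuple(int(x) for x in v.split("-")),
            steps=int(w),
        )
    loci = tuple(f"L{i}" for i in range(loci_len or 0))
    return MJNetwork(graph=g, epsilon=0, loci=loci)
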