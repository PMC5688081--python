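"""Median-joining haplotype networks for binary haplotypes (ε = 0).

The network starts from the minimum-spanning network (the union of all
minimum spanning trees under Hamming distance; ε = 0 keeps only links that
occur in some MST).  For binary characters the quasi-median of three
sequences is exactly their per-site majority vector, so candidate Steiner
("median") vertices are majority vectors of connected vertex triples; a
candidate is added only when it strictly reduces the total spanning cost,
and inferred vertices that stop paying for themselves are deleted.  The
procedure iterates to a fixpoint and is deterministic: candidates are
ranked by cost reduction then lexicographic string order.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Vertex:
    haplotype: str
    kind: str                     # "observed" | "median"
    counts: dict[str, int] = field(default_factory=dict)   # population → count

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class MedianJoiningNetwork:
    vertices: list[Vertex]
    edges: list[tuple[int, int, int]]     # (vertex index, vertex index, Hamming weight)
    total_length: int

    def vertex_index(self, haplotype: str) -> int:
        for i, v in enumerate(self.vertices):
            if v.haplotype == haplotype:
                return i
        raise KeyError(haplotype)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, v in enumerate(self.vertices):
            g.add_node(i, haplotype=v.haplotype, kind=v.kind, counts=v.counts)
        for i, j, w in self.edges:
            g.add_edge(i, j, weight=w)
        return g


def _hamming_matrix(strings: list[str]) -> np.ndarray:
    arr = np.array([[int(c) for c in s] for s in strings], dtype=np.int8)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def _msn_edges(dist: np.ndarray) -> list[tuple[int, int, int]]:
    """Edges belonging to at least one minimum spanning tree.

    Kruskal characterisation: an edge of weight w is in some MST iff its
    endpoints are in different components of the graph restricted to edges
    of weight strictly below w.
    """
    n = dist.shape[0]
    if n <= 1:
        return []
    pairs = sorted(
        ((int(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, int]] = []
    k = 0
    while k < len(pairs):
        w = pairs[k][0]
        tier = []
        while k < len(pairs) and pairs[k][0] == w:
            tier.append(pairs[k])
            k += 1
        # membership test against components formed by strictly smaller weights
        for w_, i, j in tier:
            if find(i) != find(j):
                edges.append((i, j, w_))
        for w_, i, j in tier:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return edges


def _mst_length(dist: np.ndarray) -> int:
    from scipy.sparse.csgraph import minimum_spanning_tree

    if dist.shape[0] <= 1:
        return 0
    return int(round(minimum_spanning_tree(dist).sum()))


def _majority(a: str, b: str, c: str) -> str:
    return "".join(
        "1" if (x + y + z).count("1") >= 2 else "0" for x, y, z in zip(a, b, c)
    )


def _normalise_input(haplotypes) -> dict[str, dict[str, int]]:
    """Accept dict str→int, dict str→{pop: int}, or iterable of (str, pop)."""
    table: dict[str, dict[str, int]] = {}
    if isinstance(haplotypes, dict):
        for s, v in haplotypes.items():
            if isinstance(v, dict):
                table[s] = {p: int(c) for p, c in v.items()}
            else:
                table[s] = {"all": int(v)}
        return table
    seen_dupes = False
    for item in haplotypes:
        if isinstance(item, str):
            s, pop = item, "all"
        else:
            s, pop = item
        if s in table:
            seen_dupes = True
        table.setdefault(s, {})
        table[s][pop] = table[s].get(pop, 0) + 1
    if seen_dupes:
        warnings.warn("duplicate haplotype strings merged with summed counts")
    return table


def median_joining(haplotypes, epsilon: int = 0) -> MedianJoiningNetwork:
    """Median-joining network of binary haplotype strings (ε = 0 only).

    ``haplotypes`` maps each distinct 0/1 string to a count or a per-population
    count table; duplicate strings supplied separately are merged with a
    warning.
    """
    if epsilon != 0:
        raise NotImplementedError("only the simplest (epsilon = 0) network is supported")
    table = _normalise_input(haplotypes)
    if not table:
        raise ValueError("need at least one haplotype")
    lengths = {len(s) for s in table}
    if len(lengths) != 1:
        raise ValueError("haplotype strings must share one length")
    if any(set(s) - {"0", "1"} for s in table):
        raise ValueError("haplotypes must be binary 0/1 strings")

    observed = sorted(table)
    vertices = list(observed)

    def length_of(strs: list[str]) -> int:
        return _mst_length(_hamming_matrix(strs))

    while True:
        changed = False
        # (c) prune inferred vertices that no longer reduce spanning cost
        while True:
            removed = False
            for s in sorted(v for v in vertices if v not in table):
                rest = [v for v in vertices if v != s]
                if length_of(rest) <= length_of(vertices):
                    vertices = rest
                    removed = True
                    changed = True
                    break
            if not removed:
                break
        # (a) minimum-spanning network over the current vertex set
        dist = _hamming_matrix(vertices)
        base_len = _mst_length(dist)
        msn = _msn_edges(dist)
        adj: dict[int, set[int]] = {i: set() for i in range(len(vertices))}
        for i, j, _ in msn:
            adj[i].add(j)
            adj[j].add(i)
        # (b) medians of connected triples that strictly reduce the cost
        best: tuple[int, str] | None = None
        seen: set[str] = set()
        for v in range(len(vertices)):
            for u, w in itertools.combinations(sorted(adj[v]), 2):
                m = _majority(vertices[u], vertices[v], vertices[w])
                if m in vertices or m in seen:
                    continue
                seen.add(m)
                new_len = length_of(vertices + [m])
                if new_len < base_len:
                    cand = (new_len, m)
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            vertices.append(best[1])
            vertices.sort()
            changed = True
        if not changed:
            break

    dist = _hamming_matrix(vertices)
    edges = _msn_edges(dist)
    verts = [
        Vertex(
            haplotype=s,
            kind="observed" if s in table else "median",
            counts=dict(table.get(s, {})),
        )
        for s in vertices
    ]
    return MedianJoiningNetwork(
        vertices=verts, edges=edges, total_length=_mst_length(dist)
    )


# -- NEXUS serialisation -------------------------------------------------

def export_network(network: MedianJoiningNetwork, path: str | Path) -> None:
    """Write observed haplotypes + population counts as a NEXUS file.

    The file carries a standard-datatype CHARACTERS matrix of the observed
    haplotypes and a PopArt-style TRAITS block of per-population counts, so
    the network can be re-derived from the emitted data alone.
    """
    observed = [v for v in network.vertices if v.kind == "observed"]
    if not observed:
        raise ValueError("network has no observed haplotypes")
    pops = sorted({p for v in observed for p in v.counts})
    if not pops:
        pops = ["all"]
    nchar = len(observed[0].haplotype)
    labels = [f"H{i+1}" for i in range(len(observed))]
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"DIMENSIONS NTAX={len(observed)};",
        "TAXLABELS " + " ".join(labels) + ";",
        "END;",
        "",
        "BEGIN CHARACTERS;",
        f"DIMENSIONS NCHAR={nchar};",
        'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for lab, v in zip(labels, observed):
        lines.append(f"{lab} {v.haplotype}")
    lines += [
        ";",
        "END;",
        "",
        "BEGIN TRAITS;",
        f"Dimensions NTRAITS={len(pops)};",
        "Format labels=yes missing=? separator=Comma;",
        "TraitLabels " + " ".join(pops) + ";",
        "Matrix",
    ]
    for lab, v in zip(labels, observed):
        lines.append(lab + " " + ",".join(str(v.counts.get(p, 0)) for p in pops))
    lines += [";", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_network_nexus(path: str | Path) -> dict[str, dict[str, int]]:
    """Recover haplotype strings and per-population counts from NEXUS."""
    text = Path(path).read_text()
    blocks: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        up = line.upper()
        if up.startswith("BEGIN "):
            current = up.split()[1].rstrip(";")
            blocks[current] = []
        elif up == "END;" or up == "ENDBLOCK;":
            current = None
        elif current is not None:
            blocks[current].append(line)
    def matrix_rows(block: list[str]) -> list[tuple[str, str]]:
        rows: list[tuple[str, str]] = []
        in_matrix = False
        for line in block:
            if line.upper().startswith("MATRIX"):
                in_matrix = True
                continue
            if in_matrix:
                if line.startswith(";"):
                    break
                parts = line.rstrip(";").split()
                if len(parts) >= 2:
                    rows.append((parts[0], parts[1]))
        return rows

    chars = matrix_rows(blocks.get("CHARACTERS", blocks.get("DATA", [])))
    haps = dict(chars)
    traits = blocks.get("TRAITS", [])
    pop_labels: list[str] = []
    for line in traits:
        if line.upper().startswith("TRAITLABELS"):
            pop_labels = line.rstrip(";").split()[1:]
    counts = {}
    for label, row in matrix_rows(traits):
        vals = [int(x) for x in row.split(",")]
        counts[label] = dict(zip(pop_labels, vals))
    out: dict[str, dict[str, int]] = {}
    for label, string in haps.items():
        out[string] = counts.get(label, {})
    return out
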