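"""Molecular graphs for alkane carbon skeletons.

Alkanes C_nH_{2n+2} are represented by their hydrogen-suppressed carbon
skeletons: free trees on ``n`` vertices with maximum degree 4.  This module
builds those graphs from a small SMILES subset or a plain-text edge list,
provides generators for the structural families used throughout the package
(paths ``P_n``, brooms ``B_{n,q}``, and the high-conduction ``E_n`` series),
and enumerates all constitutional isomers of a given order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "MolecularGraph",
    "SmilesError",
    "EdgeListError",
    "parse_smiles",
    "to_smiles",
    "parse_edge_list",
    "write_edge_list",
    "path_graph",
    "broom_graph",
    "e_graph",
    "E_CATALOGUE",
    "enumerate_alkanes",
    "canonical_form",
    "is_isomorphic",
]


class SmilesError(ValueError):
    """Raised for SMILES text outside the supported carbon-skeleton subset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class EdgeListError(ValueError):
    """Raised for malformed or invalid edge-list text."""


@dataclass(frozen=True)
class MolecularGraph:
    """An undirected, simple, connected graph with 0-based vertex ids.

    Parameters
    ----------
    n : int
        Number of vertices (carbon atoms).
    edges : frozenset of (int, int)
        Unordered vertex pairs, stored as sorted tuples.
    label : str, optional
        Compound name.
    alkane_flag : bool
        When True the graph must be a valid alkane skeleton: acyclic
        (``|E| = n - 1``) with every degree at most 4.
    """

    n: int
    edges: frozenset = field()
    label: str | None = None
    alkane_flag: bool = True

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("graph needs at least one vertex")
        edges = frozenset(tuple(sorted(e)) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u}, {v}) outside vertex range 0..{self.n - 1}")
        adj = self._build_adjacency()
        object.__setattr__(self, "_adj", adj)
        if not self._connected():
            raise ValueError("graph is not connected")
        if self.alkane_flag:
            if len(edges) != self.n - 1:
                raise ValueError("alkane skeleton must be acyclic (|E| = n - 1)")
            bad = [v for v in range(self.n) if len(adj[v]) > 4]
            if bad:
                raise ValueError(f"vertex {bad[0]} has degree > 4; not an alkane skeleton")

    def _build_adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        for nbrs in adj:
            nbrs.sort()
        return adj

    def _connected(self) -> bool:
        seen = [False] * self.n
        stack = [0]
        seen[0] = True
        count = 1
        while stack:
            u = stack.pop()
            for w in self._adj[u]:
                if not seen[w]:
                    seen[w] = True
                    count += 1
                    stack.append(w)
        return count == self.n

    @property
    def adjacency(self) -> list[list[int]]:
        """Sorted adjacency lists, one per vertex."""
        return self._adj

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def degrees(self) -> list[int]:
        return [len(a) for a in self._adj]

    @property
    def is_tree(self) -> bool:
        return len(self.edges) == self.n - 1

    def neighbors(self, v: int) -> list[int]:
        return self._adj[v]

    def relabel(self, perm: dict[int, int], label: str | None = None) -> "MolecularGraph":
        """Return the graph with vertex ``v`` renamed to ``perm[v]``."""
        return MolecularGraph(
            self.n,
            frozenset((perm[u], perm[v]) for u, v in self.edges),
            label=label if label is not None else self.label,
            alkane_flag=self.alkane_flag,
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        name = f" {self.label!r}" if self.label else ""
        return f"<MolecularGraph{name} n={self.n} m={len(self.edges)}>"


# ---------------------------------------------------------------------------
# SMILES subset
# ---------------------------------------------------------------------------

def parse_smiles(text: str, alkane: bool = True, label: str | None = None) -> MolecularGraph:
    """Parse a carbon-skeleton SMILES string.

    Supported subset: ``C`` atoms, parenthesised branches, and — only when
    ``alkane`` is False — single-digit ring-closure labels.  Anything else
    (heteroatoms, bond symbols, aromatic atoms) raises :class:`SmilesError`
    naming the offending position.
    """
    if not text:
        raise SmilesError("empty SMILES", 0)
    edges: list[tuple[int, int]] = []
    stack: list[int] = []
    ring_open: dict[str, int] = {}
    prev: int | None = None
    n = 0

    def add_edge(u: int, v: int, pos: int) -> None:
        e = (min(u, v), max(u, v))
        if u == v or e in edge_set:
            raise SmilesError("duplicate or self bond", pos)
        edge_set.add(e)
        edges.append(e)

    edge_set: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text):
        if ch == "C":
            v = n
            n += 1
            if prev is not None:
                add_edge(prev, v, pos)
            prev = v
        elif ch == "(":
            if prev is None:
                raise SmilesError("branch before any atom", pos)
            stack.append(prev)
        elif ch == ")":
            if not stack:
                raise SmilesError("unbalanced ')'", pos)
            prev = stack.pop()
        elif ch.isdigit():
            if alkane:
                raise SmilesError("ring closure not allowed in an alkane skeleton", pos)
            if prev is None:
                raise SmilesError("ring closure before any atom", pos)
            if ch in ring_open:
                add_edge(ring_open.pop(ch), prev, pos)
            else:
                ring_open[ch] = prev
        else:
            raise SmilesError(f"unsupported token {ch!r} (carbon skeletons only)", pos)
    if stack:
        raise SmilesError("unbalanced '('", len(text))
    if ring_open:
        raise SmilesError(f"unclosed ring label {sorted(ring_open)[0]!r}", len(text))
    try:
        return MolecularGraph(n, frozenset(edges), label=label, alkane_flag=alkane)
    except ValueError as exc:
        raise SmilesError(str(exc), len(text)) from exc


def to_smiles(g: MolecularGraph) -> str:
    """Write a tree graph back out as branch-only SMILES (DFS from vertex 0)."""
    if not g.is_tree:
        raise ValueError("SMILES output is supported for acyclic skeletons only")
    out: list[str] = []

    def walk(v: int, parent: int | None) -> None:
        out.append("C")
        children = [w for w in g.neighbors(v) if w != parent]
        for i, w in enumerate(children):
            last = i == len(children) - 1
            if not last:
                out.append("(")
            walk(w, v)
            if not last:
                out.append(")")

    walk(0, None)
    return "".join(out)


# ---------------------------------------------------------------------------
# Edge-list text format
# ---------------------------------------------------------------------------

def parse_edge_list(text: str, alkane: bool = False, label: str | None = None) -> MolecularGraph:
    """Parse ``"u v"`` pairs, one per line; ``#`` starts a comment.

    Arbitrary nonnegative integer labels are accepted and renumbered to
    0..n-1 preserving ascending label order.
    """
    pairs: list[tuple[int, int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise EdgeListError(f"line {lineno}: expected two labels, got {line!r}")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise EdgeListError(f"line {lineno}: non-integer label in {line!r}") from exc
        if u < 0 or v < 0:
            raise EdgeListError(f"line {lineno}: labels must be nonnegative")
        if u == v:
            raise EdgeListError(f"line {lineno}: self-loop at {u}")
        pairs.append((u, v))
    if not pairs:
        raise EdgeListError("no edges found")
    labels = sorted({x for e in pairs for x in e})
    remap = {lab: i for i, lab in enumerate(labels)}
    edges = set()
    for u, v in pairs:
        e = (min(remap[u], remap[v]), max(remap[u], remap[v]))
        if e in edges:
            raise EdgeListError(f"duplicate edge {u} {v}")
        edges.add(e)
    try:
        return MolecularGraph(len(labels), frozenset(edges), label=label, alkane_flag=alkane)
    except ValueError as exc:
        raise EdgeListError(str(exc)) from exc


def write_edge_list(g: MolecularGraph) -> str:
    lines = [f"# {g.label}" if g.label else "# molecular graph"]
    lines += [f"{u} {v}" for u, v in sorted(g.edges)]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Graph families
# ---------------------------------------------------------------------------

def path_graph(n: int, label: str | None = None) -> MolecularGraph:
    """The path P_n: the normal-alkane skeleton of n carbons."""
    if n < 1:
        raise ValueError("path needs n >= 1")
    return MolecularGraph(n, frozenset((i, i + 1) for i in range(n - 1)), label=label)


def broom_graph(n: int, q: int, alkane: bool = True, label: str | None = None) -> MolecularGraph:
    """The broom B_{n,q}: P_{n-q} with q pendant vertices on one end.

    B_{n,2} and B_{n,3} are the 2-methyl and 2,2-dimethyl alkane series;
    B_{n,1} is the path P_n.
    """
    if q < 1:
        raise ValueError("broom needs q >= 1")
    if n - q < 1:
        raise ValueError("broom needs n - q >= 1")
    if alkane and q > 3:
        raise ValueError("alkane skeleton allows at most q = 3 pendant vertices")
    # vertices 0..n-q-1 form the path; pendants n-q..n-1 hang off vertex n-q-1
    path_part = [(i, i + 1) for i in range(n - q - 1)]
    hub = n - q - 1
    pendants = [(hub, n - q + j) for j in range(q)]
    return MolecularGraph(n, frozenset(path_part + pendants), label=label, alkane_flag=alkane)


#: The E_n series as catalogued in the source data: the known high-conduction
#: alkane of each order.  The verbal rule ("as many degree-4 vertices on a
#: path as possible") does not determine these uniquely, so the family is a
#: fixed catalogue and n outside 5..10 is refused rather than guessed.
E_CATALOGUE: dict[int, tuple[str, str]] = {
    5: ("2,2-Dimethylpropane", "CC(C)(C)C"),
    6: ("2,3-Dimethylbutane", "CC(C)C(C)C"),
    7: ("2,2,3-Trimethylbutane", "CC(C)(C)C(C)C"),
    8: ("2,2,3,3-Tetramethylbutane", "CC(C)(C)C(C)(C)C"),
    9: ("2,3,3,4-Tetramethylpentane", "CC(C)C(C)(C)C(C)C"),
    10: ("2,2,3,3,4-Pentamethylpentane", "CC(C)C(C)(C)C(C)(C)C"),
}


def e_graph(n: int) -> MolecularGraph:
    """The catalogued E_n structure (5 <= n <= 10)."""
    if n not in E_CATALOGUE:
        raise ValueError(f"E_{n} not catalogued (only 5 <= n <= 10)")
    name, smiles = E_CATALOGUE[n]
    return parse_smiles(smiles, label=name)


# ---------------------------------------------------------------------------
# Isomer enumeration and canonical forms
# ---------------------------------------------------------------------------

def enumerate_alkanes(n: int) -> list[MolecularGraph]:
    """All constitutional isomers of C_n: free trees with max degree <= 4.

    One representative per isomorphism class, sorted by canonical form.
    Bounded at n <= 12 (355 isomers), which covers every order the boiling
    point model is exercised on.
    """
    if not 1 <= n <= 12:
        raise ValueError("enumerate_alkanes supports 1 <= n <= 12")
    if n == 1:
        return [MolecularGraph(1, frozenset())]
    if n == 2:
        return [MolecularGraph(2, frozenset({(0, 1)}))]
    out = []
    for t in nx.nonisomorphic_trees(n):
        if max(d for _, d in t.degree()) <= 4:
            out.append(MolecularGraph(n, frozenset(t.edges())))
    out.sort(key=canonical_form)
    return out


def _ahu(g: MolecularGraph, root: int) -> str:
    """AHU encoding of the tree rooted at ``root``."""

    def enc(v: int, parent: int | None) -> str:
        subs = sorted(enc(w, v) for w in g.neighbors(v) if w != parent)
        return "(" + "".join(subs) + ")"

    return enc(root, None)


def _tree_centers(g: MolecularGraph) -> list[int]:
    # iterative leaf stripping
    if g.n == 1:
        return [0]
    deg = g.degrees()
    layer = [v for v in range(g.n) if deg[v] == 1]
    remaining = g.n
    while remaining > 2:
        remaining -= len(layer)
        nxt = []
        for v in layer:
            deg[v] = 0
            for w in g.neighbors(v):
                if deg[w] > 0:
                    deg[w] -= 1
                    if deg[w] == 1:
                        nxt.append(w)
        layer = nxt
    return sorted(layer)


def canonical_form(g: MolecularGraph) -> str:
    """Canonical string for a free tree: AHU encoding rooted at the center.

    Two trees are isomorphic iff their canonical forms are equal.  Raises for
    cyclic graphs (use :func:`is_isomorphic`, which falls back to a general
    isomorphism test).
    """
    if not g.is_tree:
        raise ValueError("canonical_form is defined for trees only")
    return min(_ahu(g, c) for c in _tree_centers(g))


def is_isomorphic(a: MolecularGraph, b: MolecularGraph) -> bool:
    if a.n != b.n or len(a.edges) != len(b.edges):
        return False
    if a.is_tree and b.is_tree:
        return canonical_form(a) == canonical_form(b)
    return nx.is_isomorphic(a.to_networkx(), b.to_networkx())
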