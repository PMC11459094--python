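"""Hydrogen-suppressed molecular graphs and degree-pair edge partitions.

A molecule is modelled as a simple connected graph: vertices are heavy
(non-hydrogen) atoms, edges are covalent bonds, and every bond — single,
double, triple or aromatic — contributes exactly one edge.  The *edge
partition* counts edges by the unordered pair of endpoint degrees
``{d_u, d_v}``; it is a sufficient statistic for every degree-based
topological index, so downstream modules never need the graph itself.
"""

from __future__ import annotations

import csv
import json
import warnings
from collections import Counter
from collections.abc import Hashable, Iterable, Iterator, Mapping
from pathlib import Path

import networkx as nx

from .errors import (
    DisconnectedGraphError,
    DuplicateEdgeError,
    EmptyInputError,
    SelfLoopError,
    SmilesParseError,
)

__all__ = [
    "MolecularGraph",
    "EdgePartition",
    "build_graph",
    "edge_partition",
    "parse_smiles",
    "read_edge_list",
]


class MolecularGraph:
    """Immutable simple connected graph of heavy atoms.

    Vertex identifiers are opaque hashables; no canonical atom ordering is
    assumed anywhere.  Construction validates the molecular-graph invariants
    (no self-loops, no parallel edges, connected, every degree >= 1).
    """

    __slots__ = ("_g",)

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise EmptyInputError("graph has no vertices")
        loops = list(nx.nodes_with_selfloops(graph))
        if loops:
            raise SelfLoopError(f"self-loop at vertex {loops[0]!r}")
        if not nx.is_connected(graph):
            n = nx.number_connected_components(graph)
            raise DisconnectedGraphError(
                f"graph has {n} connected components; expected a single molecule"
            )
        if graph.number_of_nodes() < 2:
            raise EmptyInputError("a molecular graph needs at least one bond")
        self._g = nx.freeze(nx.Graph(graph))

    # -- basic views ---------------------------------------------------------

    @property
    def vertices(self) -> frozenset:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> tuple[tuple[Hashable, Hashable], ...]:
        return tuple(self._g.edges)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, vertex: Hashable) -> int:
        return self._g.degree[vertex]

    def degrees(self) -> dict[Hashable, int]:
        """Vertex -> heavy-atom degree (the valency d_u of the vertex)."""
        return dict(self._g.degree)

    def max_degree(self) -> int:
        return max(d for _, d in self._g.degree)

    def to_networkx(self) -> nx.Graph:
        """Mutable copy of the underlying graph."""
        return nx.Graph(self._g)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MolecularGraph(n_vertices={self.n_vertices}, n_edges={self.n_edges})"


class EdgePartition(Mapping):
    """Multiset of canonical degree pairs ``(a, b)`` with ``a <= b``.

    Maps each pair to the number of edges whose endpoint degrees are
    ``{a, b}``; counts sum to the number of edges of the source graph.
    Behaves as a read-only mapping; missing pairs look up as 0 via
    :meth:`get` while ``[]`` raises ``KeyError`` as usual.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[tuple[int, int], int]):
        clean: dict[tuple[int, int], int] = {}
        for pair, count in counts.items():
            a, b = pair
            if not (isinstance(a, int) and isinstance(b, int)) or a < 1 or b < 1:
                raise ValueError(f"degree pair {pair!r} must be positive integers")
            if not isinstance(count, int) or count < 1:
                raise ValueError(f"count for {pair!r} must be a positive integer")
            key = (a, b) if a <= b else (b, a)
            clean[key] = clean.get(key, 0) + count
        self._counts = dict(sorted(clean.items()))

    @property
    def n_edges(self) -> int:
        """Total edge count |E| of the source graph."""
        return sum(self._counts.values())

    def __getitem__(self, pair: tuple[int, int]) -> int:
        a, b = pair
        return self._counts[(a, b) if a <= b else (b, a)]

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EdgePartition({self._counts!r})"


def build_graph(
    edges: Iterable[tuple[Hashable, Hashable]],
    *,
    on_disconnected: str = "error",
) -> MolecularGraph:
    """Validate an explicit edge list into a :class:`MolecularGraph`.

    Parameters
    ----------
    edges
        Unordered vertex-identifier pairs, one per bond.
    on_disconnected
        ``"error"`` (default) rejects multi-component input;
        ``"largest"`` keeps the largest component and warns, for users who
        feed salt/mixture records anyway.
    """
    if on_disconnected not in ("error", "largest"):
        raise ValueError("on_disconnected must be 'error' or 'largest'")
    edge_list = list(edges)
    if not edge_list:
        raise EmptyInputError("edge list is empty")
    seen: set[frozenset] = set()
    g = nx.Graph()
    for u, v in edge_list:
        if u == v:
            raise SelfLoopError(f"self-loop edge ({u!r}, {v!r})")
        key = frozenset((u, v))
        if key in seen:
            raise DuplicateEdgeError(f"edge ({u!r}, {v!r}) listed more than once")
        seen.add(key)
        g.add_edge(u, v)
    if on_disconnected == "largest" and not nx.is_connected(g):
        components = sorted(nx.connected_components(g), key=len, reverse=True)
        warnings.warn(
            f"input has {len(components)} components; keeping the largest "
            f"({len(components[0])} of {g.number_of_nodes()} vertices)",
            stacklevel=2,
        )
        g = g.subgraph(components[0]).copy()
    return MolecularGraph(g)


def edge_partition(graph: MolecularGraph) -> EdgePartition:
    """Reduce a graph to its degree-pair edge partition.

    Every edge (u, v) is counted once under the canonical pair
    ``(min(d_u, d_v), max(d_u, d_v))``.
    """
    deg = graph.degrees()
    counts: Counter[tuple[int, int]] = Counter()
    for u, v in graph.edges:
        a, b = deg[u], deg[v]
        counts[(a, b) if a <= b else (b, a)] += 1
    return EdgePartition(counts)


def parse_smiles(smiles: str, *, on_disconnected: str = "error") -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed molecular graph.

    Heavy atoms become vertices; every bond (regardless of order or
    aromaticity) becomes one simple edge, so a vertex degree is its count of
    heavy-atom neighbours.  Stereochemistry, charges and isotopes are
    accepted by the parser but carry no weight in the graph.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    edges = [
        (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()) for bond in mol.GetBonds()
    ]
    if not edges:
        raise EmptyInputError(f"SMILES {smiles!r} has no bonds between heavy atoms")
    return build_graph(edges, on_disconnected=on_disconnected)


def read_edge_list(path: str | Path, *, on_disconnected: str = "error") -> MolecularGraph:
    """Read an edge list from CSV/TSV (two columns, header optional) or JSON.

    JSON input is a list of two-element lists.  CSV/TSV delimiter is sniffed;
    a first row that repeats no vertex and parses as text labels like
    ``source,target`` is treated as a header.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        pairs = json.loads(path.read_text())
        return build_graph([tuple(p) for p in pairs], on_disconnected=on_disconnected)
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows = [row for row in csv.reader(text.splitlines(), delimiter=delimiter) if row]
    if not rows:
        raise EmptyInputError(f"{path} is empty")
    header_tokens = {"source", "target", "u", "v", "from", "to", "atom1", "atom2"}
    if {cell.strip().lower() for cell in rows[0][:2]} <= header_tokens:
        rows = rows[1:]
    return build_graph(
        [(r[0].strip(), r[1].strip()) for r in rows], on_disconnected=on_disconnected
    )
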