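"""Directed acyclic causal graphs with observed/latent nodes and d-separation.

The graph is the substrate for everything else in the package: implied
conditional independencies, covariate adjustment sets and the structural
equation simulator all reduce to reachability questions on it.  Two
independent d-separation routines are provided:

``CausalGraph.d_separated``
    The production routine, via reachability in the moralized ancestral
    subgraph (the classical Lauritzen construction, equivalent to Bayes-ball).

``CausalGraph.d_separated_bruteforce``
    A deliberately naive oracle that enumerates every simple path between the
    two nodes and applies the chain/fork/collider blocking rules path by path.
    It exists so the efficient routine can be cross-validated exhaustively in
    the test suite; it refuses graphs with more than ``2**16`` simple paths.

Nodes are case-sensitive strings.  Latent (unmeasured) nodes participate in
all separation queries as ordinary vertices; they are only special in that
conditioning on them is rejected by default, since one cannot condition on a
variable that was never measured.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator

import networkx as nx

from .errors import (
    CyclicGraphError,
    GraphQueryError,
    PathBudgetError,
    UnknownNodeError,
)

__all__ = ["CausalGraph"]

_PATH_BUDGET = 2**16


class CausalGraph:
    """A directed acyclic graph whose nodes carry an observed/latent flag.

    Construction is all-or-nothing: duplicate edges, self-loops, undeclared
    endpoints and directed cycles raise immediately and leave no partially
    built object.  Mutation (``add_node``/``add_edge``) re-validates.

    Parameters
    ----------
    nodes:
        Iterable of node names.  Every edge endpoint must be declared here
        (or via ``latent``).
    edges:
        Iterable of ``(cause, effect)`` pairs.
    latent:
        Subset of ``nodes`` flagged as unmeasured.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
        latent: Iterable[str] = (),
    ):
        nodes = list(nodes)
        latent = set(latent)
        if len(nodes) != len(set(nodes)):
            raise GraphQueryError("duplicate node names in declaration")
        unknown_latent = latent - set(nodes)
        if unknown_latent:
            raise UnknownNodeError(sorted(unknown_latent)[0])
        g = nx.DiGraph()
        g.add_nodes_from((n, {"latent": n in latent}) for n in nodes)
        seen: set[tuple[str, str]] = set()
        for cause, effect in edges:
            if cause == effect:
                raise GraphQueryError(f"self-loop on {cause!r}")
            if (cause, effect) in seen:
                raise GraphQueryError(f"duplicate edge {cause!r} -> {effect!r}")
            for end in (cause, effect):
                if end not in g:
                    raise UnknownNodeError(end)
            seen.add((cause, effect))
            g.add_edge(cause, effect)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CyclicGraphError(f"edge list contains a directed cycle: {cycle}")
        self._g = g
        self._rebuild_index()

    # -- bitmask index ------------------------------------------------------
    # Separation queries are hot (the test oracle runs millions of them), so
    # parents/children/ancestors are cached as integer bitmasks over a fixed
    # sorted node order.

    def _rebuild_index(self) -> None:
        self._order: tuple[str, ...] = tuple(sorted(self._g.nodes))
        self._idx = {n: i for i, n in enumerate(self._order)}
        n = len(self._order)
        self._pmask = [0] * n
        self._cmask = [0] * n
        for cause, effect in self._g.edges:
            self._pmask[self._idx[effect]] |= 1 << self._idx[cause]
            self._cmask[self._idx[cause]] |= 1 << self._idx[effect]

    def _mask(self, names: Iterable[str]) -> int:
        m = 0
        for name in names:
            m |= 1 << self._index(name)
        return m

    def _index(self, name: str) -> int:
        try:
            return self._idx[name]
        except KeyError:
            raise UnknownNodeError(name) from None

    @staticmethod
    def _bits(mask: int) -> Iterator[int]:
        while mask:
            low = mask & -mask
            yield low.bit_length() - 1
            mask ^= low

    def _closure(self, seed_mask: int, step: list[int]) -> int:
        """Reflexive-transitive closure of ``seed_mask`` under ``step`` masks."""
        out = seed_mask
        frontier = seed_mask
        while frontier:
            nxt = 0
            for i in self._bits(frontier):
                nxt |= step[i]
            frontier = nxt & ~out
            out |= nxt
        return out

    # -- basic accessors ----------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """All node names in sorted order."""
        return self._order

    @property
    def observed(self) -> tuple[str, ...]:
        return tuple(n for n in self._order if not self._g.nodes[n]["latent"])

    @property
    def latent(self) -> tuple[str, ...]:
        return tuple(n for n in self._order if self._g.nodes[n]["latent"])

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self._g.edges))

    def is_latent(self, node: str) -> bool:
        self._index(node)
        return bool(self._g.nodes[node]["latent"])

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return len(self._order)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and set(self.latent) == set(other.latent)
            and set(self.edges) == set(other.edges)
        )

    def __hash__(self):  # mutable; identity hash keeps dict usage honest
        return id(self)

    def has_edge(self, cause: str, effect: str) -> bool:
        return self._g.has_edge(cause, effect)

    def parents(self, node: str) -> set[str]:
        self._index(node)
        return set(self._g.predecessors(node))

    def children(self, node: str) -> set[str]:
        self._index(node)
        return set(self._g.successors(node))

    def ancestors(self, node: str) -> set[str]:
        """Reflexive ancestor set: ``node`` plus everything upstream of it."""
        m = self._closure(1 << self._index(node), self._pmask)
        return {self._order[i] for i in self._bits(m)}

    def descendants(self, node: str) -> set[str]:
        """Reflexive descendant set: ``node`` plus everything downstream."""
        m = self._closure(1 << self._index(node), self._cmask)
        return {self._order[i] for i in self._bits(m)}

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._g))

    # -- mutation -----------------------------------------------------------

    def add_node(self, node: str, latent: bool = False) -> None:
        if node in self._g:
            raise GraphQueryError(f"node {node!r} already declared")
        self._g.add_node(node, latent=latent)
        self._rebuild_index()

    def add_edge(self, cause: str, effect: str) -> None:
        """Add an edge, re-running the acyclicity check immediately."""
        for end in (cause, effect):
            self._index(end)
        if cause == effect:
            raise GraphQueryError(f"self-loop on {cause!r}")
        if self._g.has_edge(cause, effect):
            raise GraphQueryError(f"duplicate edge {cause!r} -> {effect!r}")
        self._g.add_edge(cause, effect)
        if not nx.is_directed_acyclic_graph(self._g):
            self._g.remove_edge(cause, effect)
            raise CyclicGraphError(
                f"adding {cause!r} -> {effect!r} would create a cycle"
            )
        self._rebuild_index()

    def remove_edge(self, cause: str, effect: str) -> None:
        if not self._g.has_edge(cause, effect):
            raise GraphQueryError(f"no edge {cause!r} -> {effect!r}")
        self._g.remove_edge(cause, effect)
        self._rebuild_index()

    def copy(self) -> "CausalGraph":
        return CausalGraph(self.nodes, self._g.edges, self.latent)

    def subgraph_without_edges(
        self, drop: Iterable[tuple[str, str]]
    ) -> "CausalGraph":
        drop = set(drop)
        return CausalGraph(
            self.nodes,
            (e for e in self._g.edges if e not in drop),
            self.latent,
        )

    # -- d-separation -------------------------------------------------------

    def _check_query(self, x: str, y: str, z: Iterable[str], allow_latent_z: bool):
        zs = set(z)
        xi, yi = self._index(x), self._index(y)
        if x == y:
            raise GraphQueryError("x and y must be distinct")
        if x in zs or y in zs:
            raise GraphQueryError("conditioning set must not contain x or y")
        zmask = 0
        for v in zs:
            if not allow_latent_z and self.is_latent(v):
                raise GraphQueryError(
                    f"cannot condition on latent node {v!r} "
                    "(pass allow_latent_z=True to permit)"
                )
            zmask |= 1 << self._index(v)
        return xi, yi, zmask

    def d_separated(
        self,
        x: str,
        y: str,
        z: Iterable[str] = (),
        *,
        allow_latent_z: bool = False,
    ) -> bool:
        """True iff ``z`` blocks every path between ``x`` and ``y``.

        Uses reachability in the moralized subgraph induced on the ancestors
        of ``{x, y} | z``: ``x`` and ``y`` are d-separated given ``z`` exactly
        when they fall in different components of that undirected graph after
        deleting ``z``.
        """
        xi, yi, zmask = self._check_query(x, y, z, allow_latent_z)
        return self._dsep_moral(xi, yi, zmask)

    def _dsep_moral(self, xi: int, yi: int, zmask: int) -> bool:
        anc = self._closure((1 << xi) | (1 << yi) | zmask, self._pmask)
        # Undirected moral adjacency restricted to the ancestral set: keep
        # original edges, and marry the parents of every retained node.
        n = len(self._order)
        adj = [0] * n
        for v in self._bits(anc):
            pa = self._pmask[v] & anc
            adj[v] |= pa
            for p in self._bits(pa):
                adj[p] |= (1 << v) | (pa & ~(1 << p))
        # BFS from x avoiding z.
        blocked = zmask
        seen = (1 << xi) | blocked
        frontier = 1 << xi
        target = 1 << yi
        while frontier:
            nxt = 0
            for v in self._bits(frontier):
                nxt |= adj[v]
            if nxt & target:
                return False
            frontier = nxt & ~seen
            seen |= nxt
        return True

    # -- brute-force oracle -------------------------------------------------

    def _simple_paths(self, xi: int, yi: int, budget: int = _PATH_BUDGET):
        """All simple paths x..y in the undirected skeleton, as index lists."""
        adj = [self._pmask[i] | self._cmask[i] for i in range(len(self._order))]
        paths: list[list[int]] = []
        stack = [(xi, 1 << xi, [xi])]
        while stack:
            v, visited, path = stack.pop()
            for w in self._bits(adj[v] & ~visited):
                if w == yi:
                    paths.append(path + [w])
                    if len(paths) > budget:
                        raise PathBudgetError(
                            "simple-path budget exceeded; use d_separated()"
                        )
                else:
                    stack.append((w, visited | (1 << w), path + [w]))
        return paths

    def _path_blocked(self, path: list[int], zmask: int) -> bool:
        """Blocking rules applied to one skeleton path.

        For each interior node b with neighbours a, c: if a->b<-c (collider),
        the triple blocks unless b or a descendant of b is in z; otherwise
        (chain or fork) it blocks iff b is in z.
        """
        for a, b, c in zip(path, path[1:], path[2:]):
            collider = bool(self._pmask[b] & (1 << a)) and bool(
                self._pmask[b] & (1 << c)
            )
            if collider:
                de = self._closure(1 << b, self._cmask)
                if not (de & zmask):
                    return True
            elif zmask & (1 << b):
                return True
        return False

    def d_separated_bruteforce(
        self,
        x: str,
        y: str,
        z: Iterable[str] = (),
        *,
        allow_latent_z: bool = False,
    ) -> bool:
        """Same contract as :meth:`d_separated`, by exhaustive path checking.

        Enumerates every simple path between ``x`` and ``y`` in the skeleton
        and declares separation iff each one is blocked.  Guard: raises
        :class:`PathBudgetError` beyond 2**16 paths.
        """
        xi, yi, zmask = self._check_query(x, y, z, allow_latent_z)
        return all(
            self._path_blocked(p, zmask) for p in self._simple_paths(xi, yi)
        )

    # -- serialization ------------------------------------------------------

    def to_edgelist_text(self) -> str:
        """Plain-text serialization: node declarations then one edge per line.

        Latent nodes are marked ``[latent]``.  Round-trips through
        :meth:`from_edgelist_text`.
        """
        lines = [
            f"node {n} [latent]" if self.is_latent(n) else f"node {n}"
            for n in self._order
        ]
        lines += [f"{c} -> {e}" for c, e in self.edges]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edgelist_text(cls, text: str) -> "CausalGraph":
        nodes: list[str] = []
        latent: list[str] = []
        edges: list[tuple[str, str]] = []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("node "):
                rest = line[5:].strip()
                if rest.endswith("[latent]"):
                    name = rest[: -len("[latent]")].strip()
                    latent.append(name)
                else:
                    name = rest
                nodes.append(name)
            elif "->" in line:
                cause, effect = (part.strip() for part in line.split("->", 1))
                for end in (cause, effect):
                    if end not in nodes:
                        nodes.append(end)
                edges.append((cause, effect))
            else:
                raise GraphQueryError(f"unparseable edge-list line: {raw!r}")
        return cls(nodes, edges, latent)

    def to_dot(self, name: str = "causal_model") -> str:
        """Graphviz DOT text; latent nodes rendered dashed, outputs sorted."""
        lines = [f"digraph {name} {{", "  rankdir=LR;"]
        for n in self._order:
            style = ' [style=dashed]' if self.is_latent(n) else ""
            lines.append(f'  "{n}"{style};')
        for c, e in self.edges:
            lines.append(f'  "{c}" -> "{e}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self) -> str:
        g = nx.DiGraph()
        for n in self._order:
            g.add_node(n, latent=self.is_latent(n))
        g.add_edges_from(self.edges)
        return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"

    def to_networkx(self) -> nx.DiGraph:
        """A copy of the backing :class:`networkx.DiGraph` (node attr ``latent``)."""
        return self._g.copy()

    def __repr__(self) -> str:
        return (
            f"CausalGraph({len(self.observed)} observed + "
            f"{len(self.latent)} latent nodes, {len(self.edges)} edges)"
        )
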