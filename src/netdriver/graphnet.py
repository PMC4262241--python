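"""Gene–gene network container, edge-list I/O, link counting and rewiring.

The global functional-coupling network is held as a simple undirected graph
over uppercase gene symbols. Two connectivity metrics are supported: direct
edges between a query and a gene set, and shared neighbours over query–member
pairs (useful on sparse networks). Degree-preserving randomization by repeated
double-edge swaps (Maslov–Sneppen) supplies the null model for all enrichment
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from numba import njit

logger = logging.getLogger("netdriver")

__all__ = [
    "GeneNetwork",
    "RewireConfig",
    "load_edge_list",
    "write_edge_list",
    "direct_links",
    "shared_neighbor_links",
    "within_set_links",
    "mapped_members",
    "rewire",
]


@dataclass(frozen=True)
class RewireConfig:
    """Parameters of one Maslov–Sneppen randomization.

    swap_factor
        Successful double-edge swaps performed per edge (default 100, the
        customary "well past mixing" budget).
    seed
        Integer seed; the whole randomization is deterministic given it.
    max_attempt_factor
        Attempt budget per requested swap. On rigid graphs (e.g. a star) most
        proposals are rejected; the walk stops with a warning once
        ``max_attempt_factor * swap_factor * E`` proposals have been spent.
    """

    swap_factor: float = 100.0
    seed: int = 0
    max_attempt_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.swap_factor <= 0:
            raise ValueError("swap_factor must be positive")
        if self.max_attempt_factor < 1:
            raise ValueError("max_attempt_factor must be >= 1")


class GeneNetwork:
    """Simple undirected graph over gene symbols.

    Invariants: no self-loops, no duplicate edges, sum of degrees equals twice
    the edge count. Isolated nodes are permitted only when explicitly loaded.
    Adjacency is stored as a dict of neighbour sets, which keeps the hot
    link-counting operations (set intersections) cheap.
    """

    __slots__ = ("_adj", "_ensemble_cache")

    def __init__(self, adjacency: dict[str, set[str]]):
        self._adj = adjacency
        self._ensemble_cache: dict = {}
        self._check()

    def _check(self) -> None:
        for g, nb in self._adj.items():
            if g in nb:
                raise ValueError(f"self-loop at node {g!r}")
            for h in nb:
                if g not in self._adj.get(h, ()):  # pragma: no cover - guard
                    raise ValueError(f"asymmetric adjacency {g!r}-{h!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "GeneNetwork":
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop edge {u!r}-{v!r}")
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        return cls(adj)

    @classmethod
    def from_networkx(cls, graph) -> "GeneNetwork":
        return cls.from_edges(
            ((str(u), str(v)) for u, v in graph.edges()),
            nodes=(str(n) for n in graph.nodes()),
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._adj)
        g.add_edges_from(self.edges())
        return g

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    @property
    def edge_count(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def degree(self, gene: str) -> int:
        try:
            return len(self._adj[gene])
        except KeyError:
            raise KeyError(f"gene {gene!r} not in network") from None

    def degrees(self) -> dict[str, int]:
        return {g: len(nb) for g, nb in self._adj.items()}

    def neighbors(self, gene: str) -> set[str]:
        try:
            return self._adj[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in network") from None

    def edges(self) -> Iterator[tuple[str, str]]:
        for g, nb in self._adj.items():
            for h in nb:
                if g < h:
                    yield (g, h)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges())


# -- I/O -------------------------------------------------------------------


def _open(source: str | Path | IO[str]):
    if hasattr(source, "read"):
        return source, False
    return open(source, "rt"), True


def load_edge_list(
    source: str | Path | IO[str],
    min_confidence: float | None = None,
    sif: bool = False,
) -> GeneNetwork:
    """Read a network from a TSV edge list.

    Expected layout is ``geneA<TAB>geneB[<TAB>confidence]``; ``#`` starts a
    comment. With ``sif=True`` the middle field of a 3-column SIF line is a
    relation label and is discarded. Symbols are uppercased, duplicate and
    reversed-duplicate pairs collapsed, and self-loop lines dropped with a
    warning. Lines with confidence below ``min_confidence`` are skipped.
    """
    fh, close = _open(source)
    adj: dict[str, set[str]] = {}
    n_lines = 0
    n_selfloops = 0
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2 or (sif and len(fields) < 3):
                raise ValueError(f"malformed edge line {lineno}: {raw!r}")
            if sif:
                u, v = fields[0], fields[2]
                conf = None
            else:
                u, v = fields[0], fields[1]
                conf = None
                if len(fields) >= 3:
                    try:
                        conf = float(fields[2])
                    except ValueError:
                        raise ValueError(
                            f"malformed confidence on line {lineno}: {fields[2]!r}"
                        ) from None
            n_lines += 1
            if min_confidence is not None and conf is not None and conf < min_confidence:
                continue
            u, v = u.upper(), v.upper()
            if u == v:
                n_selfloops += 1
                continue
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
    finally:
        if close:
            fh.close()
    if n_lines == 0:
        raise ValueError("empty network input: no edge lines found")
    if n_selfloops:
        logger.warning("dropped %d self-loop line(s) while loading network", n_selfloops)
    return GeneNetwork(adj)


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for u, v in sorted(net.edges()):
            fh.write(f"{u}\t{v}\n")


# -- link counting ---------------------------------------------------------


def mapped_members(net: GeneNetwork, genes: Iterable[str]) -> tuple[set[str], list[str]]:
    """Split a gene set into network-mapped members and unmapped symbols."""
    mapped, missing = set(), []
    for g in genes:
        (mapped.add if g in net else missing.append)(g)
    return mapped, missing


def direct_links(net: GeneNetwork, i: str, G: Iterable[str]) -> int:
    """Number of edges between gene ``i`` and members of ``G`` (``i`` excluded).

    The query is always treated as external: if ``i`` itself is a member of
    ``G`` it does not contribute. Members of ``G`` absent from the network are
    ignored.
    """
    nb = net.neighbors(i)
    members, _ = mapped_members(net, G)
    members.discard(i)
    return len(nb & members)


def shared_neighbor_links(net: GeneNetwork, i: str, G: Iterable[str]) -> int:
    """Sum over ``j`` in ``G`` (excluding ``i``) of shared-neighbour counts
    ``|N(i) ∩ N(j)|``."""
    nb = net.neighbors(i)
    members, _ = mapped_members(net, G)
    members.discard(i)
    return sum(len(nb & net.neighbors(j)) for j in members)


def within_set_links(net: GeneNetwork, G: Iterable[str], mode: str = "direct") -> int:
    """Internal connectivity of a gene set.

    ``direct``: number of edges with both endpoints in ``G``. ``shared``:
    shared-neighbour counts summed over all unordered member pairs.
    """
    members, _ = mapped_members(net, G)
    if len(members) < 2:
        raise ValueError(
            f"within-set count needs >=2 mapped members, got {len(members)}"
        )
    ordered = sorted(members)
    if mode == "direct":
        return sum(len(net.neighbors(g) & members) for g in members) // 2
    if mode == "shared":
        total = 0
        for a in range(len(ordered)):
            na = net.neighbors(ordered[a])
            for b in range(a + 1, len(ordered)):
                total += len(na & net.neighbors(ordered[b]))
        return total
    raise ValueError(f"unknown mode {mode!r}")


# -- degree-preserving randomization ---------------------------------------


@njit(cache=True)
def _swap_chunk(eu, ev, off, deg, neigh, e1, e2, flip, nswap_left):  # pragma: no cover
    """Apply a batch of proposed double-edge swaps in place.

    ``eu/ev`` hold edge endpoints as node indices; ``off/deg/neigh`` is a
    fixed-slab adjacency (each node owns a slab of length ``deg`` whose values
    are its current neighbours). Returns (swaps done, proposals consumed).
    """
    swaps = 0
    used = 0
    for t in range(e1.size):
        if swaps >= nswap_left:
            break
        used += 1
        i1 = e1[t]
        i2 = e2[t]
        if i1 == i2:
            continue
        a = eu[i1]
        b = ev[i1]
        c = eu[i2]
        d = ev[i2]
        if flip[t] == 1:
            c, d = d, c
        # proposal: replace (a,b),(c,d) with (a,d),(c,b)
        if a == c or a == d or b == c or b == d:
            continue  # self-loop or no-op
        dup = False
        s = off[a]
        for k in range(s, s + deg[a]):
            if neigh[k] == d:
                dup = True
                break
        if not dup:
            s = off[c]
            for k in range(s, s + deg[c]):
                if neigh[k] == b:
                    dup = True
                    break
        if dup:
            continue
        for k in range(off[a], off[a] + deg[a]):
            if neigh[k] == b:
                neigh[k] = d
                break
        for k in range(off[b], off[b] + deg[b]):
            if neigh[k] == a:
                neigh[k] = c
                break
        for k in range(off[c], off[c] + deg[c]):
            if neigh[k] == d:
                neigh[k] = b
                break
        for k in range(off[d], off[d] + deg[d]):
            if neigh[k] == c:
                neigh[k] = a
                break
        eu[i1], ev[i1] = a, d
        eu[i2], ev[i2] = c, b
        swaps += 1
    return swaps, used


def rewire(net: GeneNetwork, cfg: RewireConfig | None = None, **kwargs) -> GeneNetwork:
    """Return a degree-preserving randomized replica of ``net``.

    Repeated double-edge swaps: pick two edges (a,b) and (c,d), replace them
    with (a,d) and (c,b) unless that would create a self-loop or a duplicate
    edge. The node set, every node degree and the total edge count are
    preserved exactly. Performs ``swap_factor * E`` successful swaps, or stops
    with a warning once the attempt budget is exhausted (which is the expected
    outcome on rigid graphs whose degree sequence admits few rewirings).
    Deterministic given ``cfg.seed``.
    """
    if cfg is None:
        cfg = RewireConfig(**kwargs)
    E = net.edge_count
    if E < 2:
        raise ValueError("rewiring needs at least 2 edges")

    nodes = sorted(net._adj)
    index = {g: k for k, g in enumerate(nodes)}
    deg = np.array([len(net._adj[g]) for g in nodes], dtype=np.int64)
    off = np.zeros(len(nodes) + 1, dtype=np.int64)
    np.cumsum(deg, out=off[1:])
    neigh = np.empty(2 * E, dtype=np.int64)
    eu = np.empty(E, dtype=np.int64)
    ev = np.empty(E, dtype=np.int64)
    fill = off[:-1].copy()
    e = 0
    for g in nodes:
        gi = index[g]
        for h in net._adj[g]:
            hi = index[h]
            neigh[fill[gi]] = hi
            fill[gi] += 1
            if gi < hi:
                eu[e] = gi
                ev[e] = hi
                e += 1

    nswap = max(1, int(round(cfg.swap_factor * E)))
    budget = int(round(cfg.max_attempt_factor * nswap))
    rng = np.random.default_rng(cfg.seed)
    done = 0
    spent = 0
    while done < nswap and spent < budget:
        chunk = min(budget - spent, max(4096, 2 * (nswap - done)))
        s, u = _swap_chunk(
            eu,
            ev,
            off,
            deg,
            neigh,
            rng.integers(0, E, size=chunk),
            rng.integers(0, E, size=chunk),
            rng.integers(0, 2, size=chunk),
            nswap - done,
        )
        done += s
        spent += u
    if done < nswap:
        logger.warning(
            "rewiring stopped after %d/%d swaps (attempt budget %d exhausted)",
            done,
            nswap,
            budget,
        )
    adj: dict[str, set[str]] = {g: set() for g in nodes}
    for k in range(E):
        u, v = nodes[eu[k]], nodes[ev[k]]
        adj[u].add(v)
        adj[v].add(u)
    return GeneNetwork(adj)
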