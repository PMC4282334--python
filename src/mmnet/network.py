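"""Friendship-nomination networks: adjacency matrices, ego-nets and cliques.

Sociometric instruments ask each respondent (the *ego*) to name friends
(*alters*).  The resulting directed nomination structure is held as a binary
adjacency matrix ``D`` with ``D[i, j] = 1`` iff ``i`` nominated ``j``; a
symmetrized matrix ``D*`` (tie present if either nominated the other) feeds
the clique analyses.  Because alters may fall outside the sample, sampled
networks are sparse and contain many *isolates* — egos with no retained
nomination — which downstream models must tolerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedNetwork",
    "UndirectedNetwork",
    "CliqueSet",
    "NetworkSummary",
    "parse_adjacency_list",
    "parse_edge_list",
    "symmetrize",
    "ego_alters",
    "enumerate_maximal_cliques",
    "network_descriptives",
]


def _sort_key(x):
    # IDs may be ints or strings; keep numeric order when homogeneous,
    # fall back to a type-tagged key for mixed collections.
    return (type(x).__name__, x) if not isinstance(x, (int, np.integer)) else ("", x)


@dataclass(frozen=True)
class DirectedNetwork:
    """Directed nomination network.

    Attributes
    ----------
    node_ids : tuple
        Ordered, unique individual identifiers; fixes the row/column order.
    D : ndarray of shape (n, n)
        Binary matrix, ``D[i, j] = 1`` iff individual ``i`` nominates ``j``.
        Zero diagonal (self-nominations are excluded by construction).
    """

    node_ids: tuple
    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D)
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValueError("node_ids must be unique")
        if D.shape != (n, n):
            raise ValueError(f"D must be {n}x{n}, got {D.shape}")
        if not np.isin(D, (0, 1)).all():
            raise ValueError("D entries must be 0/1")
        if np.diagonal(D).any():
            raise ValueError("D must have a zero diagonal")
        object.__setattr__(self, "D", D.astype(np.int8, copy=False))

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index(self, node_id) -> int:
        try:
            return self._index[node_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {v: i for i, v in enumerate(self.node_ids)}
            )
            return self._index[node_id]

    def out_degrees(self) -> np.ndarray:
        return self.D.sum(axis=1)


@dataclass(frozen=True)
class UndirectedNetwork:
    """Symmetrized network: a tie wherever at least one nomination exists."""

    node_ids: tuple
    Dstar: np.ndarray

    def __post_init__(self):
        Dstar = np.asarray(self.Dstar)
        if not np.array_equal(Dstar, Dstar.T):
            raise ValueError("Dstar must be symmetric")
        if np.diagonal(Dstar).any():
            raise ValueError("Dstar must have a zero diagonal")
        object.__setattr__(self, "Dstar", Dstar.astype(np.int8, copy=False))

    @property
    def n(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True)
class CliqueSet:
    """Maximal (Luce–Perry) cliques of the undirected network, size >= min_size.

    Cliques are stored in canonical order: members sorted by ID, cliques
    sorted lexicographically, so repeated runs are byte-identical.
    """

    cliques: tuple
    min_size: int

    def __post_init__(self):
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        canon = tuple(
            tuple(sorted(c, key=_sort_key)) for c in self.cliques
        )
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate cliques")
        object.__setattr__(self, "cliques", tuple(sorted(canon)))

    def __len__(self) -> int:
        return len(self.cliques)

    def membership_counts(self, node_ids: Sequence) -> np.ndarray:
        """Number of cliques each individual belongs to, in node_ids order."""
        counts = {v: 0 for v in node_ids}
        for c in self.cliques:
            for v in c:
                counts[v] += 1
        return np.array([counts[v] for v in node_ids])


@dataclass(frozen=True)
class NetworkSummary:
    """Descriptive statistics of a sampled nomination network."""

    n: int
    n_isolates: int
    isolate_fraction: float
    mean_egonet_size_nonisolate: float
    clique_membership_counts: Mapping[str, np.ndarray] = field(default_factory=dict)
    max_memberships: Mapping[str, int] = field(default_factory=dict)


def parse_adjacency_list(
    records: Iterable[tuple],
    node_ids: Sequence | None = None,
    on_unknown: str = "drop",
) -> DirectedNetwork:
    """Build a directed network from an adjacency (node) list.

    Parameters
    ----------
    records : iterable of (ego_id, [alter_id, ...])
        One record per ego listing the friends it nominated.
    node_ids : sequence, optional
        The sample roster (e.g. from the covariate table), fixing node order.
        Individuals on the roster who never appear as ego get all-zero rows.
        If omitted, the roster is the egos in order of first appearance.
    on_unknown : {"drop", "error"}
        Nominations of individuals not on the roster emulate out-of-sample
        friends: dropped (with a logged count) by default, or raised on.
    """
    if on_unknown not in ("drop", "error"):
        raise ValueError("on_unknown must be 'drop' or 'error'")
    records = list(records)
    if not records:
        raise ValueError("empty adjacency list")
    seen = set()
    for ego, _ in records:
        if ego in seen:
            raise ValueError(f"duplicate ego record for ID {ego!r}")
        seen.add(ego)
    if node_ids is None:
        roster = tuple(ego for ego, _ in records)
    else:
        roster = tuple(node_ids)
        missing = seen - set(roster)
        if missing:
            raise ValueError(f"egos not on roster: {sorted(missing, key=_sort_key)}")
    index = {v: i for i, v in enumerate(roster)}
    n = len(roster)
    D = np.zeros((n, n), dtype=np.int8)
    n_dropped = 0
    for ego, alters in records:
        i = index[ego]
        for alter in alters:
            if alter == ego:  # self-nominations are assumed absent
                continue
            j = index.get(alter)
            if j is None:
                if on_unknown == "error":
                    raise ValueError(f"unknown alter {alter!r} nominated by {ego!r}")
                n_dropped += 1
                continue
            D[i, j] = 1
    if n_dropped:
        logger.info("dropped %d out-of-sample nominations", n_dropped)
    return DirectedNetwork(roster, D)


def parse_edge_list(edges: Iterable[tuple], node_ids: Sequence | None = None,
                    on_unknown: str = "drop") -> DirectedNetwork:
    """Build a directed network from (from_id, to_id) pairs."""
    edges = list(edges)
    by_ego: dict = {}
    order = []
    for a, b in edges:
        if a not in by_ego:
            by_ego[a] = []
            order.append(a)
        by_ego[a].append(b)
        if node_ids is None and b not in by_ego:
            by_ego[b] = []
            order.append(b)
    records = [(ego, by_ego[ego]) for ego in order]
    return parse_adjacency_list(records, node_ids=node_ids, on_unknown=on_unknown)


def symmetrize(net: DirectedNetwork) -> UndirectedNetwork:
    """Tie i–j present iff i nominated j, j nominated i, or both."""
    Dstar = np.maximum(net.D, net.D.T)
    return UndirectedNetwork(net.node_ids, Dstar)


def ego_alters(net: DirectedNetwork, ego) -> tuple:
    """The alters of ``ego``: everyone it nominated, in roster order."""
    i = net.index(ego)
    return tuple(net.node_ids[j] for j in np.flatnonzero(net.D[i]))


def enumerate_maximal_cliques(unet: UndirectedNetwork, min_size: int = 2) -> CliqueSet:
    """All maximal completely-connected subgroups with at least ``min_size`` members.

    Uses Bron–Kerbosch enumeration (networkx); only maximal cliques are
    emitted, matching the Luce–Perry definition. Output order is canonical.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    G = nx.from_numpy_array(unet.Dstar)
    cliques = [
        tuple(unet.node_ids[i] for i in c)
        for c in nx.find_cliques(G)
        if len(c) >= min_size
    ]
    return CliqueSet(tuple(cliques), min_size)


def network_descriptives(
    net: DirectedNetwork,
    unet: UndirectedNetwork | None = None,
    clique_sets: Mapping[str, CliqueSet] | None = None,
) -> NetworkSummary:
    """Isolate share, mean non-isolate ego-net size, clique membership counts.

    An *isolate* has out-degree zero in the directed network (no in-sample
    nominations).  Clique membership counts are tallied per individual for
    each supplied clique classification.
    """
    if unet is not None and unet.node_ids != net.node_ids:
        raise ValueError("node_ids differ between directed and undirected networks")
    out_deg = net.out_degrees()
    isolates = int((out_deg == 0).sum())
    nonzero = out_deg[out_deg > 0]
    mean_size = float(nonzero.mean()) if nonzero.size else float("nan")
    counts = {}
    maxima = {}
    for name, cs in (clique_sets or {}).items():
        c = cs.membership_counts(net.node_ids)
        counts[name] = c
        maxima[name] = int(c.max()) if c.size else 0
    return NetworkSummary(
        n=net.n,
        n_isolates=isolates,
        isolate_fraction=isolates / net.n,
        mean_egonet_size_nonisolate=mean_size,
        clique_membership_counts=counts,
        max_memberships=maxima,
    )


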