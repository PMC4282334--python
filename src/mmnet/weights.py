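"""Classifications and membership weight matrices.

A *classification* is a set of subgroups (schools, counties, dyads, cliques,
ego-nets) whose random effects enter the model.  Each individual may belong
to zero, one or many subgroups; the n x K weight matrix W links individual
responses to subgroup effects.  Three weighting schemes are supported:

``equal``
    w[i, j] = 1/n_i over the n_i memberships of i (rows sum to 1, or to 0
    for individuals with no membership — e.g. network isolates).
``unit``
    w[i, j] = 1 for every membership.
``inv_sqrt``
    w[i, j] = 1/sqrt(n_i).

Single-membership classifications (school, area) are the special case of
exactly one membership per individual, so every scheme gives one weight of 1
per row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .network import CliqueSet, DirectedNetwork, _sort_key

SCHEMES = ("equal", "unit", "inv_sqrt")

__all__ = [
    "MembershipMap",
    "WeightMatrix",
    "classification_from_cliques",
    "classification_from_egonets",
    "classification_from_labels",
    "build_weight_matrix",
    "row_standardize",
]


@dataclass(frozen=True)
class MembershipMap:
    """Subgroups of one classification and each individual's memberships.

    Attributes
    ----------
    classification_name : str
    node_ids : tuple
        Roster fixing the row order of derived weight matrices.
    groups : tuple of frozensets
        Member IDs of each subgroup (columns of the weight matrix).
    group_labels : tuple
        One label per subgroup.
    member_index : tuple of tuples
        ``member_index[i]`` lists the subgroup indices individual i belongs
        to; consistent with ``groups``.
    """

    classification_name: str
    node_ids: tuple
    groups: tuple
    group_labels: tuple

    def __post_init__(self):
        if len(self.groups) != len(self.group_labels):
            raise ValueError("groups and group_labels length mismatch")
        roster = set(self.node_ids)
        for g in self.groups:
            if not set(g) <= roster:
                raise ValueError("group member not on roster")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def member_index(self) -> tuple:
        try:
            return self._member_index
        except AttributeError:
            idx = {v: i for i, v in enumerate(self.node_ids)}
            per = [[] for _ in self.node_ids]
            for j, g in enumerate(self.groups):
                for v in sorted(g, key=_sort_key):
                    per[idx[v]].append(j)
            mi = tuple(tuple(m) for m in per)
            object.__setattr__(self, "_member_index", mi)
            return mi

    def membership_counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.member_index])


@dataclass(frozen=True)
class WeightMatrix:
    """Sparse n x K nonnegative weights linking individuals to subgroups."""

    W: sp.csr_matrix
    scheme: str
    kind: str  # multiple-membership | single-membership | row-standardized-adjacency
    classification_name: str
    node_ids: tuple
    group_labels: tuple

    def __post_init__(self):
        W = sp.csr_matrix(self.W)
        if (W.data < 0).any():
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "W", W)

    @property
    def shape(self):
        return self.W.shape

    def toarray(self) -> np.ndarray:
        return self.W.toarray()


def classification_from_labels(
    labels: Sequence, node_ids: Sequence, name: str
) -> MembershipMap:
    """Single-membership classification from a group label per individual."""
    if len(labels) != len(node_ids):
        raise ValueError("labels and node_ids length mismatch")
    uniq = sorted(set(labels), key=_sort_key)
    members = {u: set() for u in uniq}
    for v, lab in zip(node_ids, labels):
        members[lab].add(v)
    return MembershipMap(
        classification_name=name,
        node_ids=tuple(node_ids),
        groups=tuple(frozenset(members[u]) for u in uniq),
        group_labels=tuple(uniq),
    )


def classification_from_cliques(
    cliques: CliqueSet, node_ids: Sequence, rule: str = "joint"
):
    """Clique classifications for the model.

    rule="joint" splits the maximal cliques into a dyad classification
    (size exactly 2) and a clique-3 classification (size >= 3) — when both
    enter one model the dyad level holds dyads only.  rule="alone" keeps all
    cliques in a single classification.
    """
    if rule not in ("joint", "alone"):
        raise ValueError("rule must be 'joint' or 'alone'")
    node_ids = tuple(node_ids)

    def _map(name, cs):
        return MembershipMap(
            classification_name=name,
            node_ids=node_ids,
            groups=tuple(frozenset(c) for c in cs),
            group_labels=tuple("+".join(map(str, c)) for c in cs),
        )

    if rule == "alone":
        return _map(f"clique{cliques.min_size}", cliques.cliques)
    dyads = [c for c in cliques.cliques if len(c) == 2]
    larger = [c for c in cliques.cliques if len(c) >= 3]
    return _map("clique2", dyads), _map("clique3", larger)


def classification_from_egonets(net: DirectedNetwork) -> MembershipMap:
    """Ego-net classification with one subgroup per individual-as-friend.

    The random effects attached to individual i's response are those of i's
    alters, so subgroup j collects the egos who nominated j and i's
    membership list is exactly i's alter list.  Under equal weights the
    resulting weight matrix coincides with the row-standardized adjacency
    matrix, giving the multiple-membership ego-net model and the network
    disturbances model literally the same weight information.  Network
    isolates belong to no subgroup and keep an all-zero weight row.
    """
    D = net.D
    groups = tuple(
        frozenset(net.node_ids[i] for i in np.flatnonzero(D[:, j]))
        for j in range(net.n)
    )
    return MembershipMap(
        classification_name="egonet",
        node_ids=net.node_ids,
        groups=groups,
        group_labels=net.node_ids,
    )


def build_weight_matrix(mmap: MembershipMap, scheme: str = "equal") -> WeightMatrix:
    """Weight matrix for a classification under the given scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    rows, cols, vals = [], [], []
    counts = mmap.membership_counts()
    for i, members in enumerate(mmap.member_index):
        n_i = len(members)
        if n_i == 0:
            continue
        if scheme == "equal":
            w = 1.0 / n_i
        elif scheme == "unit":
            w = 1.0
        else:
            w = 1.0 / np.sqrt(n_i)
        for j in members:
            rows.append(i)
            cols.append(j)
            vals.append(w)
    W = sp.csr_matrix(
        (vals, (rows, cols)), shape=(mmap.n, mmap.n_groups), dtype=float
    )
    single = bool(counts.size) and (counts == 1).all()
    return WeightMatrix(
        W=W,
        scheme=scheme,
        kind="single-membership" if single else "multiple-membership",
        classification_name=mmap.classification_name,
        node_ids=mmap.node_ids,
        group_labels=mmap.group_labels,
    )


def row_standardize(net: DirectedNetwork) -> WeightMatrix:
    """Row-standardized adjacency matrix (zero rows stay zero).

    This is the n x n weight matrix of the network autocorrelation models;
    it carries the same weight information as the equal-scheme ego-net
    multiple-membership matrix.
    """
    D = net.D.astype(float)
    deg = D.sum(axis=1)
    nz = deg > 0
    D[nz] /= deg[nz, None]
    return WeightMatrix(
        W=sp.csr_matrix(D),
        scheme="equal",
        kind="row-standardized-adjacency",
        classification_name="egonet",
        node_ids=net.node_ids,
        group_labels=net.node_ids,
    )
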