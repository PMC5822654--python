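"""Friendship-network construction from friend nominations.

Children nominate up to a handful of their closest schoolmates; the analysis
works on per-sex, within-school directed networks built from those
nominations.  The end product is the row-standardised weight matrix W used by
the Moran diagnostics and the network autocorrelation model: entry (i, j) is
positive iff child i nominated child j, and every non-zero row is scaled to
sum to one, so Wy is the average outcome of each child's nominated friends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FriendshipNetwork",
    "WeightMatrix",
    "MatchReport",
    "RemovalReport",
    "match_nominations",
    "filter_same_sex",
    "prune_isolates",
    "build_weight_matrix",
]

UNMATCHED = "<unmatched>"


@dataclass
class FriendshipNetwork:
    """Directed graph of nominations; nodes carry ``sex`` and ``school``.

    ``stratum`` is the sex label once the network has been restricted to
    same-sex ties, else ``None``.
    """

    graph: nx.DiGraph
    stratum: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class MatchReport:
    n_nominated: int
    n_matched: int

    @property
    def match_rate(self) -> float:
        return self.n_matched / self.n_nominated if self.n_nominated else float("nan")


@dataclass
class RemovalReport:
    removed: list = field(default_factory=list)
    total_before: int = 0

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.total_before if self.total_before else 0.0


class WeightMatrix:
    """Square friendship weight matrix over an explicit node order.

    Nodes are ordered by (school, id) so the matrix is block-diagonal by
    school.  The diagonal is zero; when ``standardised`` every row sums to
    exactly 1 or exactly 0 (a zero row is a child whose nominations all fell
    outside the stratum).
    """

    def __init__(
        self,
        w: np.ndarray,
        ids: Sequence,
        schools: Sequence,
        standardised: bool = False,
    ):
        w = np.asarray(w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if w.shape[0] != len(ids) or len(ids) != len(schools):
            raise ValueError("ids/schools must match matrix dimension")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-nomination)")
        self.w = w
        self.ids = list(ids)
        self.schools = np.asarray(schools)
        self.standardised = bool(standardised)
        self._eigenvalues: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.w.sum(axis=1)

    def standardise(self) -> "WeightMatrix":
        """Divide each non-zero row by its sum ("row standardisation")."""
        s = self.row_sums()
        out = self.w.copy()
        nz = s > 0
        out[nz] = out[nz] / s[nz, None]
        return WeightMatrix(out, self.ids, self.schools, standardised=True)

    def blocks(self) -> Iterator[tuple[object, np.ndarray]]:
        """Yield (school, index array) per school block, in node order."""
        for school in pd.unique(self.schools):
            yield school, np.flatnonzero(self.schools == school)

    def eigenvalues(self) -> np.ndarray:
        """All eigenvalues of W (complex for directed W).

        Computed per school block and concatenated — exact because W is
        block-diagonal under the school ordering — and cached.
        """
        if self._eigenvalues is None:
            if self.is_block_diagonal():
                vals = [np.linalg.eigvals(self.w[np.ix_(idx, idx)]) for _, idx in self.blocks()]
                self._eigenvalues = np.concatenate(vals) if vals else np.array([], dtype=complex)
            else:  # custom node order may interleave schools
                self._eigenvalues = np.linalg.eigvals(self.w)
        return self._eigenvalues

    def is_block_diagonal(self) -> bool:
        """True when no entry links two distinct schools."""
        same = self.schools[:, None] == self.schools[None, :]
        return not np.any(self.w[~same] != 0)

    def feasible_interval(self, cap: float = 0.999) -> tuple[float, float]:
        """Interval of the network-dependence parameter rho for which
        I - rho*W is guaranteed non-singular along the real eigenvalues,
        intersected with (-cap, cap)."""
        lam = self.eigenvalues()
        real = lam[np.abs(lam.imag) < 1e-10].real
        lo, hi = -cap, cap
        pos = real[real > 1e-12]
        neg = real[real < -1e-12]
        if pos.size:
            hi = min(hi, 1.0 / pos.max())
        if neg.size:
            lo = max(lo, 1.0 / neg.min())
        return lo, hi

    def subset(self, index: np.ndarray) -> "WeightMatrix":
        return WeightMatrix(
            self.w[np.ix_(index, index)],
            [self.ids[i] for i in index],
            self.schools[index],
            standardised=False,
        )

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet representation (row id, col id, weight)."""
        r, c = np.nonzero(self.w)
        return pd.DataFrame(
            {
                "source": [self.ids[i] for i in r],
                "target": [self.ids[j] for j in c],
                "weight": self.w[r, c],
            }
        )


def _network_from_edges(roster: pd.DataFrame, edges: list[tuple], stratum=None) -> FriendshipNetwork:
    g = nx.DiGraph()
    for row in roster.itertuples():
        g.add_node(row.child_id, sex=row.sex, school=row.school_id)
    g.add_edges_from(edges)
    return FriendshipNetwork(g, stratum=stratum)


def match_nominations(
    nominations: pd.DataFrame, roster: pd.DataFrame
) -> tuple[FriendshipNetwork, MatchReport]:
    """Match nominated friends against the enrolled roster.

    Only nominations whose nominee is an enrolled child of the same school
    become edges; out-of-study or out-of-school nominees are dropped and
    counted.  Nominations must arrive resolved to ids (or the unmatched
    label); name linkage is out of scope.

    Raises
    ------
    ValueError
        If any nominator is not on the roster.
    """
    if roster["child_id"].duplicated().any():
        raise ValueError("roster child_id values must be unique")
    info = roster.set_index("child_id")[["school_id", "sex"]]
    unknown = sorted(set(nominations["nominator_id"]) - set(info.index))
    if unknown:
        raise ValueError(f"nominators absent from roster: {unknown}")

    edges = []
    n_nominated = len(nominations)
    for row in nominations.itertuples():
        nominee = row.nominee_id
        if nominee == UNMATCHED or nominee not in info.index:
            continue
        if info.at[nominee, "school_id"] != info.at[row.nominator_id, "school_id"]:
            continue
        if nominee == row.nominator_id:
            continue
        edges.append((row.nominator_id, nominee))
    net = _network_from_edges(roster, edges)
    return net, MatchReport(n_nominated=n_nominated, n_matched=len(edges))


def filter_same_sex(
    network: FriendshipNetwork,
) -> tuple[dict[str, FriendshipNetwork], RemovalReport]:
    """Split into per-sex networks, removing opposite-sex ties.

    Returns one network per sex (nodes of that sex, same-sex edges only) and
    a report of how many directed ties were removed.
    """
    g = network.graph
    sexes = nx.get_node_attributes(g, "sex")
    missing = [n for n in g.nodes if sexes.get(n) is None]
    if missing:
        raise ValueError(f"nodes with unknown sex: {missing}")

    removed = [(u, v) for u, v in g.edges if sexes[u] != sexes[v]]
    report = RemovalReport(removed=removed, total_before=g.number_of_edges())
    out: dict[str, FriendshipNetwork] = {}
    for sex in sorted(set(sexes.values())):
        sub = g.subgraph([n for n in g.nodes if sexes[n] == sex]).copy()
        out[sex] = FriendshipNetwork(sub, stratum=sex)
    return out, report


def prune_isolates(network: FriendshipNetwork) -> tuple[FriendshipNetwork, RemovalReport]:
    """Remove children with no in-study friendship tie at all.

    A node is removed when it has zero in-degree and zero out-degree;
    removal is iterated to a fixpoint.  Returns the pruned network and the
    list of removed children.
    """
    g = network.graph.copy()
    total = g.number_of_nodes()
    removed: list = []
    while True:
        isolates = [n for n in g.nodes if g.in_degree(n) == 0 and g.out_degree(n) == 0]
        if not isolates:
            break
        removed.extend(isolates)
        g.remove_nodes_from(isolates)
    if g.number_of_nodes() == 0:
        raise ValueError("network empty after isolate pruning")
    return FriendshipNetwork(g, stratum=network.stratum), RemovalReport(
        removed=removed, total_before=total
    )


def build_weight_matrix(
    network: FriendshipNetwork,
    standardise: bool = True,
    symmetrise: bool = False,
    node_order: Sequence | None = None,
) -> WeightMatrix:
    """Binary contiguity matrix of nominations, optionally row-standardised.

    Direction is preserved: a nomination i -> j sets entry (i, j) = 1, and a
    mutual nomination yields two entries.  ``symmetrise`` instead treats any
    tie as mutual.  Nodes are ordered by (school, id) unless an explicit
    order is given, so the matrix is block-diagonal by school.
    """
    g = network.graph
    if node_order is None:
        node_order = sorted(g.nodes, key=lambda n: (str(g.nodes[n]["school"]), str(n)))
    else:
        node_order = list(node_order)
        if set(node_order) != set(g.nodes):
            raise ValueError("node_order must be a permutation of the network's nodes")
    pos = {n: i for i, n in enumerate(node_order)}
    n = len(node_order)
    w = np.zeros((n, n))
    for u, v in g.edges:
        w[pos[u], pos[v]] = 1.0
        if symmetrise:
            w[pos[v], pos[u]] = 1.0
    schools = [g.nodes[nd]["school"] for nd in node_order]
    wm = WeightMatrix(w, node_order, schools, standardised=False)
    return wm.standardise() if standardise else wm
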