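"""Node tables, interaction events, valued networks and the spatial covariate.

The data model mirrors how field data on individually tagged insects is
recorded: a table of individuals (id, sex, adult emergence location, year)
and a log of dyadic interaction events (matings and fights).  Aggregating
the event log yields a weighted, undirected network whose edge weight is
the number of interactions between a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEXES = ("female", "male")
KINDS = ("mating", "fighting")


class NetworkDataError(ValueError):
    """Raised when input data violates the data-model invariants."""


# ---------------------------------------------------------------------------
# Node table
# ---------------------------------------------------------------------------

class NodeTable:
    """Individuals with sex, emergence coordinates (metres) and year label.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``id, sex, x, y, year``.  Row order is preserved and defines
        the node indexing of every matrix built on top of the table.
    """

    COLUMNS = ("id", "sex", "x", "y", "year")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise NetworkDataError(f"node table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["id"] = df["id"].astype(str)
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise NetworkDataError(f"duplicate node id(s): {sorted(set(dup))}")
        bad_sex = df.loc[~df["sex"].isin(SEXES)]
        if len(bad_sex):
            row = bad_sex.index[0]
            raise NetworkDataError(
                f"unknown sex token {bad_sex['sex'].iloc[0]!r} at row {row}"
            )
        for col in ("x", "y"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(vals.index[vals.isna()][0])
                raise NetworkDataError(f"non-numeric coordinate {col!r} at row {row}")
            if not np.isfinite(vals).all():
                raise NetworkDataError(f"non-finite coordinate in column {col!r}")
            df[col] = vals.astype(float)
        df["year"] = df["year"].astype(int)
        self._df = df
        self._index = {i: k for k, i in enumerate(df["id"])}

    # -- accessors ----------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def ids(self) -> list[str]:
        return list(self._df["id"])

    @property
    def sex(self) -> np.ndarray:
        return self._df["sex"].to_numpy()

    @property
    def male(self) -> np.ndarray:
        """0/1 indicator of males, aligned to row order (females are the
        reference level throughout)."""
        return (self._df["sex"].to_numpy() == "male").astype(np.int8)

    @property
    def coords(self) -> np.ndarray:
        return self._df[["x", "y"]].to_numpy(float)

    @property
    def years(self) -> np.ndarray:
        return self._df["year"].to_numpy()

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[str(node_id)]
        except KeyError:
            raise NetworkDataError(f"unknown node id {node_id!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, NodeTable) or len(self) != len(other):
            return False
        a, b = self._df, other._df
        # coordinates compared to within float round-trip noise
        return (
            a["id"].equals(b["id"])
            and a["sex"].equals(b["sex"])
            and a["year"].equals(b["year"])
            and np.allclose(self.coords, other.coords, rtol=1e-9, atol=1e-12)
        )

    def __repr__(self) -> str:
        yrs = sorted(set(self._df["year"]))
        return f"NodeTable(n={len(self)}, years={yrs})"


@dataclass(frozen=True)
class InteractionEvent:
    """One observed dyadic interaction bout count between two individuals."""

    id_a: str
    id_b: str
    kind: str  # "mating" or "fighting"
    count: int = 1

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise NetworkDataError(f"self-interaction for id {self.id_a!r}")
        if self.kind not in KINDS:
            raise NetworkDataError(f"unknown interaction kind {self.kind!r}")
        if int(self.count) < 1:
            raise NetworkDataError(f"count must be >= 1, got {self.count}")


# ---------------------------------------------------------------------------
# Valued network
# ---------------------------------------------------------------------------

def _check_weight_matrix(w: np.ndarray, n: int, name: str) -> np.ndarray:
    w = np.asarray(w)
    if w.shape != (n, n):
        raise NetworkDataError(f"{name} matrix shape {w.shape} != ({n}, {n})")
    if not np.issubdtype(w.dtype, np.integer):
        if not np.allclose(w, np.round(w)):
            raise NetworkDataError(f"{name} weights must be integers")
        w = np.round(w).astype(np.int64)
    else:
        w = w.astype(np.int64)
    if (w < 0).any():
        raise NetworkDataError(f"negative weight in {name} matrix")
    if not np.array_equal(w, w.T):
        raise NetworkDataError(f"{name} matrix is not symmetric")
    if np.diagonal(w).any():
        raise NetworkDataError(f"{name} matrix has nonzero diagonal")
    return w


@dataclass
class ValuedNetwork:
    """Symmetric integer-weighted network over a :class:`NodeTable`.

    ``weights[i, j]`` is the total number of interactions between nodes i
    and j; the optional per-kind matrices split it into matings and fights.
    """

    nodes: NodeTable
    weights: np.ndarray
    mating: np.ndarray | None = None
    fighting: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.nodes)
        self.weights = _check_weight_matrix(self.weights, n, "weight")
        if (self.mating is None) != (self.fighting is None):
            raise NetworkDataError("per-kind matrices must be given together")
        if self.mating is not None:
            self.mating = _check_weight_matrix(self.mating, n, "mating")
            self.fighting = _check_weight_matrix(self.fighting, n, "fighting")
            if not np.array_equal(self.mating + self.fighting, self.weights):
                raise NetworkDataError("per-kind matrices do not sum to weights")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum() // 2)

    @property
    def n_edges(self) -> int:
        return int((self.weights > 0).sum() // 2)

    def binary(self) -> np.ndarray:
        """0/1 adjacency of the presence/absence projection."""
        return (self.weights > 0).astype(np.int8)

    def copy(self) -> "ValuedNetwork":
        return ValuedNetwork(
            self.nodes,
            self.weights.copy(),
            None if self.mating is None else self.mating.copy(),
            None if self.fighting is None else self.fighting.copy(),
        )

    def __repr__(self) -> str:
        return (
            f"ValuedNetwork(n={self.n}, edges={self.n_edges}, "
            f"total_weight={self.total_weight})"
        )


@dataclass(frozen=True)
class ClosenessMatrix:
    """Dyadic spatial covariate c_ij = 1 / max(d_ij, epsilon), in 1/metres.

    ``epsilon`` floors the distance so that coincident emergence burrows
    give a finite covariate.
    """

    values: np.ndarray
    epsilon: float = 0.1

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise NetworkDataError("closeness matrix must be square")
        if not np.allclose(v, v.T):
            raise NetworkDataError("closeness matrix must be symmetric")
        if not np.isfinite(v).all():
            raise NetworkDataError("closeness matrix must be finite")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if v.shape[0] > 1 and (off <= 0).any():
            raise NetworkDataError("off-diagonal closeness must be positive")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def aggregate_events(
    events: Iterable[InteractionEvent], nodes: NodeTable
) -> ValuedNetwork:
    """Sum an interaction-event log into a valued network.

    An edge exists between two individuals if they ever mated or fought;
    its weight is the total number of interactions between them.  Per-kind
    mating/fighting matrices are retained.
    """
    n = len(nodes)
    mating = np.zeros((n, n), np.int64)
    fighting = np.zeros((n, n), np.int64)
    for ev in events:
        i, j = nodes.index_of(ev.id_a), nodes.index_of(ev.id_b)
        target = mating if ev.kind == "mating" else fighting
        target[i, j] += int(ev.count)
        target[j, i] += int(ev.count)
    return ValuedNetwork(nodes, mating + fighting, mating, fighting)


def closeness_matrix(nodes: NodeTable, epsilon: float = 0.1) -> ClosenessMatrix:
    """Inverse-distance covariate between adult emergence coordinates."""
    if epsilon <= 0:
        raise NetworkDataError("epsilon must be positive")
    xy = nodes.coords
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    c = 1.0 / np.maximum(d, epsilon)
    np.fill_diagonal(c, 0.0)
    return ClosenessMatrix(c, epsilon)


def fight_fraction(net: ValuedNetwork) -> float:
    """Percentage of all interactions that are fights."""
    if net.mating is None:
        raise NetworkDataError("per-kind matrices required for fight_fraction")
    total = net.weights.sum()
    if total == 0:
        raise NetworkDataError("fight fraction undefined for zero total weight")
    return 100.0 * float(net.fighting.sum()) / float(total)


# ---------------------------------------------------------------------------
# I/O — plain CSV dialects
# ---------------------------------------------------------------------------

def read_nodes(path) -> NodeTable:
    """Read a node CSV with header ``id,sex,x,y,year``."""
    df = pd.read_csv(path, dtype={"id": str})
    return NodeTable(df)


def write_nodes(nodes: NodeTable, path) -> None:
    nodes.df.to_csv(path, index=False)


def read_events(path) -> list[InteractionEvent]:
    """Read an event CSV with header ``id_a,id_b,kind,count``."""
    df = pd.read_csv(path, dtype={"id_a": str, "id_b": str})
    return [
        InteractionEvent(r.id_a, r.id_b, r.kind, int(r.count))
        for r in df.itertuples(index=False)
    ]


def write_events(events: Sequence[InteractionEvent], path) -> None:
    pd.DataFrame(
        [(e.id_a, e.id_b, e.kind, e.count) for e in events],
        columns=["id_a", "id_b", "kind", "count"],
    ).to_csv(path, index=False)


def write_network(net: ValuedNetwork, path) -> None:
    """Write the undirected edge list, one row per unordered pair.

    Pairs are stored once with id_a < id_b lexicographically; per-kind
    columns are included when available.
    """
    ids = net.nodes.ids
    rows = []
    per_kind = net.mating is not None
    iu, ju = np.nonzero(np.triu(net.weights, 1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        a, b = sorted((ids[i], ids[j]))
        row = [a, b, int(net.weights[i, j])]
        if per_kind:
            row += [int(net.mating[i, j]), int(net.fighting[i, j])]
        rows.append(row)
    cols = ["id_a", "id_b", "weight"] + (["mating", "fighting"] if per_kind else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_network(path, nodes: NodeTable) -> ValuedNetwork:
    """Read an edge-list CSV back onto a node table.

    Either orientation of a pair is accepted; the matrix is symmetrised.
    """
    df = pd.read_csv(path, dtype={"id_a": str, "id_b": str})
    n = len(nodes)
    per_kind = "mating" in df.columns
    w = np.zeros((n, n), np.int64)
    m = np.zeros((n, n), np.int64)
    f = np.zeros((n, n), np.int64)
    for r in df.itertuples(index=False):
        i, j = nodes.index_of(r.id_a), nodes.index_of(r.id_b)
        w[i, j] = w[j, i] = int(r.weight)
        if per_kind:
            m[i, j] = m[j, i] = int(r.mating)
            f[i, j] = f[j, i] = int(r.fighting)
    if per_kind:
        return ValuedNetwork(nodes, w, m, f)
    return ValuedNetwork(nodes, w)


def to_graphml(net: ValuedNetwork, path) -> None:
    """Export to GraphML for interoperability with other network tools."""
    import networkx as nx

    g = nx.Graph()
    df = net.nodes.df
    for _, row in df.iterrows():
        g.add_node(row["id"], sex=row["sex"], x=row["x"], y=row["y"],
                   year=int(row["year"]))
    ids = net.nodes.ids
    iu, ju = np.nonzero(np.triu(net.weights, 1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        g.add_edge(ids[i], ids[j], weight=int(net.weights[i, j]))
    nx.write_graphml(g, path)
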