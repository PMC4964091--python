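"""Network metrics scored on the binary projection of a valued network.

All three metrics depend only on edge presence/absence (an edge is any
dyad with at least one interaction): mean geodesic path length over
reachable pairs, the degree correlation (assortativity) over edge
endpoints, and the global clustering coefficient (transitivity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .netdata import ValuedNetwork


class UndefinedMetricError(ValueError):
    """The metric is undefined for this network (e.g. no finite pair)."""


def mean_path_length(net: ValuedNetwork) -> float:
    """Mean number of edges on shortest routes between reachable pairs.

    Pairs in different components (infinite distance) are excluded from
    the average; an empty network has no finite pair and is signalled.
    """
    if net.n < 2:
        raise UndefinedMetricError("need at least 2 nodes")
    a = net.binary()
    d = shortest_path(csr_matrix(a), method="D", unweighted=True)
    iu = np.triu_indices(net.n, 1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise UndefinedMetricError("no connected pair; path length undefined")
    return float(finite.mean())


def degree_correlation(net: ValuedNetwork) -> float:
    """Pearson correlation of the degrees at either end of each edge.

    Degree is the number of unique connections (unweighted).  Each edge
    contributes both orientations, making the statistic symmetric.
    """
    a = net.binary()
    deg = a.sum(axis=1)
    iu, ju = np.nonzero(np.triu(a, 1))
    if iu.size < 2:
        raise UndefinedMetricError("need at least 2 edges")
    x = np.concatenate([deg[iu], deg[ju]]).astype(float)
    y = np.concatenate([deg[ju], deg[iu]]).astype(float)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedMetricError("constant endpoint degrees")
    return float(np.corrcoef(x, y)[0, 1])


def clustering_coefficient(net: ValuedNetwork) -> float:
    """Global transitivity: 3 x closed triads / connected triples.

    A connected triple is two crickets both connected to a third; a closed
    triad connects all three.  The value lies in [0, 1].
    """
    a = net.binary().astype(np.int64)
    deg = a.sum(axis=1)
    triples = int((deg * (deg - 1) // 2).sum())
    if triples == 0:
        raise UndefinedMetricError("no connected triple")
    closed = int(np.trace(a @ a @ a)) // 6
    return 3.0 * closed / triples


METRIC_FUNCTIONS = {
    "path_length": mean_path_length,
    "degree_correlation": degree_correlation,
    "clustering": clustering_coefficient,
}


def compute_metrics(net: ValuedNetwork,
                    metrics: tuple[str, ...] = tuple(METRIC_FUNCTIONS)) -> dict:
    """Evaluate named metrics; undefined ones are reported as None."""
    out = {}
    for name in metrics:
        try:
            out[name] = METRIC_FUNCTIONS[name](net)
        except UndefinedMetricError:
            out[name] = None
    return out


def metrics_table(nets: dict, metrics: tuple[str, ...] = tuple(METRIC_FUNCTIONS)
                  ) -> pd.DataFrame:
    """Long-format metric table (network id, metric, value) for export."""
    rows = []
    for net_id, net in nets.items():
        vals = compute_metrics(net, metrics)
        for name, v in vals.items():
            rows.append((net_id, name, v))
    return pd.DataFrame(rows, columns=["network", "metric", "value"])
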