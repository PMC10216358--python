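"""Natural visibility graphs of short time series.

Node ``i`` of the graph is sample ``i`` of the series; nodes ``m < n`` are
joined iff every strictly intermediate sample lies strictly below the chord
from ``(m, x_m)`` to ``(n, x_n)``.  A sample exactly on the chord blocks
visibility (strict inequality), so a collinear run maps to a bare path.
Adjacent samples have no intermediates and are always joined, which makes
every visibility graph connected.

The construction is invariant under positive affine transforms of the
series and equivariant under time reversal.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

__all__ = ["build_vg", "write_edgelist"]


def build_vg(series: np.ndarray) -> nx.Graph:
    """Natural visibility graph of ``series`` (nodes ``0..n-1``).

    Uses the running-maximum-slope formulation of the chord test: ``n`` is
    visible from ``m`` iff the slope from ``m`` to ``n`` strictly exceeds
    the slope from ``m`` to every intermediate sample.  O(n^2).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite series values")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for m in range(n - 1):
        g.add_edge(m, m + 1)
        max_slope = (x[m + 1] - x[m])  # slope to the nearest sample
        for k in range(m + 2, n):
            slope = (x[k] - x[m]) / (k - m)
            if slope > max_slope:
                g.add_edge(m, k)
            max_slope = max(max_slope, slope)
    return g


def write_edgelist(g: nx.Graph, path) -> None:
    """Two-column text export (0-based node ids, one edge per line)."""
    with open(path, "w") as fh:
        for u, v in sorted((min(e), max(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\n")
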