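"""Global connection strength (GCS) and global nonequivalence (GN) scores.

GCS quantifies the functional interaction between two metabolites from a
global network perspective, accounting for both the number and the length
of walks connecting them: walks of length L contribute the product of
their edge weights, attenuated by ``beta**(L-1)``, up to a maximum walk
length ``lmax``. In matrix form

    GCS = sum_{L=1..lmax} beta**(L-1) * W**L

for the weighted adjacency W, with the diagonal zeroed by convention.
The GN score of a metabolite is the mean of its GCS values to all other
network metabolites (unreachable pairs contribute zero). High GN marks a
well-connected metabolite whose dysfunction is easily compensated for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network_io import MetaboliteNetwork

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.5
DEFAULT_LMAX = 6

# above this node count the walk sum is accumulated with sparse matrices
_SPARSE_THRESHOLD = 5000


@dataclass
class GCSMatrix:
    """Pairwise global connection strengths over a fixed node order.

    ``values`` is symmetric, nonnegative, with zero diagonal; entry (i, j)
    is zero whenever no walk of length <= lmax connects i and j.
    """

    node_order: list[str]
    values: np.ndarray
    beta: float
    lmax: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {n: i for i, n in enumerate(self.node_order)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def index_of(self, node: str) -> int:
        return self._index[node]


def _adjacency(net: MetaboliteNetwork, nodes: list[str], sparse: bool):
    idx = {n: i for i, n in enumerate(nodes)}
    m = len(nodes)
    if sparse:
        rows, cols, vals = [], [], []
        for u, v, w in net.edges():
            i, j = idx[u], idx[v]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    a = np.zeros((m, m))
    for u, v, w in net.edges():
        i, j = idx[u], idx[v]
        a[i, j] = a[j, i] = w
    return a


def compute_gcs(
    net: MetaboliteNetwork, beta: float = DEFAULT_BETA, lmax: int = DEFAULT_LMAX
) -> GCSMatrix:
    """Length-attenuated walk-sum connection strengths via matrix powers."""
    if lmax < 1:
        raise ValueError(f"lmax must be >= 1, got {lmax}")
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    nodes = net.node_list()
    if net.n_edges == 0:
        logger.warning("network has no edges: GCS is identically zero")
        return GCSMatrix(nodes, np.zeros((len(nodes), len(nodes))), beta, lmax)
    use_sparse = net.n_nodes > _SPARSE_THRESHOLD
    w = _adjacency(net, nodes, use_sparse)
    power = w.copy()
    total = w.copy()
    for ell in range(2, lmax + 1):
        power = power @ w
        total = total + beta ** (ell - 1) * power
    if use_sparse:
        total = np.asarray(total.todense())
    total = np.asarray(total, dtype=float)
    np.fill_diagonal(total, 0.0)
    total = (total + total.T) / 2.0  # kill symmetric round-off drift
    return GCSMatrix(nodes, total, beta, lmax)


def brute_force_gcs(
    net: MetaboliteNetwork, beta: float = DEFAULT_BETA, lmax: int = DEFAULT_LMAX
) -> GCSMatrix:
    """Exact walk enumeration oracle for tiny graphs (tests only).

    Recursively enumerates every walk of length <= lmax between each node
    pair and sums beta**(L-1) times the product of edge weights. Refuses
    instances with more than 8 nodes or lmax > 6.
    """
    if net.n_nodes > 8 or lmax > 6:
        raise ValueError("brute_force_gcs is restricted to <= 8 nodes and lmax <= 6")
    if lmax < 1 or beta <= 0:
        raise ValueError("invalid beta/lmax")
    nodes = net.node_list()
    idx = {n: i for i, n in enumerate(nodes)}
    m = len(nodes)
    g = net.graph
    vals = np.zeros((m, m))

    def walk(current: str, target: str, length: int, prod: float):
        total = 0.0
        for nb in g[current]:
            p = prod * g[current][nb]["weight"]
            if nb == target:
                total += beta ** (length) * p  # walk length = length + 1
            if length + 1 < lmax:
                total += walk(nb, target, length + 1, p)
        return total

    for a in nodes:
        for b in nodes:
            if a < b:
                v = walk(a, b, 0, 1.0)
                vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = v
    return GCSMatrix(nodes, vals, beta, lmax)


def compute_gn(gcs: GCSMatrix) -> dict[str, float]:
    """GN score per metabolite: mean GCS to the other M-1 network metabolites."""
    m = len(gcs.node_order)
    if m < 2:
        raise ValueError("GN scores need at least 2 network nodes")
    sums = gcs.values.sum(axis=1)  # diagonal is zero
    return {n: float(sums[i] / (m - 1)) for i, n in enumerate(gcs.node_order)}


def write_gn(gn: dict[str, float], path) -> None:
    """GN table as 2-column TSV (metabolite_id, gn_score, 10 significant digits)."""
    with open(path, "w") as fh:
        fh.write("metabolite_id\tgn_score\n")
        for node in sorted(gn, key=int):
            fh.write(f"{node}\t{gn[node]:.10g}\n")


def write_gcs(gcs: GCSMatrix, path) -> None:
    """GCS as a matrix TSV with a header row/column of metabolite IDs."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(gcs.node_order) + "\n")
        for i, node in enumerate(gcs.node_order):
            row = "\t".join(f"{v:.10g}" for v in gcs.values[i])
            fh.write(f"{node}\t{row}\n")
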