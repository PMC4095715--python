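"""Parsing of STITCH-dialect chemical link files and the weighted metabolite network.

The global human metabolite network is built from chemical-chemical
association records (two compound identifiers plus an integer combined
score on the 0-1000 scale), restricted to a background of human
metabolites, with the combined score / 1000 used as the edge weight.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

_STITCH_ID = re.compile(r"^(?:CIDs|CIDm|CID)?0*(\d+)$", re.IGNORECASE)


class NetworkIOError(ValueError):
    """Raised for malformed link files, backgrounds, or networks."""


def canonical_id(raw: str) -> str:
    """Canonicalize a compound identifier to a bare PubChem CID digit string.

    Accepts ``CIDs...`` / ``CIDm...`` prefixed STITCH forms and bare digits;
    strips the prefix and leading zeros. Stereospecific and merged forms
    collapse to the same canonical CID. Idempotent.
    """
    raw = raw.strip()
    m = _STITCH_ID.match(raw)
    if not m:
        raise NetworkIOError(f"unrecognized compound identifier: {raw!r}")
    digits = m.group(1).lstrip("0")
    if not digits:
        raise NetworkIOError(f"identifier has no nonzero digits: {raw!r}")
    return digits


@dataclass(frozen=True)
class EdgeRecord:
    """One chemical-chemical association: canonical endpoints and combined score."""

    a: str
    b: str
    score: int

    def __post_init__(self):
        if self.a == self.b:
            raise NetworkIOError(f"self link: {self.a}")
        if not (0 < self.score <= 1000):
            raise NetworkIOError(f"score {self.score} outside (0, 1000]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


class MetaboliteNetwork:
    """Simple undirected graph over canonical metabolite IDs, weights in (0, 1].

    Thin wrapper around a :class:`networkx.Graph` that enforces the
    invariants (no self loops, weights in (0, 1]) at construction.
    """

    def __init__(self, graph: nx.Graph):
        for u, v, w in graph.edges(data="weight"):
            if u == v:
                raise NetworkIOError(f"self loop at {u}")
            if w is None or not (0.0 < w <= 1.0):
                raise NetworkIOError(f"edge ({u},{v}) weight {w!r} outside (0, 1]")
        self._g = graph

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def node_list(self) -> list[str]:
        """Nodes in a deterministic (sorted-numeric) order."""
        return sorted(self._g.nodes, key=int)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def weight(self, a: str, b: str) -> float:
        return self._g[a][b]["weight"]

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for u, v, w in self._g.edges(data="weight"):
            yield u, v, w

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetaboliteNetwork):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        mine = {(min(u, v), max(u, v)): round(w, 9) for u, v, w in self.edges()}
        theirs = {(min(u, v), max(u, v)): round(w, 9) for u, v, w in other.edges()}
        return mine == theirs


def read_stitch_links(path, min_score: int = 0) -> list[EdgeRecord]:
    """Read a STITCH-dialect chemical-chemical link file.

    Expects whitespace- or tab-separated lines with at least three columns
    (chemical A, chemical B, integer combined score); one header line is
    auto-detected and skipped. Records with score < ``min_score`` are
    dropped, self links are dropped with a logged count, and for duplicate
    unordered pairs the maximum score is kept (first-seen order preserved).
    """
    records: dict[tuple[str, str], EdgeRecord] = {}
    n_self = 0
    n_low = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 3:
                raise NetworkIOError(f"{path}:{lineno}: expected >= 3 columns")
            a_raw, b_raw, score_raw = fields[0], fields[1], fields[2]
            try:
                score = int(score_raw)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise NetworkIOError(
                    f"{path}:{lineno}: non-integer score {score_raw!r}"
                ) from None
            if not (0 < score <= 1000):
                raise NetworkIOError(f"{path}:{lineno}: score {score} outside (0, 1000]")
            a, b = canonical_id(a_raw), canonical_id(b_raw)
            if a == b:
                n_self += 1
                continue
            if score < min_score:
                n_low += 1
                continue
            rec = EdgeRecord(a, b, score)
            prev = records.get(rec.pair)
            if prev is None or score > prev.score:
                # keep insertion order of first occurrence
                if prev is None:
                    records[rec.pair] = rec
                else:
                    records[rec.pair] = EdgeRecord(prev.a, prev.b, score)
    if n_self:
        logger.info("dropped %d self links", n_self)
    if n_low:
        logger.info("dropped %d records below min_score=%d", n_low, min_score)
    if not records:
        logger.warning("no edge records retained from %s", path)
    return list(records.values())


def read_background(path) -> set[str]:
    """Read a one-CID-per-line background metabolite list, canonicalized."""
    members: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                members.add(canonical_id(line))
    if not members:
        raise NetworkIOError(f"empty background file: {path}")
    return members


def restrict_to_background(
    edges: Sequence[EdgeRecord], background: set[str]
) -> list[EdgeRecord]:
    """Keep exactly the records whose both endpoints are background metabolites."""
    if not background:
        raise NetworkIOError("empty background set")
    kept = [e for e in edges if e.a in background and e.b in background]
    logger.info("background restriction kept %d / %d edges", len(kept), len(edges))
    return kept


def build_network(edges: Sequence[EdgeRecord]) -> MetaboliteNetwork:
    """Assemble the edge-weighted network; weight = combined score / 1000."""
    if not edges:
        raise NetworkIOError("no edges: cannot build a network")
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.a, e.b, weight=e.score / 1000.0)
    net = MetaboliteNetwork(g)
    logger.info("built network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    return net


def write_network(net: MetaboliteNetwork, path) -> None:
    """Serialize as 3-column TSV (node_a, node_b, weight to 6 decimals)."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v in sorted(
            ((min(u, v, key=int), max(u, v, key=int)) for u, v, _ in net.edges()),
            key=lambda p: (int(p[0]), int(p[1])),
        ):
            fh.write(f"{u}\t{v}\t{net.weight(u, v):.6f}\n")


def read_network(path) -> MetaboliteNetwork:
    """Read a network TSV written by :func:`write_network` (lossless round trip)."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise NetworkIOError(f"{path}:{lineno}: expected 3 columns")
            if lineno == 1 and fields[2] == "weight":
                continue
            try:
                w = float(fields[2])
            except ValueError:
                raise NetworkIOError(
                    f"{path}:{lineno}: malformed weight {fields[2]!r}"
                ) from None
            g.add_edge(canonical_id(fields[0]), canonical_id(fields[1]), weight=w)
    if g.number_of_edges() == 0:
        raise NetworkIOError(f"no edges in network file {path}")
    return MetaboliteNetwork(g)
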