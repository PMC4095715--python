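"""Pathway collections: GMT reading and background annotation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .network_io import canonical_id

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 3


@dataclass
class Pathway:
    id: str
    name: str
    members: set[str]
    source: str = ""
    m1: int | None = None  # background-annotated size, set by annotate()

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.id} has no members")


@dataclass
class PathwayCollection:
    """Ordered sequence of uniquely-identified pathways.

    ``K`` (the number of retained pathways) is the collection length; it
    is the denominator count in the relative-weight calculation.
    """

    pathways: list[Pathway]
    min_size: int = 0
    _by_id: dict[str, Pathway] = field(init=False, repr=False)

    def __post_init__(self):
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dup}")
        self._by_id = {p.id: p for p in self.pathways}

    @property
    def K(self) -> int:
        return len(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pid: str) -> Pathway:
        return self._by_id[pid]

    def member_universe(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.members
        return out


def read_gmt(path) -> PathwayCollection:
    """Read a GMT file: tab-separated id, description, member CIDs.

    Members are canonicalized and de-duplicated within a line; duplicate
    pathway ids or lines with fewer than 3 fields are errors.
    """
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            pid, desc = fields[0], fields[1]
            members = {canonical_id(m) for m in fields[2:] if m.strip()}
            pathways.append(Pathway(id=pid, name=desc, members=members))
    if not pathways:
        raise ValueError(f"empty GMT file: {path}")
    return PathwayCollection(pathways)


def write_gmt(coll: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for p in coll:
            fh.write(p.id + "\t" + p.name + "\t" + "\t".join(sorted(p.members, key=int)) + "\n")


def annotate(
    coll: PathwayCollection, background: set[str], min_size: int = DEFAULT_MIN_SIZE
) -> PathwayCollection:
    """Intersect memberships with the background and drop small pathways.

    Each pathway's members are replaced by their intersection with the
    background; pathways whose annotated size m1 falls below ``min_size``
    are dropped (logged). Idempotent.
    """
    if not background:
        raise ValueError("empty background set")
    kept: list[Pathway] = []
    for p in coll:
        inter = p.members & background
        if len(inter) < min_size:
            logger.info("dropping pathway %s (annotated size %d < %d)", p.id, len(inter), min_size)
            continue
        kept.append(Pathway(id=p.id, name=p.name, members=inter, source=p.source, m1=len(inter)))
    if not kept:
        raise ValueError("all pathways dropped during background annotation")
    return PathwayCollection(kept, min_size=min_size)
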