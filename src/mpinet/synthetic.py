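"""Seeded synthetic networks, pathways, and biased metabolite selections.

The generator emulates the statistical structure the enrichment model
assumes: a weighted metabolite network in which some metabolites are
globally well connected (high GN) and others pathway-specific (low GN);
pathway memberships drawn preferentially from one connectivity stratum
("common" vs "pathway-specific" pathways); and an interesting-metabolite
selection whose probability increases with normalized GN score — the
detection bias of metabolomic profiling — optionally multiplied inside
planted pathways to create true enrichment signal.

A single integer seed governs every stage through independent numpy
SeedSequence substreams ([seed, stage]), so identical configurations
reproduce identical outputs while stages stay statistically independent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_io import MetaboliteNetwork, write_network
from .connectivity import compute_gcs, compute_gn
from .pathways import Pathway, PathwayCollection, write_gmt

_STAGE_NETWORK, _STAGE_PATHWAYS, _STAGE_INTERESTING = 0, 1, 2


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic benchmark, with study-scale defaults.

    ``specificity_mix`` is the fraction of pathways whose members are
    drawn from the low-GN stratum (pathway-specific pathways);
    ``bias_strength`` is the slope of the selection probability in the
    min-max-normalized GN score; ``enrichment_multiplier`` scales the
    selection probability inside ``planted_pathways``.
    """

    seed: int
    n_nodes: int = 150
    edge_model: str = "scale-free"  # or "erdos-renyi"
    ba_m: int = 2
    er_p: float = 0.04
    score_low: int = 150
    score_high: int = 1000
    n_pathways: int = 20
    size_range: tuple[int, int] = (5, 15)
    specificity_mix: float = 0.5
    stratum_purity: float = 0.8
    base_rate: float = 0.1
    bias_strength: float = 0.6
    planted_pathways: tuple[str, ...] = ()
    enrichment_multiplier: float = 1.0
    gcs_beta: float = 0.5
    gcs_lmax: int = 6

    def __post_init__(self):
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if self.edge_model not in {"scale-free", "erdos-renyi"}:
            raise ValueError(f"unknown edge model {self.edge_model!r}")
        if self.edge_model == "erdos-renyi" and self.er_p <= 0:
            raise ValueError("erdos-renyi requires er_p > 0")
        if not (0 < self.score_low <= self.score_high <= 1000):
            raise ValueError("scores must satisfy 0 < low <= high <= 1000")
        if not (0.0 <= self.specificity_mix <= 1.0):
            raise ValueError("specificity_mix must be in [0, 1]")
        if not (0.0 <= self.stratum_purity <= 1.0):
            raise ValueError("stratum_purity must be in [0, 1]")
        if self.size_range[0] < 1 or self.size_range[0] > self.size_range[1]:
            raise ValueError("invalid size_range")
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def simulate_network(cfg: SimulationConfig) -> MetaboliteNetwork:
    """Connected weighted graph; node ids are the digit strings 1..n_nodes."""
    rng = _rng(cfg, _STAGE_NETWORK)
    n = cfg.n_nodes
    if cfg.edge_model == "scale-free":
        g0 = nx.barabasi_albert_graph(n, cfg.ba_m, seed=int(rng.integers(2**31)))
        edges = list(g0.edges())
    else:
        # random spanning tree guarantees connectivity, ER edges on top
        perm = rng.permutation(n)
        edges = [
            (int(perm[i]), int(perm[int(rng.integers(i))])) for i in range(1, n)
        ]
        extra = rng.random((n, n)) < cfg.er_p
        for i in range(n):
            for j in range(i + 1, n):
                if extra[i, j]:
                    edges.append((i, j))
    g = nx.Graph()
    seen = set()
    for u, v in edges:
        a, b = str(u + 1), str(v + 1)
        key = (min(a, b, key=int), max(a, b, key=int))
        if a == b or key in seen:
            continue
        seen.add(key)
        score = int(rng.integers(cfg.score_low, cfg.score_high + 1))
        g.add_edge(a, b, weight=score / 1000.0)
    for i in range(n):  # isolated nodes cannot occur by construction, keep ids dense
        g.add_node(str(i + 1))
    return MetaboliteNetwork(g)


def _gn_strata(net: MetaboliteNetwork, cfg: SimulationConfig):
    gn = compute_gn(compute_gcs(net, cfg.gcs_beta, cfg.gcs_lmax))
    ordered = sorted(gn, key=lambda n: (gn[n], int(n)))
    half = len(ordered) // 2
    return gn, ordered[:half], ordered[half:]  # low-GN, high-GN strata


def simulate_pathways(net: MetaboliteNetwork, cfg: SimulationConfig) -> PathwayCollection:
    """Pathways drawn from GN strata per the specificity mix.

    The first ``round(specificity_mix * n_pathways)`` pathways are
    pathway-specific (members mostly low-GN); the rest are common
    (mostly high-GN). ``stratum_purity`` is the fraction of members
    drawn from the designated stratum; the remainder comes from the
    whole node set, which creates cross-pathway overlap.
    """
    rng = _rng(cfg, _STAGE_PATHWAYS)
    gn, low, high = _gn_strata(net, cfg)
    all_nodes = sorted(net.nodes, key=int)
    n_specific = round(cfg.specificity_mix * cfg.n_pathways)
    pathways = []
    for k in range(cfg.n_pathways):
        specific = k < n_specific
        pool = low if specific else high
        size = int(rng.integers(cfg.size_range[0], cfg.size_range[1] + 1))
        size = min(size, len(all_nodes))
        n_pool = min(int(round(cfg.stratum_purity * size)), len(pool))
        members = set(rng.choice(pool, size=n_pool, replace=False))
        rest = [x for x in all_nodes if x not in members]
        members |= set(rng.choice(rest, size=size - n_pool, replace=False))
        pathways.append(
            Pathway(
                id=f"pw{k + 1}",
                name=f"synthetic {'specific' if specific else 'common'} pathway {k + 1}",
                members=members,
                source="synthetic",
            )
        )
    return PathwayCollection(pathways)


def simulate_interesting(
    net: MetaboliteNetwork, coll: PathwayCollection, cfg: SimulationConfig
) -> set[str]:
    """Biased selection: P(select) = clamp(base + bias * GN_norm), boosted in planted pathways."""
    rng = _rng(cfg, _STAGE_INTERESTING)
    gn = compute_gn(compute_gcs(net, cfg.gcs_beta, cfg.gcs_lmax))
    vals = np.asarray(list(gn.values()))
    lo, span = vals.min(), max(np.ptp(vals), 1e-12)
    planted_members: set[str] = set()
    for pid in cfg.planted_pathways:
        planted_members |= coll[pid].members
    selected = set()
    for node in sorted(net.nodes, key=int):
        p = cfg.base_rate + cfg.bias_strength * (gn[node] - lo) / span
        if node in planted_members:
            p *= cfg.enrichment_multiplier
        p = min(max(p, 0.0), 1.0)
        if rng.random() < p:
            selected.add(node)
    if not selected:  # degenerate config; keep downstream stages well-posed
        selected = {max(gn, key=lambda n: (gn[n], int(n)))}
    return selected


def planted_decoy_scenario(
    seed: int,
    *,
    n_nodes: int = 120,
    pathway_size: int = 10,
    n_filler: int = 10,
    multiplier: float = 4.0,
):
    """Benchmark scenario: a planted pathway-specific pathway and a matched decoy.

    The planted pathway is drawn purely from the low-GN stratum and its
    members' selection probability is multiplied; after the interesting
    set is drawn, a decoy pathway with identical (m1, g) is assembled
    from high-GN nodes. An unweighted overrepresentation test cannot
    separate the pair; the CGNB-weighted test should favour the planted
    (pathway-specific) one. Returns
    (network, collection, interesting, planted_id, decoy_id).
    """
    cfg = SimulationConfig(
        seed=seed,
        n_nodes=n_nodes,
        n_pathways=n_filler,
        size_range=(pathway_size, pathway_size + 4),
        specificity_mix=0.5,
        planted_pathways=("planted",),
        enrichment_multiplier=multiplier,
    )
    net = simulate_network(cfg)
    rng = _rng(cfg, 3)  # scenario-assembly substream
    gn, low, high = _gn_strata(net, cfg)

    planted = Pathway(
        id="planted",
        name="planted pathway-specific pathway",
        members=set(rng.choice(low, size=pathway_size, replace=False)),
        source="synthetic",
    )
    filler = simulate_pathways(net, cfg)
    coll = PathwayCollection([planted] + list(filler))
    interesting = simulate_interesting(net, coll, cfg)

    g = len(planted.members & interesting)
    high_sorted = sorted(high, key=lambda n: (-gn[n], int(n)))
    candidates_hit = [x for x in high_sorted if x in interesting and x not in planted.members]
    candidates_miss = [x for x in high_sorted if x not in interesting and x not in planted.members]
    if len(candidates_hit) < g or len(candidates_miss) < pathway_size - g:
        raise RuntimeError("cannot assemble a matched decoy; enlarge the network")
    decoy = Pathway(
        id="zz_decoy",
        name="matched common decoy pathway",
        members=set(candidates_hit[:g]) | set(candidates_miss[: pathway_size - g]),
        source="synthetic",
    )
    coll = PathwayCollection(list(coll) + [decoy])
    return net, coll, interesting, "planted", "zz_decoy"


def write_fixture_dir(cfg: SimulationConfig, outdir) -> dict[str, str]:
    """Emit a complete fixture directory in the formats the pipeline reads."""
    os.makedirs(outdir, exist_ok=True)
    net = simulate_network(cfg)
    coll = simulate_pathways(net, cfg)
    interesting = simulate_interesting(net, coll, cfg)
    paths = {
        "network": os.path.join(outdir, "network.tsv"),
        "pathways": os.path.join(outdir, "pathways.gmt"),
        "metabolites": os.path.join(outdir, "interesting.txt"),
        "background": os.path.join(outdir, "background.txt"),
    }
    write_network(net, paths["network"])
    write_gmt(coll, paths["pathways"])
    with open(paths["metabolites"], "w") as fh:
        for m in sorted(interesting, key=int):
            fh.write(m + "\n")
    with open(paths["background"], "w") as fh:
        for m in sorted(net.nodes, key=int):
            fh.write(m + "\n")
    return paths
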