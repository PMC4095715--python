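"""Pathway significance: relative weights, Wallenius test, FDR, diagnostics.

Each pathway receives a relative weight

    W = mean_{j in P}(1 - C_j) / ( (1/K) sum_k mean_{r in P_k}(1 - C_r) )

from the CGNB scores C of its members; the odds weight of pathway members
in the enrichment test is w1 = W**6 (non-members have weight w2 = 1).
Significance is the upper tail of the Wallenius noncentral hypergeometric
distribution: with N background metabolites, m1 of them in the pathway,
n interesting metabolites and g interesting members observed,

    p = 1 - sum_{x=0}^{g-1} C(m1,x) C(m2,n-x)
            * int_0^1 (1 - t^(w1/d_x))^x (1 - t^(w2/d_x))^(n-x) dt,

with m2 = N - m1 and d_x = w1*(m1-x) + w2*(m2-(n-x)). Pathways rich in
high-CGNB (pathway-specific, hard-to-detect) metabolites get W < 1, hence
w1 < 1, which makes an observed overlap more surprising and the pathway
more significant; with w1 = w2 the test reduces to the central
hypergeometric overrepresentation test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .connectivity import GCSMatrix
from .pathways import PathwayCollection

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_EXPONENT = 6
_WEIGHT_FLOOR = 1e-6
_QUAD_RTOL = 1e-10


# ---------------------------------------------------------------------------
# Wallenius noncentral hypergeometric upper tail


def _wallenius_pmf_terms(n: int, m1: int, N: int, w1: float, w2: float) -> np.ndarray:
    """P(X = x) for x = 0..min(n, m1) via the integral representation."""
    m2 = N - m1
    out = np.zeros(min(n, m1) + 1)
    for x in range(len(out)):
        if n - x > m2:
            continue  # impossible configuration, binomial factor is zero
        d = w1 * (m1 - x) + w2 * (m2 - (n - x))
        if d <= 0:
            # only when every item is drawn (n == N); a single atom remains
            out[x] = 1.0 if (x == m1 and n - x == m2) else 0.0
            continue
        e1, e2 = w1 / d, w2 / d

        # substitute t = exp(-v): the raw integrand concentrates its mass
        # in an exponentially thin layer near t = 0 once d is large, which
        # defeats quadrature on [0, 1]; in v the integrand is smooth and
        # decays like exp(-v) with its peak near v = n.
        def integrand(v, x=x, e1=e1, e2=e2):
            return (
                (-np.expm1(-v * e1)) ** x
                * (-np.expm1(-v * e2)) ** (n - x)
                * np.exp(-v)
            )

        val, _ = integrate.quad(
            integrand, 0.0, np.inf, epsabs=1e-300, epsrel=_QUAD_RTOL, limit=400
        )
        logb = (
            math.lgamma(m1 + 1)
            - math.lgamma(x + 1)
            - math.lgamma(m1 - x + 1)
            + math.lgamma(m2 + 1)
            - math.lgamma(n - x + 1)
            - math.lgamma(m2 - (n - x) + 1)
        )
        out[x] = math.exp(logb + math.log(val)) if val > 0 else 0.0
    return out


def wallenius_pvalue(
    g: int, n: int, m1: int, N: int, w1: float, w2: float = 1.0
) -> float:
    """Upper-tail P(X >= g) of the Wallenius noncentral hypergeometric.

    ``n`` interesting metabolites drawn without replacement from ``N``
    background metabolites of which ``m1`` belong to the pathway; pathway
    members carry odds weight ``w1``, the rest ``w2``. Monotone
    nondecreasing in ``w1`` for g >= 1; equal weights recover the central
    hypergeometric tail.
    """
    if w1 <= 0 or w2 <= 0:
        raise ValueError(f"weights must be positive (w1={w1}, w2={w2})")
    if not 0 <= m1 <= N:
        raise ValueError(f"m1={m1} outside [0, N={N}]")
    if not 0 <= n <= N:
        raise ValueError(f"n={n} outside [0, N={N}]")
    if not 0 <= g <= min(n, m1):
        raise ValueError(f"g={g} outside [0, min(n={n}, m1={m1})]")
    if g == 0:
        return 1.0
    if n == N:
        # degenerate: everything is drawn, g = m1 with certainty
        return 1.0
    pmf = _wallenius_pmf_terms(n, m1, N, w1, w2)
    p = 1.0 - float(pmf[:g].sum())
    return min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Relative pathway weights (CGNB -> odds weight)


@dataclass
class EnrichmentContext:
    """Inputs of the weighted enrichment test for one analysis run.

    ``background`` is the metabolite universe (size N), ``interesting``
    the query list restricted to it (size n), ``cgnb`` the per-metabolite
    CGNB scores; background metabolites without a CGNB score contribute
    ``impute_value`` (default: background mean of 1 - C) to pathway
    means. ``collection`` must already be background-annotated.
    """

    background: set[str]
    interesting: set[str]
    cgnb: dict[str, float]
    collection: PathwayCollection
    impute_value: float | None = None

    def __post_init__(self):
        if not self.background:
            raise ValueError("empty background")
        dropped = len(self.interesting - self.background)
        if dropped:
            logger.info("%d interesting metabolites outside the background dropped", dropped)
        self.interesting = self.interesting & self.background
        if not self.interesting:
            raise ValueError("no interesting metabolites in the background")
        if self.impute_value is None:
            scored = [1.0 - self.cgnb[m] for m in self.background if m in self.cgnb]
            self.impute_value = float(np.mean(scored)) if scored else 0.0

    @property
    def N(self) -> int:
        return len(self.background)

    @property
    def n(self) -> int:
        return len(self.interesting)


def pathway_relative_weight(ctx: EnrichmentContext) -> dict[str, float]:
    """Relative weight W per pathway: its mean (1 - C) over the across-pathway average."""
    means: dict[str, float] = {}
    for p in ctx.collection:
        vals = [
            1.0 - ctx.cgnb[m] if m in ctx.cgnb else ctx.impute_value for m in p.members
        ]
        n_imputed = sum(1 for m in p.members if m not in ctx.cgnb)
        if n_imputed:
            logger.info("pathway %s: imputed CGNB for %d members", p.id, n_imputed)
        means[p.id] = max(float(np.mean(vals)), _WEIGHT_FLOOR)
    raw_denom = float(np.mean([float(np.mean([
        1.0 - ctx.cgnb[m] if m in ctx.cgnb else ctx.impute_value for m in p.members
    ])) for p in ctx.collection]))
    if raw_denom == 0.0:
        raise ValueError("all CGNB scores are 1: relative weights undefined")
    denom = max(float(np.mean(list(means.values()))), _WEIGHT_FLOOR)
    return {pid: m / denom for pid, m in means.items()}


# ---------------------------------------------------------------------------
# Multiple testing


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, aligned to input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# Per-pathway statistics and the full pipeline


@dataclass
class PathwayStats:
    pathway_id: str
    pathway_name: str
    m1: int
    m2: int
    g: int
    relative_weight: float
    w1: float
    w2: float
    pvalue: float
    fdr: float = field(default=float("nan"))
    members_interesting: list[str] = field(default_factory=list)


def score_pathways(
    ctx: EnrichmentContext, weight_exponent: float = DEFAULT_WEIGHT_EXPONENT
) -> list[PathwayStats]:
    """Weights, Wallenius p-values and BH FDR for every retained pathway.

    Rows are sorted by ascending p-value, ties broken by pathway id.
    Pathways with no interesting members are reported with p = 1.
    """
    weights = pathway_relative_weight(ctx)
    rows: list[PathwayStats] = []
    for p in ctx.collection:
        hits = sorted(p.members & ctx.interesting, key=int)
        m1 = len(p.members)
        w_rel = weights[p.id]
        w1 = w_rel**weight_exponent
        pval = wallenius_pvalue(len(hits), ctx.n, m1, ctx.N, w1, 1.0)
        rows.append(
            PathwayStats(
                pathway_id=p.id,
                pathway_name=p.name,
                m1=m1,
                m2=ctx.N - m1,
                g=len(hits),
                relative_weight=w_rel,
                w1=w1,
                w2=1.0,
                pvalue=pval,
                members_interesting=hits,
            )
        )
    adj = bh_fdr([r.pvalue for r in rows])
    for r, a in zip(rows, adj):
        r.fdr = float(a)
    rows.sort(key=lambda r: (r.pvalue, r.pathway_id))
    return rows


def run_mpinet(interesting, net, coll, config=None, **kwargs):
    """End-to-end pipeline; see :class:`mpinet.model.MPINet` for parameters.

    Convenience wrapper: builds the model, fits it, and returns the
    :class:`mpinet.model.MPINetResults`.
    """
    from .model import MPINet  # local import avoids a cycle

    params = dict(config or {})
    params.update(kwargs)
    return MPINet(interesting, net, coll, **params).fit()


# ---------------------------------------------------------------------------
# Diagnostics


def pathway_gn_bias_test(
    coll: PathwayCollection, gn: dict[str, float], sides: str = "two"
) -> dict[str, float]:
    """Wilcoxon rank-sum p per pathway: member GN scores vs all network GN scores.

    ``sides="one"`` tests whether members have systematically higher GN
    (the detection-bias direction); ``"two"`` is direction-agnostic. Exact
    enumeration for pathways with <= 10 scored members, tie-corrected
    normal approximation otherwise.
    """
    if sides not in {"one", "two"}:
        raise ValueError("sides must be 'one' or 'two'")
    all_scores = np.asarray(list(gn.values()), dtype=float)
    alternative = "greater" if sides == "one" else "two-sided"
    out: dict[str, float] = {}
    for p in coll:
        member_scores = np.asarray([gn[m] for m in p.members if m in gn], dtype=float)
        if member_scores.size == 0:
            logger.warning("pathway %s has no members with GN scores; skipped", p.id)
            continue
        method = "exact" if member_scores.size <= 10 else "asymptotic"
        res = stats.mannwhitneyu(
            member_scores, all_scores, alternative=alternative, method=method
        )
        out[p.id] = float(res.pvalue)
    return out


def pathway_crosstalk(
    coll: PathwayCollection, gcs: GCSMatrix
) -> list[tuple[str, str, float]]:
    """Pathway pairs whose mean cross-set GCS exceeds the global median GCS.

    The mean runs over all cross-set member pairs present in the network,
    excluding same-node pairs (shared members); pathway pairs with no
    valid member pair are skipped. Returns (id_a, id_b, mean_gcs) edges.
    """
    if coll.K < 2:
        raise ValueError("crosstalk needs at least 2 pathways")
    m = len(gcs.node_order)
    if m == 0 or gcs.values.size == 0:
        raise ValueError("empty GCS matrix")
    iu = np.triu_indices(m, k=1)
    median = float(np.median(gcs.values[iu]))
    in_net = set(gcs.node_order)
    member_idx = {
        p.id: np.asarray(sorted(gcs.index_of(x) for x in p.members & in_net), dtype=int)
        for p in coll
    }
    pids = [p.id for p in coll]
    edges: list[tuple[str, str, float]] = []
    for i, a in enumerate(pids):
        ia = member_idx[a]
        for b in pids[i + 1 :]:
            ib = member_idx[b]
            if ia.size == 0 or ib.size == 0:
                continue
            sub = gcs.values[np.ix_(ia, ib)]
            # mask same-node pairs (shared members sit on the zero diagonal)
            mask = ia[:, None] != ib[None, :]
            if not mask.any():
                continue
            mean = float(sub[mask].mean())
            if mean > median:
                edges.append((a, b, mean))
    return edges


def overlap_pvalue(list_a: set, list_b: set, universe: int) -> float:
    """Hypergeometric upper-tail significance of the overlap of two pathway lists."""
    a, b = set(list_a), set(list_b)
    if len(a) > universe or len(b) > universe:
        raise ValueError("list larger than universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, universe, len(a), len(b)))


def write_results_tsv(rows: list[PathwayStats], path) -> None:
    """Result table TSV in the documented column order."""
    def fmt(v: float, pval: bool = False) -> str:
        if pval and v < 1e-4:
            return f"{v:.6e}"
        return f"{v:.6g}"

    with open(path, "w") as fh:
        fh.write(
            "pathway_id\tpathway_name\tm1\tg\trelative_weight\tw1\tpvalue\tfdr\tinteresting_members\n"
        )
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.pathway_id,
                        r.pathway_name,
                        str(r.m1),
                        str(r.g),
                        fmt(r.relative_weight),
                        fmt(r.w1),
                        fmt(r.pvalue, pval=True),
                        fmt(r.fdr, pval=True),
                        ";".join(r.members_interesting),
                    ]
                )
                + "\n"
            )
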