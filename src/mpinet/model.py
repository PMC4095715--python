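"""The MPINet model object: from inputs to a fitted pathway table.

Organised like a statsmodels model: :class:`MPINet` holds the data
(interesting-metabolite list, weighted metabolite network, pathway
collection) and the tunables; :meth:`MPINet.fit` runs the pipeline

    GCS -> GN scores -> binary labels -> monotone spline -> CGNB
        -> background annotation -> relative weights W -> w1 = W**6
        -> Wallenius p per pathway -> BH FDR

and returns a :class:`MPINetResults` carrying the per-pathway statistics,
the intermediate fits, and a ``summary()`` table.
"""

from __future__ import annotations

import logging

import pandas as pd

from .network_io import MetaboliteNetwork
from .connectivity import compute_gcs, compute_gn, GCSMatrix, DEFAULT_BETA, DEFAULT_LMAX
from .bias_model import MonotoneBiasModel, BiasFit, DEFAULT_KNOTS
from .pathways import PathwayCollection, annotate, DEFAULT_MIN_SIZE
from .enrichment import (
    EnrichmentContext,
    PathwayStats,
    score_pathways,
    write_results_tsv,
    DEFAULT_WEIGHT_EXPONENT,
)

logger = logging.getLogger(__name__)


class MPINet:
    """Network-based pathway enrichment model with detection-bias correction.

    Parameters
    ----------
    interesting : set of metabolite ids
        The query list (e.g. differential metabolites).
    network : MetaboliteNetwork
        Global edge-weighted metabolite network.
    pathways : PathwayCollection
        Candidate pathways (un-annotated; annotation happens in fit).
    beta, lmax : walk attenuation and maximum walk length of the GCS.
    knots : number of spline knots for the bias curve.
    weight_exponent : exponent turning the relative weight W into the
        odds weight w1 = W**exponent (0 recovers the unweighted
        hypergeometric overrepresentation test).
    min_pathway_size : smallest background-annotated pathway retained.
    background : explicit metabolite universe; default is the pathway
        member universe restricted to metabolites carrying a CGNB score.
    lambda_strategy : "gcv" or a fixed smoothing parameter.
    """

    def __init__(
        self,
        interesting: set[str],
        network: MetaboliteNetwork,
        pathways: PathwayCollection,
        *,
        beta: float = DEFAULT_BETA,
        lmax: int = DEFAULT_LMAX,
        knots: int = DEFAULT_KNOTS,
        weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
        min_pathway_size: int = DEFAULT_MIN_SIZE,
        background: set[str] | None = None,
        lambda_strategy="gcv",
    ):
        self.interesting = set(interesting)
        self.network = network
        self.pathway_collection = pathways
        self.beta = beta
        self.lmax = lmax
        self.knots = knots
        self.weight_exponent = weight_exponent
        self.min_pathway_size = min_pathway_size
        self.background = set(background) if background is not None else None
        self.lambda_strategy = lambda_strategy

    def fit(self) -> "MPINetResults":
        gcs = compute_gcs(self.network, self.beta, self.lmax)
        gn = compute_gn(gcs)
        bias = MonotoneBiasModel.from_network(
            self.network, gn, self.interesting, self.knots
        ).fit(self.lambda_strategy)
        cgnb = bias.cgnb

        if self.background is not None:
            background = self.background
        else:
            background = self.pathway_collection.member_universe() & set(cgnb)
        logger.info("background size N = %d", len(background))

        annotated = annotate(self.pathway_collection, background, self.min_pathway_size)
        ctx = EnrichmentContext(
            background=background,
            interesting=self.interesting,
            cgnb=cgnb,
            collection=annotated,
        )
        rows = score_pathways(ctx, self.weight_exponent)
        return MPINetResults(self, rows, gcs=gcs, gn=gn, bias_fit=bias, context=ctx)


class MPINetResults:
    """Fitted pathway table plus the intermediate model fits."""

    def __init__(
        self,
        model: MPINet,
        rows: list[PathwayStats],
        *,
        gcs: GCSMatrix,
        gn: dict[str, float],
        bias_fit: BiasFit,
        context: EnrichmentContext,
    ):
        self.model = model
        self.rows = rows
        self.gcs = gcs
        self.gn = gn
        self.bias_fit = bias_fit
        self.context = context

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway_id": [r.pathway_id for r in self.rows],
                "pathway_name": [r.pathway_name for r in self.rows],
                "m1": [r.m1 for r in self.rows],
                "g": [r.g for r in self.rows],
                "relative_weight": [r.relative_weight for r in self.rows],
                "w1": [r.w1 for r in self.rows],
                "pvalue": [r.pvalue for r in self.rows],
                "fdr": [r.fdr for r in self.rows],
                "interesting_members": [
                    ";".join(r.members_interesting) for r in self.rows
                ],
            }
        )

    def pvalue(self, pathway_id: str) -> float:
        for r in self.rows:
            if r.pathway_id == pathway_id:
                return r.pvalue
        raise KeyError(pathway_id)

    def rank(self, pathway_id: str, column: str = "pvalue") -> int:
        """Competition ('min') rank of a pathway by ascending p-value."""
        target = self.pvalue(pathway_id)
        return 1 + sum(1 for r in self.rows if getattr(r, column) < target)

    def to_tsv(self, path) -> None:
        write_results_tsv(self.rows, path)

    def summary(self, max_rows: int = 15) -> str:
        ctx = self.context
        head = [
            "MPINet pathway enrichment",
            f"  background N = {ctx.N}, interesting n = {ctx.n}, "
            f"pathways K = {ctx.collection.K}",
            f"  GCS: beta = {self.model.beta}, lmax = {self.model.lmax}; "
            f"spline knots = {self.model.knots}; "
            f"weight exponent = {self.model.weight_exponent}",
            "",
        ]
        df = self.table.drop(columns=["interesting_members"]).head(max_rows)
        body = df.to_string(
            index=False,
            float_format=lambda v: f"{v:.4g}",
        )
        return "\n".join(head) + "\n" + body

    def __repr__(self) -> str:
        return (
            f"<MPINetResults: K={self.context.collection.K} pathways, "
            f"N={self.context.N}, n={self.context.n}>"
        )
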