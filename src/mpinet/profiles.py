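"""Metabolomic-profile helpers: differential selection and drug-sensitivity screens.

Two preprocessing screens produce the interesting-metabolite lists the
enrichment model consumes: a two-group Wilcoxon rank-sum test on an
abundance matrix (differential metabolites at p < alpha), and a Pearson
correlation of metabolite abundance against drug -log(GI50) potency with
Benjamini-Hochberg adjustment at a deliberately permissive FDR cutoff
(default 0.6) for sensitivity screening.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 20  # combined group size up to which the rank-sum test is exact


def _rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p; exact for small combined n, tie-corrected normal otherwise."""
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= _EXACT_MAX_N and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def select_differential_wilcoxon(
    mat: pd.DataFrame, groups: dict[str, str], alpha: float = 0.1
) -> tuple[set[str], pd.DataFrame]:
    """Differential metabolites between two labeled sample groups.

    ``mat`` is metabolites x samples; ``groups`` maps sample id to one of
    exactly two labels, each with >= 2 samples. Returns the selected set
    (p < alpha) and the per-metabolite statistics table. Metabolites that
    are constant across all samples get p = 1 with a warning.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels}")
    cols_a = [s for s in mat.columns if groups.get(s) == labels[0]]
    cols_b = [s for s in mat.columns if groups.get(s) == labels[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    records = []
    for mid, row in mat.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            logger.warning("metabolite %s constant across all samples; p = 1", mid)
            p = 1.0
        else:
            p = _rank_sum_pvalue(a, b)
        records.append((str(mid), p))
    table = pd.DataFrame(records, columns=["metabolite_id", "pvalue"]).set_index(
        "metabolite_id"
    )
    selected = set(table.index[table["pvalue"] < alpha])
    logger.info("selected %d / %d metabolites at p < %g", len(selected), len(table), alpha)
    return selected, table


def drug_sensitivity_metabolites(
    gi50: dict[str, float] | pd.Series,
    mat: pd.DataFrame,
    fdr_cut: float = 0.6,
) -> tuple[set[str], pd.DataFrame]:
    """Metabolites whose abundance correlates with drug potency (-log GI50).

    Pearson r and two-sided p per metabolite over the samples shared
    between ``gi50`` and ``mat`` (replicate gi50 entries must be averaged
    beforehand into one value per sample; a pandas Series with duplicate
    index entries is averaged here). Benjamini-Hochberg adjusted p below
    ``fdr_cut`` selects; the permissive default (0.6) matches a screening
    rather than a confirmatory use. Metabolites with zero variance or
    fewer than 3 complete pairs are skipped with a warning.
    """
    if isinstance(gi50, pd.Series):
        gi50 = gi50.groupby(level=0).mean().to_dict()
    shared = [s for s in mat.columns if s in gi50]
    if len(shared) < 3:
        raise ValueError("need >= 3 samples shared between gi50 and the matrix")
    gvec = np.asarray([gi50[s] for s in shared], dtype=float)
    if np.ptp(gvec[~np.isnan(gvec)]) == 0:
        raise ValueError("gi50 values have zero variance")
    records = []
    for mid, row in mat.iterrows():
        avec = row[shared].to_numpy(dtype=float)
        ok = ~(np.isnan(avec) | np.isnan(gvec))
        if ok.sum() < 3:
            logger.warning("metabolite %s: < 3 complete pairs; skipped", mid)
            continue
        if np.ptp(avec[ok]) == 0:
            logger.warning("metabolite %s has zero variance; skipped", mid)
            continue
        r, p = stats.pearsonr(avec[ok], gvec[ok])
        records.append((str(mid), float(r), float(p)))
    if not records:
        raise ValueError("no testable metabolites")
    table = pd.DataFrame(records, columns=["metabolite_id", "r", "pvalue"]).set_index(
        "metabolite_id"
    )
    table["fdr"] = bh_fdr(table["pvalue"].to_numpy())
    selected = set(table.index[table["fdr"] < fdr_cut])
    logger.info("selected %d / %d metabolites at FDR < %g", len(selected), len(table), fdr_cut)
    return selected, table
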