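"""Gene-set analysis of factor weight vectors and selected molecule sets.

``gsea_preranked`` is a preranked gene-set enrichment analysis with the
weighted Kolmogorov-Smirnov running-sum statistic (weight exponent 1): genes
are ranked by a signed statistic (here typically a factor's weight vector),
the enrichment score ES is the maximal deviation of the running sum, and the
null is obtained by gene-label permutation preserving set size. NES divides
ES by the mean |null ES| of matching sign; p-values are one-sided within the
matching-sign null with the standard +1 correction, so the minimum
attainable p is 1/(n_perm+1). ``fisher_ora`` is a one-sided hypergeometric
overrepresentation test of a selected gene list against the universe. Both
apply Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import bh_adjust
from .syndata import GeneSetCollection

logger = logging.getLogger(__name__)

SET_SIZE_BOUNDS = (10, 500)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame
    method: str

    def top(self, n: int = 20) -> pd.DataFrame:
        return self.table.sort_values("pval", kind="stable").head(n)


def _running_es(order_stat: np.ndarray, member_mask: np.ndarray, weight: float = 1.0):
    """ES and leading-edge cut from a descending-ranked statistic."""
    w = np.abs(order_stat) ** weight
    hit_w = np.where(member_mask, w, 0.0)
    total_hit = hit_w.sum()
    n = len(order_stat)
    n_miss = n - member_mask.sum()
    if total_hit == 0 or n_miss == 0:
        return np.nan, 0
    p_hit = np.cumsum(hit_w) / total_hit
    p_miss = np.cumsum(~member_mask) / n_miss
    dev = p_hit - p_miss
    i_max = int(np.argmax(np.abs(dev)))
    return float(dev[i_max]), i_max


def gsea_preranked(
    stat: pd.Series,
    sets: GeneSetCollection | dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = SET_SIZE_BOUNDS[0],
    max_size: int = SET_SIZE_BOUNDS[1],
    weight: float = 1.0,
) -> EnrichmentResult:
    """Preranked GSEA of a gene-level statistic against gene sets."""
    if n_perm < 100:
        raise ValueError("n_perm too small for stable permutation p-values")
    if stat.index.duplicated().any():
        raise ValueError("duplicate gene ids in ranking statistic")
    if stat.round(12).duplicated().any():
        logger.warning("ties in the ranking statistic broken by gene id")
    set_dict = sets.sets if isinstance(sets, GeneSetCollection) else sets
    # deterministic ranking: statistic descending, ties by gene id
    order = stat.sort_index().sort_values(ascending=False, kind="stable")
    genes = np.array(order.index)
    values = order.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in set_dict.items():
        inside = sorted(set(members) & set(genes))
        if not inside:
            raise ValueError(f"gene set {name!r} has no overlap with the universe")
        if len(inside) >= n:
            raise ValueError(f"gene set {name!r} covers the entire universe; ES undefined")
        if not (min_size <= len(inside) <= max_size):
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in inside]] = True
        es, i_max = _running_es(values, mask, weight)
        k = len(inside)
        null = np.empty(n_perm)
        for b in range(n_perm):
            pmask = np.zeros(n, dtype=bool)
            pmask[rng.choice(n, size=k, replace=False)] = True
            null[b], _ = _running_es(values, pmask, weight)
        if es >= 0:
            same = null[null >= 0]
            p = (1 + np.sum(same >= es)) / (len(same) + 1)
            denom = np.mean(same) if same.size else np.nan
        else:
            same = null[null < 0]
            p = (1 + np.sum(same <= es)) / (len(same) + 1)
            denom = np.abs(np.mean(same)) if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom != 0 else np.nan
        lead = genes[: i_max + 1][mask[: i_max + 1]] if es >= 0 else genes[i_max:][mask[i_max:]]
        rows.append({"set": name, "size": k, "ES": es, "NES": nes, "pval": p, "leading_edge": ",".join(lead)})
    table = pd.DataFrame(rows).set_index("set")
    table["padj"] = bh_adjust(table["pval"].to_numpy()) if len(table) else []
    return EnrichmentResult(table=table, method="gsea_preranked")


def fisher_ora(
    selected: set[str],
    universe: set[str],
    sets: GeneSetCollection | dict[str, set[str]],
    min_size: int = 1,
    max_size: int = 10**9,
) -> EnrichmentResult:
    """One-sided hypergeometric overrepresentation test per set."""
    if not selected:
        raise ValueError("empty selection")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    set_dict = sets.sets if isinstance(sets, GeneSetCollection) else sets
    big_n = len(universe)
    n_sel = len(selected)
    rows = []
    for name, members in set_dict.items():
        inset = set(members) & universe
        if not (min_size <= len(inset) <= max_size):
            continue
        k = len(inset & selected)
        big_k = len(inset)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n_sel))
        # odds ratio of the 2x2 table (Haldane 0.5 correction on zero cells)
        a, b = k, big_k - k
        c, d = n_sel - k, big_n - big_k - (n_sel - k)
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append({"set": name, "size": big_k, "overlap": k, "odds_ratio": (a * d) / (b * c), "pval": p})
    table = pd.DataFrame(rows).set_index("set")
    table["padj"] = bh_adjust(table["pval"].to_numpy()) if len(table) else []
    return EnrichmentResult(table=table, method="fisher_ora")
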