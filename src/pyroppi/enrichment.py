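"""Two-group gene ranking and permutation GSEA (NES, FDR) plus ORA.

Genes are ranked between high- and low-PPI groups by the signal-to-noise
ratio (mean_high - mean_low) / (sd_high + sd_low), each sd floored at
max(0.2 * |group mean|, 0.2) so near-constant genes cannot blow up the
metric.  Enrichment of a gene set against the ranked list is the classic
weighted Kolmogorov-Smirnov running sum: hits increment by
|metric|^p / sum_hits |metric|^p (p = 1 by default), misses decrement by
1 / (N - hits); the ES is the extremum of the walk (maximum deviation from
zero, signed).

Significance comes from a gene-label permutation null (sample labels are
no longer available once only the ranked list is retained): NES divides
the observed ES by the mean |null ES| of matching sign, the permutation
p-value is the +1-smoothed tail proportion among matching-sign nulls, and
the FDR is the GSEA-style ratio of null to observed tail proportions over
the pooled normalized distributions, clipped to [0, 1] and made monotone
in |NES| within each sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pyroppi.catalog import GeneSet

#: signal-to-noise sd floor constant
SD_FLOOR = 0.2


class DegenerateSetError(ValueError):
    pass


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a ranking metric, descending; ties broken by symbol."""

    genes: tuple[str, ...]
    metric: np.ndarray  # aligned with genes, descending

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate gene symbols in ranked list")
        if not np.all(np.isfinite(self.metric)):
            raise ValueError("non-finite metric values")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_values(cls, metric: pd.Series) -> "RankedList":
        df = metric.rename("metric").rename_axis("gene").reset_index()
        df = df.sort_values(["metric", "gene"], ascending=[False, True],
                            kind="stable")
        return cls(genes=tuple(df["gene"]),
                   metric=df["metric"].to_numpy(dtype=float))


def rank_genes(expr: pd.DataFrame, groups: pd.DataFrame) -> RankedList:
    """Signal-to-noise ranking of all genes between high and low groups."""
    high = groups.index[groups["group"] == "high"].intersection(expr.columns)
    low = groups.index[groups["group"] == "low"].intersection(expr.columns)
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"needs >= 2 samples per group, got high={len(high)} low={len(low)}"
        )
    xh = expr[high].to_numpy(dtype=float)
    xl = expr[low].to_numpy(dtype=float)
    mh, ml = xh.mean(axis=1), xl.mean(axis=1)
    sh = np.maximum(xh.std(axis=1, ddof=1), np.maximum(SD_FLOOR * np.abs(mh), SD_FLOOR))
    sl = np.maximum(xl.std(axis=1, ddof=1), np.maximum(SD_FLOOR * np.abs(ml), SD_FLOOR))
    s2n = (mh - ml) / (sh + sl)
    return RankedList.from_values(pd.Series(s2n, index=expr.index))


def gsea_es(ranked: RankedList, gene_set: GeneSet, p: float = 1.0) -> float:
    """Weighted KS enrichment score of a gene set against a ranked list."""
    hits = np.fromiter((g in gene_set.members for g in ranked.genes),
                       dtype=bool, count=len(ranked))
    n_hits = int(hits.sum())
    n = len(ranked)
    if n_hits == 0 or n_hits == n:
        raise DegenerateSetError(
            f"set {gene_set.name!r} hits {n_hits} of {n} ranked genes"
        )
    weights = np.abs(ranked.metric) ** p
    denom = weights[hits].sum()
    if denom == 0:
        # all hit metrics are exactly zero; fall back to unweighted steps
        steps = np.where(hits, 1.0 / n_hits, -1.0 / (n - n_hits))
    else:
        steps = np.where(hits, weights / denom, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    m_pos = max(float(running.max()), 0.0)
    m_neg = min(float(running.min()), 0.0)
    # maximum deviation from zero, signed; exact ties resolve positive
    return m_pos if m_pos >= -m_neg else m_neg


def _null_es_batch(weights: np.ndarray, n_hits: int, n_perm: int,
                   rng: np.random.Generator) -> np.ndarray:
    """ES of ``n_perm`` random gene-label sets of size n_hits.

    Works on sorted hit positions only (O(k) per permutation): the running
    sum's extrema occur immediately before or after a hit.
    """
    n = len(weights)
    miss_step = 1.0 / (n - n_hits)
    positions = np.empty((n_perm, n_hits), dtype=np.int64)
    for b in range(n_perm):
        positions[b] = rng.choice(n, size=n_hits, replace=False)
    positions.sort(axis=1)
    w = weights[positions]
    denom = w.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cumw = np.cumsum(w, axis=1) / denom
    if zero.any():
        cumw[zero] = (np.arange(1, n_hits + 1) / n_hits)[None, :]
    j = np.arange(1, n_hits + 1)[None, :]
    after = cumw - (positions + 1 - j) * miss_step        # just after hit j
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cumw[:, :-1]], axis=1
    ) - (positions - (j - 1)) * miss_step                  # just before hit j
    m_pos = np.maximum(after.max(axis=1), 0.0)
    m_neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(m_pos >= -m_neg, m_pos, m_neg)


def gsea_permutation(
    ranked: RankedList,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int | None = None,
    p: float = 1.0,
) -> pd.DataFrame:
    """Gene-label permutation GSEA for a collection of sets.

    Returns a table (set, size, es, nes, p_perm, fdr) deterministic for a
    fixed seed.  NES and p are computed against matching-sign null scores;
    a set whose sign has no null mass is flagged with NES = nan.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if seed is None:
        raise ValueError("a seed is required for reproducible permutation GSEA")
    rng = np.random.default_rng(seed)
    weights = np.abs(ranked.metric) ** p
    n = len(ranked)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    by_size: dict[int, np.ndarray] = {}
    for gs in gene_sets:
        members = gs.members & set(ranked.genes)
        k = len(members)
        if k == 0 or k == n:
            rows.append({"set": gs.name, "size": k, "es": np.nan,
                         "nes": np.nan, "p_perm": np.nan, "fdr": np.nan,
                         "flag": "degenerate"})
            continue
        eff = GeneSet(name=gs.name, description=gs.description,
                      members=frozenset(members))
        es = gsea_es(ranked, eff, p=p)
        if k not in by_size:
            by_size[k] = _null_es_batch(weights, k, n_perm, rng)
        null = by_size[k]
        pos, neg = null[null >= 0], null[null < 0]
        flag = ""
        if es >= 0:
            same = pos
            mean_abs = pos.mean() if len(pos) else np.nan
        else:
            same = -neg
            mean_abs = (-neg).mean() if len(neg) else np.nan
        if len(same) == 0 or not np.isfinite(mean_abs) or mean_abs == 0:
            nes = np.nan
            p_perm = np.nan
            flag = "no_matching_sign_null"
        else:
            nes = es / mean_abs
            p_perm = (1 + int((same >= abs(es)).sum())) / (1 + len(same))
        # normalized null for the pooled FDR distribution
        null_nes = np.empty_like(null)
        if len(pos):
            null_nes[null >= 0] = pos / pos.mean() if pos.mean() else 0.0
        if len(neg):
            null_nes[null < 0] = neg / (-neg).mean() if neg.mean() else 0.0
        null_nes_pool.append(null_nes)
        rows.append({"set": gs.name, "size": k, "es": es, "nes": nes,
                     "p_perm": p_perm, "fdr": np.nan, "flag": flag})

    result = pd.DataFrame(rows)
    ok = result["nes"].notna()
    if ok.any() and null_nes_pool:
        pool = np.concatenate(null_nes_pool)
        obs = result.loc[ok, "nes"].to_numpy()
        fdr = np.empty(len(obs))
        for i, nes in enumerate(obs):
            if nes >= 0:
                null_tail = (pool >= nes).sum() / max((pool >= 0).sum(), 1)
                obs_tail = (obs >= nes).sum() / max((obs >= 0).sum(), 1)
            else:
                null_tail = (pool <= nes).sum() / max((pool < 0).sum(), 1)
                obs_tail = (obs <= nes).sum() / max((obs < 0).sum(), 1)
            fdr[i] = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else 1.0
        # enforce monotonicity (BH-style): walking from the least extreme
        # |NES| upward, each set takes the running minimum, so a more
        # extreme set never carries a larger FDR
        for sign in (1, -1):
            m = (obs >= 0) if sign == 1 else (obs < 0)
            if m.sum():
                order = np.argsort(np.abs(obs[m]), kind="stable")
                fdr_m = fdr[m]
                fdr_m[order] = np.minimum.accumulate(fdr_m[order])
                fdr[m] = fdr_m
        result.loc[ok, "fdr"] = fdr
    return result


def ora_hypergeometric(
    query: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    annotation_sets: list[GeneSet],
) -> pd.DataFrame:
    """Over-representation analysis: upper-tail hypergeometric per set.

    Each annotation set is intersected with the universe; p is the
    probability of an overlap at least as large as observed; BH-adjusted
    q across sets.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    big_n, n = len(universe), len(query)
    rows = []
    for gs in annotation_sets:
        members = gs.members & universe
        big_k = len(members)
        k = len(members & query)
        # upper tail including the observed overlap
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append({"set": gs.name, "set_size": big_k, "overlap": k,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
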