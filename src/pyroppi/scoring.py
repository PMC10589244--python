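"""Single-sample gene-set enrichment (ssGSEA) and the directional PPI.

The pyroptosis potential index of a sample is

    PPI = ES(positive regulators) - ES(negative regulators)

where each ES is the single-sample GSEA statistic of the corresponding
regulator set against that sample's expression ranks.  ssGSEA ranks genes
within one sample (1 = lowest expression, average ranks for ties), walks
the genes in decreasing rank order, and accumulates the difference between
a rank-weighted in-set ECDF and the uniform out-of-set ECDF:

    P_in(i)  = sum_{set genes at positions <= i} r^alpha
               / sum_{set genes} r^alpha
    P_out(i) = (# non-set genes at positions <= i) / (N - |set|)
    ES       = sum_{i=1..N} [P_in(i) - P_out(i)]

alpha (default 0.25) is the rank-weighting exponent.  The score depends on
a sample's expression values only through their within-sample ranks, so any
strictly monotone transform of a sample leaves its raw ES unchanged.

Optionally each gene set's ES column is range-normalized across the samples
of the run (divide by max - min); PPI subtracts normalized scores by
default, raw scores on request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from pyroppi.catalog import DirectionalCatalog, GeneSet, restrict_to_measured


class DegenerateSetError(ValueError):
    """Gene set covers all or none of the ranked genes."""


@dataclass(frozen=True)
class EnrichmentParams:
    """ssGSEA parameters: rank-weight exponent and range normalization."""

    alpha: float = 0.25
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene x sample expression matrix.

    Requires >= 2 genes, >= 1 sample, unique gene symbols and sample ids,
    and no missing values (missing data are rejected, not imputed).
    """
    if expr.shape[0] < 2:
        raise ValueError("expression matrix needs at least 2 genes")
    if expr.shape[1] < 1:
        raise ValueError("expression matrix needs at least 1 sample")
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene symbols: {dups}")
    if expr.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    if expr.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    return expr


def read_expression_tsv(path) -> pd.DataFrame:
    """Read an expression TSV (first column gene symbol, rest samples)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str).str.strip()
    return validate_expression(expr)


def rank_within_sample(expr: pd.DataFrame, sample: str) -> pd.Series:
    """Within-sample expression ranks: 1 = lowest, ties get average ranks."""
    if sample not in expr.columns:
        raise KeyError(f"unknown sample {sample!r}")
    values = expr[sample].to_numpy(dtype=float)
    return pd.Series(rankdata(values, method="average"), index=expr.index, name=sample)


def _es_from_ranks(ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    # Walk genes in decreasing rank order, accumulating P_in - P_out.
    order = np.argsort(-ranks, kind="stable")
    in_ordered = in_set[order]
    r_ordered = ranks[order]
    n = ranks.size
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        raise DegenerateSetError(
            f"gene set covers {n_hit} of {n} ranked genes; ES undefined"
        )
    weights = np.where(in_ordered, np.abs(r_ordered) ** alpha, 0.0)
    denom = weights.sum()
    p_in = np.cumsum(weights) / denom
    p_out = np.cumsum(~in_ordered) / (n - n_hit)
    return float(np.sum(p_in - p_out))


def ssgsea_es(ranks: pd.Series, gene_set: GeneSet, params: EnrichmentParams | None = None) -> float:
    """ssGSEA enrichment score of one gene set against one sample's ranks."""
    params = params or EnrichmentParams()
    missing = gene_set.members - set(ranks.index)
    if missing:
        raise KeyError(
            f"gene set {gene_set.name!r} has members absent from the ranked "
            f"genes: {sorted(missing)[:5]}"
        )
    in_set = ranks.index.isin(gene_set.members)
    return _es_from_ranks(ranks.to_numpy(dtype=float), in_set, params.alpha)


def score_matrix(
    expr: pd.DataFrame,
    gene_sets: list[GeneSet],
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """ssGSEA ES for every sample x gene set; samples are scored independently.

    With ``params.normalize`` each set's column is divided by the range
    (max - min) of that set's raw ES across the samples of this run; a zero
    range is left untouched.
    """
    params = params or EnrichmentParams()
    validate_expression(expr)
    genes = expr.index
    values = expr.to_numpy(dtype=float)
    masks = []
    for gs in gene_sets:
        mask = genes.isin(gs.members)
        k = int(mask.sum())
        if k == 0 or k == len(genes):
            raise DegenerateSetError(
                f"gene set {gs.name!r} covers {k} of {len(genes)} measured genes"
            )
        masks.append(mask)

    out = np.empty((expr.shape[1], len(gene_sets)))
    for j in range(expr.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        for s, mask in enumerate(masks):
            out[j, s] = _es_from_ranks(ranks, mask, params.alpha)
    table = pd.DataFrame(out, index=expr.columns, columns=[gs.name for gs in gene_sets])
    table.index.name = "sample"
    if params.normalize:
        rng = table.max(axis=0) - table.min(axis=0)
        rng = rng.replace(0.0, 1.0)
        table = table / rng
    return table


def compute_ppi(
    expr: pd.DataFrame,
    catalog: DirectionalCatalog,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Per-sample PPI table: es_positive, es_negative, ppi.

    The catalog is first restricted to measured genes (an error if either
    direction loses all members).  ppi = es_positive - es_negative row by
    row; with ``params.normalize`` the subtraction uses range-normalized
    scores (normalization applied per direction), otherwise raw scores.
    """
    params = params or EnrichmentParams()
    restricted, _report = restrict_to_measured(catalog, expr.index)
    es = score_matrix(expr, [restricted.positive, restricted.negative], params)
    table = pd.DataFrame(
        {
            "es_positive": es[restricted.positive.name],
            "es_negative": es[restricted.negative.name],
        },
        index=es.index,
    )
    table["ppi"] = table["es_positive"] - table["es_negative"]
    table.index.name = "sample"
    return table


def write_ppi_tsv(ppi: pd.DataFrame, path) -> None:
    ppi.to_csv(path, sep="\t", float_format="%.10g")


def read_ppi_tsv(path) -> pd.DataFrame:
    ppi = pd.read_csv(path, sep="\t", index_col=0)
    required = {"es_positive", "es_negative", "ppi"}
    missing = required - set(ppi.columns)
    if missing:
        raise ValueError(f"PPI table missing columns: {sorted(missing)}")
    return ppi
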