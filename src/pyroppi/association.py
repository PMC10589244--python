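"""Associations of the PPI with immune and molecular covariates.

Covers Spearman/Pearson correlation of the per-sample index with
microenvironment scores (stromal/immune/ESTIMATE score, tumor purity),
immune-cell fractions, checkpoint-gene expression and molecular features
(TMB, MSI, stemness, HRD, pathway scores); immune-subtype comparisons;
tumor mutation burden from MAF-like mutation tables; per-gene mutation
frequency; and tumor/normal log2 expression ratios.  Missing values are
pairwise-deleted per test and never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pyroppi.cohort import StratumSkipped, _mannwhitney

#: MAF variant classifications counted as nonsynonymous for TMB
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site",
})

#: full vocabulary recognized in mutation tables (silent classes included)
KNOWN_CLASSES = NONSYNONYMOUS_CLASSES | frozenset({
    "Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "RNA", "IGR",
})

DEFAULT_EXOME_MB = 38.0


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    method: str
    coefficient: float
    p: float
    n: int
    stratum: str = "pan"
    flag: str = ""


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman's rho (all n! pairings)."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    perms = np.array(list(permutations(range(n))), dtype=np.intp)
    rhos = (rx[perms] @ ry) / n
    observed = float(rx @ ry) / n
    return float((np.abs(rhos) >= abs(observed) - 1e-12).mean())


def correlate(x, y, method: str = "spearman", variable: str = "",
              stratum: str = "pan") -> CorrelationResult:
    """Correlation of two per-sample vectors with pairwise missing drop.

    Spearman is Pearson on average ranks with a t-approximation p-value;
    for n <= 9 the p-value is exact, from exhaustive permutation of the
    pairing.  A constant vector yields an undefined, flagged coefficient.
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    keep = x.notna() & y.notna()
    xv, yv = x[keep].to_numpy(), y[keep].to_numpy()
    n = len(xv)
    if n < 3:
        raise ValueError(f"needs >= 3 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(variable=variable, method=method,
                                 coefficient=float("nan"), p=float("nan"),
                                 n=n, stratum=stratum, flag="constant_input")
    if method == "spearman":
        rho, p = stats.spearmanr(xv, yv)
        if n <= 9:
            p = _spearman_exact_p(xv, yv)
        return CorrelationResult(variable, "spearman", float(rho), float(p),
                                 n, stratum)
    if method == "pearson":
        r, p = stats.pearsonr(xv, yv)
        return CorrelationResult(variable, "pearson", float(r), float(p),
                                 n, stratum)
    raise ValueError(f"unknown method {method!r}")


def association_scan(
    ppi: pd.DataFrame,
    scores: pd.DataFrame,
    method: str = "spearman",
    ann: pd.DataFrame | None = None,
    variables: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Correlate PPI with each score column, per stratum and pan-cancer.

    Returns a tidy table (stratum, variable, method, coefficient, p, q, n,
    star) with BH adjustment within each variable family, plus a skip log.
    """
    variables = variables or [c for c in scores.columns]
    strata = ["pan"]
    if ann is not None:
        strata += sorted(ann.loc[ann["tissue"] == "tumor", "cancer_type"].unique())
    rows, skips = [], {}
    for st in strata:
        if st == "pan":
            ids = ppi.index.intersection(scores.index)
        else:
            tumor_ids = ann.index[(ann["cancer_type"] == st) & (ann["tissue"] == "tumor")]
            ids = ppi.index.intersection(scores.index).intersection(tumor_ids)
        for var in variables:
            if var not in scores.columns:
                skips[f"{st}/{var}"] = "variable absent from score table"
                continue
            x = ppi.loc[ids, "ppi"]
            y = scores.loc[ids, var]
            try:
                res = correlate(x, y, method=method, variable=var, stratum=st)
            except ValueError as exc:
                skips[f"{st}/{var}"] = str(exc)
                continue
            rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if len(out):
        q = np.full(len(out), np.nan)
        for var in out["variable"].unique():
            m = (out["variable"] == var) & out["p"].notna()
            if m.sum():
                q[m.to_numpy()] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
        out["q"] = q
        out["star"] = out["p"] < 0.05
    return out, skips


def checkpoint_correlation(
    ppi: pd.DataFrame,
    expr: pd.DataFrame,
    checkpoint_genes: list[str],
    ann: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pearson r of PPI vs each checkpoint gene's expression per stratum.

    Unmeasured genes are reported with a 'missing' flag; constant genes
    are flagged 'constant_input'.
    """
    strata = ["pan"]
    if ann is not None:
        strata += sorted(ann.loc[ann["tissue"] == "tumor", "cancer_type"].unique())
    rows = []
    for st in strata:
        if st == "pan":
            ids = ppi.index.intersection(expr.columns)
        else:
            tumor_ids = ann.index[(ann["cancer_type"] == st) & (ann["tissue"] == "tumor")]
            ids = ppi.index.intersection(expr.columns).intersection(tumor_ids)
        for gene in checkpoint_genes:
            if gene not in expr.index:
                rows.append({"stratum": st, "gene": gene, "method": "pearson",
                             "coefficient": np.nan, "p": np.nan, "n": 0,
                             "flag": "missing"})
                continue
            try:
                res = correlate(ppi.loc[ids, "ppi"], expr.loc[gene, ids],
                                method="pearson", variable=gene, stratum=st)
                rows.append({"stratum": st, "gene": gene, "method": "pearson",
                             "coefficient": res.coefficient, "p": res.p,
                             "n": res.n, "flag": res.flag})
            except ValueError as exc:
                rows.append({"stratum": st, "gene": gene, "method": "pearson",
                             "coefficient": np.nan, "p": np.nan, "n": len(ids),
                             "flag": str(exc)})
    return pd.DataFrame(rows)


def subtype_compare(
    ppi: pd.DataFrame,
    ann: pd.DataFrame,
    subtype_col: str = "immune_subtype",
    stratum: str | None = None,
) -> dict:
    """PPI across immune subtypes: Kruskal-Wallis omnibus, per-subtype
    medians, and pairwise rank-sum tests with BH adjustment.

    Subtypes with fewer than 2 samples are excluded and logged.
    """
    sub = ann if stratum is None else ann[ann["cancer_type"] == stratum]
    sub = sub[sub["tissue"] == "tumor"]
    ids = sub.index.intersection(ppi.index)
    cat = sub.loc[ids, subtype_col].dropna()
    counts = cat.value_counts()
    excluded = sorted(counts.index[counts < 2])
    kept = sorted(counts.index[counts >= 2])
    if len(kept) < 2:
        raise StratumSkipped(
            f"{stratum or 'pan'}: fewer than 2 subtypes with >= 2 samples"
        )
    vals = {lv: ppi.loc[cat.index[cat == lv], "ppi"].to_numpy() for lv in kept}
    h, p = stats.kruskal(*vals.values())
    pairs, pvals = [], []
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            _, pw = _mannwhitney(vals[a], vals[b])
            pairs.append((a, b))
            pvals.append(pw)
    q = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    return {
        "stratum": stratum or "pan",
        "kruskal_h": float(h), "kruskal_p": float(p),
        "medians": {lv: float(np.median(v)) for lv, v in vals.items()},
        "n": {lv: int(len(v)) for lv, v in vals.items()},
        "pairwise": [
            {"a": a, "b": b, "p": float(pv), "q": float(qv)}
            for (a, b), pv, qv in zip(pairs, pvals, q)
        ],
        "excluded_subtypes": excluded,
    }


# ---------------------------------------------------------------------------
# mutation tables


def read_mutation_tsv(path) -> pd.DataFrame:
    """Read a MAF-like TSV; recognizes Hugo_Symbol / Tumor_Sample_Barcode /
    Variant_Classification or plain sample/gene/variant_classification."""
    mut = pd.read_csv(path, sep="\t")
    aliases = {"Hugo_Symbol": "gene", "Tumor_Sample_Barcode": "sample",
               "Variant_Classification": "variant_classification"}
    mut = mut.rename(columns=aliases)
    required = {"sample", "gene", "variant_classification"}
    missing = required - set(mut.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    return mut


def compute_tmb(
    mut: pd.DataFrame,
    samples: list[str] | pd.Index,
    exome_mb: float = DEFAULT_EXOME_MB,
    nonsynonymous: frozenset[str] = NONSYNONYMOUS_CLASSES,
) -> tuple[pd.Series, dict]:
    """Tumor mutation burden: nonsynonymous mutations per megabase.

    Rows whose classification is outside the known vocabulary are excluded
    with a warning count in the QC report; samples absent from the table
    receive TMB = 0.
    """
    if exome_mb <= 0:
        raise ValueError(f"exome_mb must be > 0, got {exome_mb}")
    known = mut["variant_classification"].isin(KNOWN_CLASSES | nonsynonymous)
    qc = {
        "rows_total": int(len(mut)),
        "rows_unknown_class": int((~known).sum()),
        "unknown_classes": sorted(
            mut.loc[~known, "variant_classification"].unique().tolist()
        ),
    }
    ns = mut[known & mut["variant_classification"].isin(nonsynonymous)]
    counts = ns.groupby("sample").size()
    tmb = pd.Series(0.0, index=pd.Index(samples, name="sample"))
    common = counts.index.intersection(tmb.index)
    tmb.loc[common] = counts.loc[common] / exome_mb
    tmb.name = "tmb"
    return tmb, qc


def mutation_frequency(
    mut: pd.DataFrame,
    ann: pd.DataFrame,
    genes: list[str],
    nonsilent_only: bool = True,
) -> pd.DataFrame:
    """Per-gene, per-stratum fraction of tumor samples with >= 1 mutation.

    A sample with multiple rows for a gene counts once.  With
    ``nonsilent_only`` (default) only nonsynonymous rows are counted.
    """
    tumor = ann[ann["tissue"] == "tumor"]
    use = mut
    if nonsilent_only:
        use = mut[mut["variant_classification"].isin(NONSYNONYMOUS_CLASSES)]
    mutated = use[["sample", "gene"]].drop_duplicates()
    rows = []
    for st in sorted(tumor["cancer_type"].unique()):
        ids = set(tumor.index[tumor["cancer_type"] == st])
        if not ids:
            continue
        hits = mutated[mutated["sample"].isin(ids)]
        per_gene = hits.groupby("gene")["sample"].nunique()
        for gene in genes:
            rows.append({"stratum": st, "gene": gene,
                         "frequency": float(per_gene.get(gene, 0)) / len(ids),
                         "n": len(ids)})
    return pd.DataFrame(rows)


def diff_expression_log2ratio(
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    genes: list[str],
    log2_offset: float = 1.0,
) -> pd.DataFrame:
    """Per-gene, per-stratum log2(mean tumor / mean normal) with Wilcoxon p.

    The expression matrix is assumed to be on the log2(x + offset) scale
    and is back-transformed to linear before averaging.  A zero normal
    mean receives a 1e-9 pseudocount and a flag.
    """
    linear = np.power(2.0, expr) - log2_offset
    rows = []
    for st in sorted(ann["cancer_type"].unique()):
        sub = ann[ann["cancer_type"] == st]
        t_ids = sub.index[sub["tissue"] == "tumor"].intersection(expr.columns)
        n_ids = sub.index[sub["tissue"] == "normal"].intersection(expr.columns)
        if len(t_ids) == 0 or len(n_ids) == 0:
            continue
        for gene in genes:
            if gene not in expr.index:
                continue
            t_vals = linear.loc[gene, t_ids].to_numpy(dtype=float)
            n_vals = linear.loc[gene, n_ids].to_numpy(dtype=float)
            t_mean, n_mean = t_vals.mean(), n_vals.mean()
            flag = ""
            if n_mean == 0:
                n_mean = 1e-9
                flag = "zero_normal_mean"
            _, p = _mannwhitney(t_vals, n_vals)
            rows.append({"stratum": st, "gene": gene,
                         "log2_ratio": float(np.log2(max(t_mean, 1e-12) / n_mean)),
                         "p": p, "n_tumor": len(t_ids), "n_normal": len(n_ids),
                         "flag": flag})
    return pd.DataFrame(rows)
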