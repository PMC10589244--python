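"""Expression-based drug-sensitivity prediction and PPI comparison.

A cell-line panel (expression plus per-drug IC50-like responses, lower =
more sensitive) trains a ridge linear model per drug on z-score-homogenized
expression; tumor samples are projected through the same homogenization and
receive predicted IC50 values, which are then compared between high- and
low-PPI groups per cancer type.  The panel's own PPI can also be correlated
directly with measured drug responses (Pearson).

This is a deliberately simple, fully documented pipeline (shared-gene
intersection, independent per-gene z-scoring, cross-validated ridge over a
fixed penalty grid); model metadata records every choice so predictions are
not mistaken for output of more elaborate transfer-learning tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from pyroppi.association import correlate
from pyroppi.catalog import DirectionalCatalog
from pyroppi.cohort import _mannwhitney
from pyroppi.scoring import EnrichmentParams, compute_ppi

#: ridge penalty grid: 10^{-3..3} in half-decade steps
PENALTY_GRID = tuple(10.0 ** e for e in np.arange(-3, 3.5, 0.5))
MIN_SHARED_GENES = 200
MIN_TRAIN_RESPONSES = 10


@dataclass
class HomogenizeReport:
    shared_genes: int
    dropped_constant: list[str] = field(default_factory=list)
    dropped_unshared: int = 0


def homogenize(
    train_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    min_shared: int = MIN_SHARED_GENES,
) -> tuple[pd.DataFrame, pd.DataFrame, HomogenizeReport]:
    """Align two expression matrices on shared genes and z-score each.

    Genes constant in either matrix are dropped (z-score undefined).  The
    matrices are standardized independently, which removes platform scale
    and location differences gene by gene.
    """
    shared = train_expr.index.intersection(target_expr.index)
    report = HomogenizeReport(
        shared_genes=len(shared),
        dropped_unshared=(len(train_expr) - len(shared)) + (len(target_expr) - len(shared)),
    )
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared genes; needs >= {min_shared}"
        )
    a = train_expr.loc[shared].astype(float)
    b = target_expr.loc[shared].astype(float)
    const = (a.std(axis=1, ddof=0) == 0) | (b.std(axis=1, ddof=0) == 0)
    report.dropped_constant = sorted(shared[const])
    a, b = a.loc[~const.values], b.loc[~const.values]
    if len(a) < min_shared:
        raise ValueError(
            f"only {len(a)} usable shared genes after dropping constants"
        )

    def zscore(m: pd.DataFrame) -> pd.DataFrame:
        mu = m.mean(axis=1)
        sd = m.std(axis=1, ddof=0)
        return m.sub(mu, axis=0).div(sd, axis=0)

    return zscore(a), zscore(b), report


@dataclass
class RidgeIc50Model:
    drug: str
    genes: list[str]
    coef: np.ndarray
    intercept: float
    alpha: float
    train_n: int
    cv_folds: int
    seed: int
    cv_scores: dict[float, float]

    def predict(self, homogenized_expr: pd.DataFrame) -> pd.Series:
        x = homogenized_expr.loc[self.genes].to_numpy(dtype=float).T
        return pd.Series(x @ self.coef + self.intercept,
                         index=homogenized_expr.columns, name=self.drug)


def fit_ridge_ic50(
    expr: pd.DataFrame,
    responses: pd.Series,
    drug: str = "",
    alphas: tuple[float, ...] = PENALTY_GRID,
    n_folds: int = 10,
    seed: int = 0,
) -> RidgeIc50Model:
    """Ridge model of drug response on (homogenized) cell-line expression.

    The penalty is chosen by seeded k-fold cross-validation over the grid,
    minimizing mean squared error; fold assignment is deterministic for a
    fixed seed.  ``expr`` is gene x cell line and should already be on the
    homogenized (z-score) scale.
    """
    y = responses.dropna()
    if len(y) < MIN_TRAIN_RESPONSES:
        raise ValueError(
            f"drug {drug!r}: {len(y)} training responses, needs >= "
            f"{MIN_TRAIN_RESPONSES}"
        )
    if float(y.std()) == 0:
        raise ValueError(f"drug {drug!r}: constant training response")
    lines = expr.columns.intersection(y.index)
    x = expr[lines].to_numpy(dtype=float).T
    yv = y.loc[lines].to_numpy(dtype=float)
    n_folds = min(n_folds, len(lines))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_scores: dict[float, float] = {}
    for alpha in alphas:
        errs = []
        for tr, te in kf.split(x):
            model = Ridge(alpha=alpha).fit(x[tr], yv[tr])
            errs.append(float(np.mean((model.predict(x[te]) - yv[te]) ** 2)))
        cv_scores[alpha] = float(np.mean(errs))
    best = min(cv_scores, key=lambda a: (cv_scores[a], a))
    final = Ridge(alpha=best).fit(x, yv)
    return RidgeIc50Model(
        drug=drug, genes=list(expr.index), coef=final.coef_,
        intercept=float(final.intercept_), alpha=float(best),
        train_n=len(lines), cv_folds=n_folds, seed=seed, cv_scores=cv_scores,
    )


def predict_and_compare(
    model: RidgeIc50Model,
    tumor_expr: pd.DataFrame,
    groups: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame, dict[str, str]]:
    """Predict IC50 for tumor samples and compare high vs low PPI groups.

    ``tumor_expr`` must be on the same homogenized scale as the training
    matrix.  Returns per-sample predictions, a per-stratum comparison table
    (median IC50 per group, two-sided rank-sum p; lower IC50 = more
    sensitive), and a skip log.
    """
    preds = model.predict(tumor_expr)
    rows, skips = [], {}
    for st in sorted(groups["cancer_type"].unique()):
        g = groups[groups["cancer_type"] == st]
        hi = g.index[g["group"] == "high"].intersection(preds.index)
        lo = g.index[g["group"] == "low"].intersection(preds.index)
        if len(hi) < 2 or len(lo) < 2:
            skips[st] = f"group too small (high={len(hi)}, low={len(lo)})"
            continue
        _, p = _mannwhitney(preds.loc[hi].to_numpy(), preds.loc[lo].to_numpy())
        rows.append({
            "stratum": st, "drug": model.drug,
            "median_ic50_high": float(preds.loc[hi].median()),
            "median_ic50_low": float(preds.loc[lo].median()),
            "p": p, "n_high": len(hi), "n_low": len(lo),
            "orientation": "lower IC50 = more sensitive",
        })
    return preds, pd.DataFrame(rows), skips


def cellline_ppi_drug_correlation(
    panel_expr: pd.DataFrame,
    drug_responses: pd.DataFrame,
    catalog: DirectionalCatalog,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """PPI of each cell line vs measured drug response, Pearson per drug.

    ``drug_responses`` is drug x cell line; missing responses are
    pairwise-dropped.  Constant responses are flagged; drugs with < 3
    complete pairs are skipped with a flag.
    """
    ppi = compute_ppi(panel_expr, catalog, params)
    rows = []
    for drug in drug_responses.index:
        y = drug_responses.loc[drug]
        common = ppi.index.intersection(y.dropna().index)
        if len(common) < 3:
            rows.append({"drug": drug, "r": np.nan, "p": np.nan,
                         "n": len(common), "flag": "too_few_pairs"})
            continue
        res = correlate(ppi.loc[common, "ppi"], y.loc[common],
                        method="pearson", variable=str(drug))
        rows.append({"drug": drug, "r": res.coefficient, "p": res.p,
                     "n": res.n, "flag": res.flag})
    return pd.DataFrame(rows)
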