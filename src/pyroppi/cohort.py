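"""Differential-PPI and survival statistics across cancer types.

Clinical annotations travel as a per-sample table with cancer type, tissue
(tumor/normal), a patient pairing key, four survival endpoints (overall,
disease-specific, disease-free, progression-free; each a time in days plus
a 0/1 event flag), and optional demographic / subtype covariates.

Tumor samples are dichotomized into high/low-PPI groups within each cancer
type (median split by default; samples exactly at the threshold go to the
low group), or trimmed to the top and bottom 30% of the PPI distribution.
Group prognosis is compared with the two-group log-rank test; the
continuous score is additionally assessed with a univariate Cox
proportional-hazards model fitted by Newton iteration on the Breslow
partial likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

ENDPOINTS = ("os", "dss", "dfs", "pfs")

#: survival times of exactly zero are shifted to half a day to keep the
#: first risk set well defined; negative times are rejected.
ZERO_TIME_SHIFT = 0.5


class StratumSkipped(Exception):
    """A stratum could not be analyzed; the reason is the message."""


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-sample clinical table.

    ``cancer_type`` and ``tissue`` must be present and non-missing; tissue
    values are 'tumor'/'normal'.  For each endpoint present, times must be
    non-negative (zeros are shifted to :data:`ZERO_TIME_SHIFT`) and events
    coded 0/1.
    """
    ann = ann.copy()
    for col in ("cancer_type", "tissue"):
        if col not in ann.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
        if ann[col].isna().any():
            raise ValueError(f"column {col!r} has missing values")
    bad = set(ann["tissue"].unique()) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unrecognized tissue labels: {sorted(bad)}")
    for ep in ENDPOINTS:
        tcol, ecol = f"{ep}_time", f"{ep}_event"
        if tcol in ann.columns:
            t = ann[tcol]
            if (t.dropna() < 0).any():
                raise ValueError(f"{tcol}: negative survival times")
            ann.loc[t == 0, tcol] = ZERO_TIME_SHIFT
            ev = ann[ecol].dropna()
            if not set(ev.unique()) <= {0, 1}:
                raise ValueError(f"{ecol}: events must be coded 0/1")
    return ann


def read_clinical_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    return validate_annotations(ann)


# ---------------------------------------------------------------------------
# tumor vs normal differential PPI


@dataclass(frozen=True)
class RankTestResult:
    stratum: str
    test: str
    statistic: float
    p: float
    n_tumor: int
    n_normal: int
    median_tumor: float
    median_normal: float


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test: exact null for combined n <= 20 without
    ties, normal approximation with continuity correction otherwise."""
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def diff_ppi_unpaired(ppi: pd.DataFrame, ann: pd.DataFrame, stratum: str) -> RankTestResult:
    """Wilcoxon rank-sum comparison of tumor vs normal PPI in one stratum."""
    sub = ann[ann["cancer_type"] == stratum]
    tumor = ppi.loc[ppi.index.intersection(sub.index[sub["tissue"] == "tumor"]), "ppi"]
    normal = ppi.loc[ppi.index.intersection(sub.index[sub["tissue"] == "normal"]), "ppi"]
    if len(tumor) == 0 or len(normal) == 0:
        raise StratumSkipped(
            f"{stratum}: needs >=1 tumor and >=1 normal sample "
            f"(got {len(tumor)}/{len(normal)})"
        )
    w, p = _mannwhitney(tumor.to_numpy(), normal.to_numpy())
    return RankTestResult(
        stratum=stratum, test="wilcoxon_rank_sum", statistic=w, p=p,
        n_tumor=len(tumor), n_normal=len(normal),
        median_tumor=float(tumor.median()), median_normal=float(normal.median()),
    )


def diff_ppi_paired(ppi: pd.DataFrame, ann: pd.DataFrame, stratum: str) -> RankTestResult:
    """Wilcoxon signed-rank on within-patient tumor-normal PPI differences.

    Zero differences are dropped (Wilcoxon's original treatment); a stratum
    with no complete pairs, or only zero differences, is skipped.
    """
    sub = ann[ann["cancer_type"] == stratum]
    tumor = sub[sub["tissue"] == "tumor"]
    normal = sub[sub["tissue"] == "normal"]
    pairs = pd.merge(
        tumor.reset_index().rename(columns={tumor.index.name or "index": "sample"}),
        normal.reset_index().rename(columns={normal.index.name or "index": "sample"}),
        on="patient_id", suffixes=("_t", "_n"),
    )
    pairs = pairs[pairs["sample_t"].isin(ppi.index) & pairs["sample_n"].isin(ppi.index)]
    if len(pairs) == 0:
        raise StratumSkipped(f"{stratum}: no complete tumor/normal pairs")
    diffs = (
        ppi.loc[pairs["sample_t"], "ppi"].to_numpy()
        - ppi.loc[pairs["sample_n"], "ppi"].to_numpy()
    )
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        raise StratumSkipped(f"{stratum}: all paired differences are zero")
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", zero_method="wilcox",
                         method=method)
    t_vals = ppi.loc[pairs["sample_t"], "ppi"]
    n_vals = ppi.loc[pairs["sample_n"], "ppi"]
    return RankTestResult(
        stratum=stratum, test="wilcoxon_signed_rank",
        statistic=float(res.statistic), p=float(min(res.pvalue, 1.0)),
        n_tumor=len(pairs), n_normal=len(pairs),
        median_tumor=float(t_vals.median()), median_normal=float(n_vals.median()),
    )


# ---------------------------------------------------------------------------
# grouping


def split_groups(
    ppi: pd.DataFrame,
    ann: pd.DataFrame,
    rule: str = "median",
    stratum: str | None = None,
    min_group: int = 2,
) -> pd.DataFrame:
    """Assign tumor samples to high/low PPI groups within each cancer type.

    rule 'median' (default) or 'mean': samples strictly above the
    within-stratum threshold are 'high', at-or-below are 'low'.
    rule 'top_bottom_30': keep the ceil(0.3 n) highest and lowest PPI
    samples and discard the middle.  Strata yielding a group smaller than
    ``min_group`` are skipped.  Returns a per-sample table with columns
    group, threshold_value, rule, cancer_type.
    """
    if rule not in {"median", "mean", "top_bottom_30"}:
        raise ValueError(f"unknown split rule {rule!r}")
    tumor = ann[ann["tissue"] == "tumor"]
    strata = [stratum] if stratum is not None else sorted(tumor["cancer_type"].unique())
    frames = []
    skipped: dict[str, str] = {}
    for st in strata:
        ids = tumor.index[tumor["cancer_type"] == st].intersection(ppi.index)
        vals = ppi.loc[ids, "ppi"].sort_values()
        if len(vals) < 4:
            skipped[st] = f"only {len(vals)} tumor samples (needs >= 4)"
            continue
        if rule in {"median", "mean"}:
            threshold = float(vals.median() if rule == "median" else vals.mean())
            group = pd.Series(
                np.where(vals > threshold, "high", "low"), index=vals.index
            )
        else:
            k = math.ceil(0.3 * len(vals))
            low_ids, high_ids = vals.index[:k], vals.index[-k:]
            threshold = float("nan")
            group = pd.concat([
                pd.Series("low", index=low_ids),
                pd.Series("high", index=high_ids),
            ])
        counts = group.value_counts()
        if counts.get("high", 0) < min_group or counts.get("low", 0) < min_group:
            skipped[st] = (
                f"group smaller than {min_group} after {rule} split "
                f"(high={counts.get('high', 0)}, low={counts.get('low', 0)})"
            )
            continue
        frames.append(pd.DataFrame({
            "group": group, "threshold_value": threshold,
            "rule": rule, "cancer_type": st,
        }))
    if not frames:
        raise StratumSkipped("; ".join(f"{k}: {v}" for k, v in skipped.items())
                             or "no strata to split")
    out = pd.concat(frames)
    out.index.name = "sample"
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    n: int
    n_events: int


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-group log-rank chi-square (1 df); deaths at equal times pooled.

    Returns a no-event sentinel (chi2 = nan, p = nan) when no events occur.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    n_events = int(events.sum())
    if n_events == 0:
        return LogrankResult(chi2=float("nan"), p=float("nan"),
                             n=len(times), n_events=0)
    a = groups == labels[0]
    res = _ll_logrank(times[a], times[~a], event_observed_A=events[a],
                      event_observed_B=events[~a])
    return LogrankResult(chi2=float(res.test_statistic), p=float(res.p_value),
                         n=len(times), n_events=n_events)


@dataclass(frozen=True)
class CoxResult:
    coef: float
    hr: float
    hr_lower: float
    hr_upper: float
    se: float
    p: float
    n: int
    n_events: int
    converged: bool
    flag: str = ""


def _breslow_score_info(beta: float, times: np.ndarray, events: np.ndarray,
                        x: np.ndarray) -> tuple[float, float, float]:
    """Log partial likelihood, score and information under Breslow ties."""
    order = np.argsort(-times, kind="stable")
    t, e, xv = times[order], events[order], x[order]
    eta = beta * xv
    # running sums over the risk set (subjects with time >= current)
    exp_eta = np.exp(eta)
    s0 = np.cumsum(exp_eta)
    s1 = np.cumsum(exp_eta * xv)
    s2 = np.cumsum(exp_eta * xv * xv)
    loglik = score = info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        # risk set for this time = subjects 0..j (times sorted descending)
        d_mask = e[i:j + 1] == 1
        d = int(d_mask.sum())
        if d > 0:
            S0, S1, S2 = s0[j], s1[j], s2[j]
            xs = xv[i:j + 1][d_mask]
            loglik += beta * xs.sum() - d * np.log(S0)
            score += xs.sum() - d * S1 / S0
            info += d * (S2 / S0 - (S1 / S0) ** 2)
        i = j + 1
    return loglik, score, info


def cox_partial_loglik(beta: float, times, events, covariate) -> float:
    """Breslow log partial likelihood at a given coefficient value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    ll, _, _ = _breslow_score_info(beta, times, events, x)
    return ll


def cox_univariate(times, events, covariate, max_iter: int = 100,
                   tol: float = 1e-10) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Breslow ties, Newton).

    Returns the hazard ratio exp(beta) with a Wald 95% CI and p-value.
    Requires >= 2 events and a non-constant covariate; non-convergence or a
    runaway coefficient (monotone likelihood / perfect separation) yields a
    flagged result with no estimate.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    n_events = int(events.sum())
    if n_events < 2:
        raise ValueError(f"needs >= 2 events, got {n_events}")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    # center + scale for numerical stability; rescale the estimate after
    mu, sd = x.mean(), x.std()
    z = (x - mu) / sd
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        _, score, info = _breslow_score_info(beta, times, events, z)
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(beta) > 50:  # monotone likelihood
            return CoxResult(coef=float("nan"), hr=float("nan"),
                             hr_lower=float("nan"), hr_upper=float("nan"),
                             se=float("nan"), p=float("nan"), n=len(times),
                             n_events=n_events, converged=False,
                             flag="monotone_likelihood")
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        return CoxResult(coef=float("nan"), hr=float("nan"),
                         hr_lower=float("nan"), hr_upper=float("nan"),
                         se=float("nan"), p=float("nan"), n=len(times),
                         n_events=n_events, converged=False,
                         flag="no_convergence")
    _, _, info = _breslow_score_info(beta, times, events, z)
    se_z = 1.0 / math.sqrt(info)
    coef, se = beta / sd, se_z / sd
    zstat = coef / se
    p = 2 * stats.norm.sf(abs(zstat))
    return CoxResult(
        coef=float(coef), hr=float(np.exp(coef)),
        hr_lower=float(np.exp(coef - 1.959963984540054 * se)),
        hr_upper=float(np.exp(coef + 1.959963984540054 * se)),
        se=float(se), p=float(p), n=len(times), n_events=n_events,
        converged=True,
    )


def survival_scan(
    scores: pd.DataFrame,
    ann: pd.DataFrame,
    endpoints: tuple[str, ...] = ENDPOINTS,
    score_col: str = "ppi",
    rule: str = "median",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per cancer type x endpoint: log-rank on the high/low split and Cox on
    the continuous score.

    Results carry raw and Benjamini-Hochberg-adjusted p-values (adjusted
    within each endpoint x test family) and a favorable (hr < 1) /
    adverse (hr > 1) direction label.  Skipped strata are returned in the
    skip log, and the scan continues past them.
    """
    tumor = ann[ann["tissue"] == "tumor"]
    rows = []
    skips: dict[str, str] = {}
    for st in sorted(tumor["cancer_type"].unique()):
        ids = tumor.index[tumor["cancer_type"] == st].intersection(scores.index)
        sub = tumor.loc[ids]
        vals = scores.loc[ids, score_col]
        try:
            groups = split_groups(scores.rename(columns={score_col: "ppi"}),
                                  ann, rule=rule, stratum=st)
        except StratumSkipped as exc:
            skips[f"{st}"] = str(exc)
            continue
        for ep in endpoints:
            tcol, ecol = f"{ep}_time", f"{ep}_event"
            if tcol not in sub.columns:
                skips[f"{st}/{ep}"] = "endpoint columns absent"
                continue
            keep = sub[tcol].notna() & sub[ecol].notna()
            ids_ep = sub.index[keep]
            t = sub.loc[ids_ep, tcol].to_numpy(dtype=float)
            e = sub.loc[ids_ep, ecol].to_numpy(dtype=int)
            if e.sum() == 0:
                skips[f"{st}/{ep}"] = "no events"
                continue
            g_ids = groups.index.intersection(ids_ep)
            lr = logrank_test(
                sub.loc[g_ids, tcol].to_numpy(dtype=float),
                sub.loc[g_ids, ecol].to_numpy(dtype=int),
                groups.loc[g_ids, "group"].to_numpy(),
            )
            try:
                cox = cox_univariate(t, e, vals.loc[ids_ep].to_numpy(dtype=float))
            except ValueError as exc:
                skips[f"{st}/{ep}/cox"] = str(exc)
                cox = None
            rows.append({
                "stratum": st, "endpoint": ep.upper(), "rule": rule,
                "n": lr.n, "n_events": lr.n_events,
                "logrank_chi2": lr.chi2, "logrank_p": lr.p,
                "hr": cox.hr if cox else float("nan"),
                "hr_lower": cox.hr_lower if cox else float("nan"),
                "hr_upper": cox.hr_upper if cox else float("nan"),
                "cox_p": cox.p if cox else float("nan"),
                "direction": (
                    "" if cox is None or not np.isfinite(cox.hr)
                    else ("adverse" if cox.hr > 1 else "favorable")
                ),
            })
    result = pd.DataFrame(rows)
    if len(result):
        for col in ("logrank_p", "cox_p"):
            adj = np.full(len(result), np.nan)
            for ep in result["endpoint"].unique():
                m = (result["endpoint"] == ep) & result[col].notna()
                if m.sum():
                    adj[m.to_numpy()] = multipletests(
                        result.loc[m, col], method="fdr_bh")[1]
            result[col.replace("_p", "_p_bh")] = adj
        result["significant"] = result["logrank_p"] < 0.05
    return result, skips


# ---------------------------------------------------------------------------
# clinical associations


def clinical_association(
    ppi: pd.DataFrame,
    ann: pd.DataFrame,
    variable: str,
    stratum: str | None = None,
    groups: pd.DataFrame | None = None,
) -> dict:
    """Association between PPI and a categorical clinical variable.

    Two levels: Wilcoxon rank-sum on PPI; more: Kruskal-Wallis.  If a
    high/low group assignment is supplied, additionally a chi-square test
    (no continuity correction) of group x category.  Missing category
    values are dropped.
    """
    sub = ann if stratum is None else ann[ann["cancer_type"] == stratum]
    sub = sub[sub["tissue"] == "tumor"]
    ids = sub.index.intersection(ppi.index)
    cat = sub.loc[ids, variable].dropna()
    levels = sorted(cat.unique())
    if len(levels) < 2:
        raise StratumSkipped(
            f"variable {variable!r} has {len(levels)} non-missing level(s)"
        )
    vals = ppi.loc[cat.index, "ppi"]
    out: dict = {"variable": variable, "stratum": stratum or "pan",
                 "levels": levels, "n": len(cat)}
    by_level = [vals[cat == lv].to_numpy() for lv in levels]
    if len(levels) == 2:
        w, p = _mannwhitney(by_level[0], by_level[1])
        out.update(test="wilcoxon_rank_sum", statistic=w, p=p)
    else:
        h, p = stats.kruskal(*by_level)
        out.update(test="kruskal_wallis", statistic=float(h), p=float(p))
    out["medians"] = {lv: float(np.median(v)) for lv, v in zip(levels, by_level)}
    if groups is not None:
        common = cat.index.intersection(groups.index)
        table = pd.crosstab(groups.loc[common, "group"], cat.loc[common])
        if table.to_numpy().sum() and (table.to_numpy().sum(axis=0) > 0).all() \
                and table.shape[0] == 2:
            chi2, chi_p, dof, _ = stats.chi2_contingency(table, correction=False)
            out.update(chi2=float(chi2), chi2_p=float(chi_p), chi2_dof=int(dof))
        else:
            out["chi2_skipped"] = "degenerate contingency table"
    return out
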