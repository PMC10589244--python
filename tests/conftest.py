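import numpy as np
import pandas as pd
import pytest

from pyroppi.catalog import GeneSet, packaged_prg_catalog
from pyroppi.simulate import worked_fixture


@pytest.fixture(scope="session")
def fixture_cohort():
    return worked_fixture()


@pytest.fixture(scope="session")
def prg_catalog():
    return packaged_prg_catalog()


def random_expression(rng, n_genes, n_samples):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    values = rng.normal(5.0, 2.0, size=(n_genes, n_samples))
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=samples)


def random_gene_set(rng, genes, k, name="set"):
    members = rng.choice(list(genes), size=k, replace=False)
    return GeneSet(name=name, members=frozenset(members))


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive, kept apart from the library code)


def brute_force_ssgsea(values: np.ndarray, member_mask: np.ndarray,
                       alpha: float) -> float:
    """Literal transcription of the ssGSEA running sum: rank, walk genes in
    decreasing rank order, accumulate P_in - P_out step by step."""
    from scipy.stats import rankdata

    ranks = rankdata(values, method="average")
    order = sorted(range(len(values)), key=lambda i: (-ranks[i], i))
    in_flags = [bool(member_mask[i]) for i in order]
    r_sorted = [ranks[i] for i in order]
    n = len(values)
    k = sum(in_flags)
    denom = sum(r ** alpha for r, f in zip(r_sorted, in_flags) if f)
    es = 0.0
    p_in = p_out = 0.0
    for i in range(n):
        if in_flags[i]:
            p_in += r_sorted[i] ** alpha / denom
        else:
            p_out += 1.0 / (n - k)
        es += p_in - p_out
    return es


def brute_force_gsea_es(metric_desc, hit_flags, p=1.0):
    """Step-by-step weighted KS running sum; ES = signed max deviation."""
    n = len(metric_desc)
    k = sum(hit_flags)
    denom = sum(abs(m) ** p for m, h in zip(metric_desc, hit_flags) if h)
    running, walk = 0.0, []
    for m, h in zip(metric_desc, hit_flags):
        if h:
            running += (abs(m) ** p / denom) if denom > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        walk.append(running)
    m_pos = max(max(walk), 0.0)
    m_neg = min(min(walk), 0.0)
    return m_pos if m_pos >= -m_neg else m_neg


def enumerate_ranksum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all C(n, k) group splits."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, k = len(pooled), len(x)
    obs = ranks[:k].sum()
    center = k * (n + 1) / 2.0
    count = total = 0
    for idx in combinations(range(n), k):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - center) >= abs(obs - center) - 1e-12:
            count += 1
    return count / total


def enumerate_signed_rank_p(diffs):
    """Exact two-sided signed-rank p over all 2^n sign assignments."""
    from itertools import product

    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    center = ranks.sum() / 2.0
    count = total = 0
    for signs in product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - center) >= abs(w_plus - center) - 1e-12:
            count += 1
    return count / total


def logrank_chi2_oracle(times, events, groups):
    """Observed-minus-expected log-rank tally, one 2x2 table per event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    o_minus_e = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_total = at_risk.sum()
        d_total = ((times == t) & (events == 1)).sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        e1 = d_total * n1 / n_total
        o_minus_e += d1 - e1
        if n_total > 1:
            var += (d_total * (n1 / n_total) * (1 - n1 / n_total)
                    * (n_total - d_total) / (n_total - 1))
    return o_minus_e ** 2 / var
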