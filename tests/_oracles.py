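"""Independent brute-force oracles shared across test modules.

These deliberately re-derive quantities from first principles (exhaustive
summation / enumeration) and stay independent of the implementations they
check.
"""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats


def make_adata(X, genes, samples=None, cells=None):
    X = np.asarray(X, dtype=float)
    obs = pd.DataFrame(index=cells or [f"c{i}" for i in range(X.shape[0])])
    obs["sample_id"] = samples if samples is not None else "S1"
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=list(genes)))


def auc_oracle(member_ranks, K, m):
    """Exhaustive recovery-curve summation: sum_k c(k) / sum_k min(k, m)."""
    num = sum(sum(1 for r in member_ranks if r <= k) for k in range(1, K + 1))
    den = sum(min(k, m) for k in range(1, K + 1))
    return num / den


def mw_enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = np.asarray(list(x) + list(y), dtype=float)
    n = len(x)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n * (n + 1) / 2.0

    us = np.array([u_of(c) for c in itertools.combinations(range(len(pooled)), n)])
    u_obs = u_of(range(n))
    lo = (us <= u_obs).mean()
    hi = (us >= u_obs).mean()
    return min(1.0, 2.0 * min(lo, hi))


def welch_oracle(a, b):
    """Textbook Welch formula assembled from first principles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p, df
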