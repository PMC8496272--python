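"""Cross-repeat correlation of directional change rates.

Rows are lines, columns are repeat classes (common simple units plus the
complex satellites); values are signed normalized change rates.  Pairwise
correlations over the c(c-1)/2 unordered column pairs reveal co-evolving
repeats: strong positive pairs are typically sequence-similar or physically
nested units, while broadly negative columns suggest copy-number tradeoffs.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def correlation_matrix(
    rates: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations and two-sided p-values between rate columns.

    Zero-variance columns are dropped with a warning; fewer than 3 complete
    rows is an error.  Returns (corr, pvals) with unit diagonals / NaN
    p-value diagonals; only the c(c-1)/2 off-diagonal unordered pairs are
    meaningful.
    """
    df = rates.dropna(axis=0, how="any")
    if len(df) < 3:
        raise ValueError(f"need >= 3 complete rows, got {len(df)}")
    variances = df.var(axis=0)
    dead = list(variances.index[variances == 0])
    if dead:
        logger.warning("dropping zero-variance columns: %s", dead)
        df = df.drop(columns=dead)
    cols = list(df.columns)
    c = len(cols)
    corr = pd.DataFrame(np.eye(c), index=cols, columns=cols)
    pvals = pd.DataFrame(np.full((c, c), np.nan), index=cols, columns=cols)
    test = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    for a, b in combinations(cols, 2):
        r, p = test(df[a].to_numpy(float), df[b].to_numpy(float))
        corr.at[a, b] = corr.at[b, a] = float(r)
        pvals.at[a, b] = pvals.at[b, a] = float(p)
    return corr, pvals


def n_pairs(n_columns: int) -> int:
    """Number of unordered column pairs, c(c-1)/2."""
    return n_columns * (n_columns - 1) // 2


def classify_pairs(
    corr: pd.DataFrame,
    pvals: pd.DataFrame,
    alpha: float = 0.05,
    strong_pos: float = 0.95,
    strong_neg: float = -0.5,
    bh_correct: bool = False,
) -> dict:
    """Counts and lists of significant / strong correlation pairs.

    Returns a dict with: n_pairs, n_significant, n_significant_positive,
    n_significant_negative, strong_positive_pairs (cor >= strong_pos), and
    strong_negative_partners (per column, count of partners with
    cor < strong_neg and p < alpha).  ``bh_correct`` applies
    Benjamini-Hochberg to the pair p-values first.
    """
    cols = list(corr.columns)
    pairs = list(combinations(cols, 2))
    r = np.array([corr.at[a, b] for a, b in pairs])
    p = np.array([pvals.at[a, b] for a, b in pairs])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    sig = p < alpha
    strong_positive = [
        (a, b, float(corr.at[a, b]))
        for (a, b), ri in zip(pairs, r)
        if ri >= strong_pos
    ]
    neg_partners: dict[str, int] = {col: 0 for col in cols}
    for (a, b), ri, si in zip(pairs, r, sig):
        if ri < strong_neg and si:
            neg_partners[a] += 1
            neg_partners[b] += 1
    return {
        "n_pairs": len(pairs),
        "n_significant": int(sig.sum()),
        "n_significant_positive": int((sig & (r > 0)).sum()),
        "n_significant_negative": int((sig & (r < 0)).sum()),
        "strong_positive_pairs": strong_positive,
        "strong_negative_partners": {
            col: n for col, n in neg_partners.items() if n > 0
        },
    }


def build_rate_matrix(
    simple_rates: pd.DataFrame, satellite_rates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pivot tidy rate tables into a lines x repeat-classes matrix.

    Expects the tidy output of branch_rates (columns line, unit,
    normalized); satellite rates are appended as extra columns.
    """
    m = simple_rates.pivot(index="line", columns="unit", values="normalized")
    if satellite_rates is not None:
        s = satellite_rates.pivot(index="line", columns="unit", values="normalized")
        overlap = set(m.columns) & set(s.columns)
        if overlap:
            raise ValueError(f"duplicated repeat classes: {sorted(overlap)}")
        m = m.join(s)
    m.columns.name = None
    return m
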