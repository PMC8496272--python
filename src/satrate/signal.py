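"""Phylogenetic signal in repeat copy numbers.

Two complementary detectors:

* Blomberg's K with a tip-label permutation test.  K compares the observed
  ratio of (variance about the phylogenetic mean) to (variance after
  whitening by the Brownian-motion tree covariance) against its expectation
  under BM; K is approximately 1 for a trait evolving by BM on the tree,
  smaller when closely related lines are no more similar than distant ones.

* A randomized-ancestor outlier test: each tip's ancestral copy number is
  replaced by the reconstructed state of a randomly chosen internal node
  and the mean signed change rate across tips is recomputed.  Without
  phylogenetic structure, mean rates under the correct and randomized
  ancestors are alike across units; units whose observed mean rate is in
  the extreme tail of the randomized distribution carry signal (the
  clade-partitioned case — hundreds of copies in one clade, near zero in
  the other — is the canonical example).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .phylogeny import GenerationTree, ancestral_bm, branch_rates


def _k_stat(Cm: np.ndarray, Cinv: np.ndarray, x: np.ndarray) -> float:
    n = x.size
    ones = np.ones(n)
    sum_cinv = float(ones @ Cinv @ ones)
    ahat = float(ones @ Cinv @ x) / sum_cinv
    d = x - ahat
    mse0 = float(d @ d) / (n - 1)
    mse = float(d @ Cinv @ d) / (n - 1)
    expected = (np.trace(Cm) - n / sum_cinv) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: GenerationTree, values: pd.Series) -> float:
    """Blomberg's K for one unit's tip values; NaN for constant values."""
    C = tree.vcv()
    x = values.loc[C.index].to_numpy(float)
    if np.allclose(x, x[0]):
        return float("nan")
    Cm = C.to_numpy(float)
    return _k_stat(Cm, np.linalg.inv(Cm), x)


def blomberg_k_test(
    tree: GenerationTree,
    values: pd.Series,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """(K, permutation p-value) by shuffling tip labels ``n_perm`` times.

    p = (1 + #{K_perm >= K_obs}) / (n_perm + 1); deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = tree.vcv()
    x = values.loc[C.index].to_numpy(float)
    if np.allclose(x, x[0]):
        return float("nan"), float("nan")
    Cm = C.to_numpy(float)
    Cinv = np.linalg.inv(Cm)
    k_obs = _k_stat(Cm, Cinv, x)
    exceed = 0
    for _ in range(n_perm):
        if _k_stat(Cm, Cinv, rng.permutation(x)) >= k_obs:
            exceed += 1
    return k_obs, (1 + exceed) / (n_perm + 1)


def randomized_ancestor_test(
    tree: GenerationTree,
    tip_values: pd.DataFrame,
    n_rand: int = 200,
    seed: int | np.random.Generator = 0,
    null_fpr: float = 0.01,
    include_true_parent: bool = False,
    min_ancestor_copies: float = 1.0,
) -> pd.DataFrame:
    """Randomized-ancestor outlier scan over all units.

    Each tip's ancestor is replaced by the reconstructed state of a random
    internal node (excluding the tip's true parent unless
    ``include_true_parent``) and the mean signed normalized rate across
    tips is recorded; a unit's statistic is that mean averaged over
    ``n_rand`` replicates.  Without signal the statistic is similar across
    units; a unit is flagged when its statistic is a robust outlier
    (|statistic - median| beyond the two-sided normal quantile for
    ``null_fpr`` in MAD units) — clade-partitioned units produce extreme
    rates against other-clade ancestors and stand far outside the pack.

    Columns: unit, rand_mean, true_mean (rates against the true parents),
    robust_z, manual_flag.  Deterministic per seed.
    """
    internal = tree.internal_labels
    if len(internal) < 2:
        raise ValueError("randomized-ancestor test needs >= 2 internal nodes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ancestors = ancestral_bm(tree, tip_values)
    obs = branch_rates(tree, tip_values, ancestors=ancestors,
                       min_ancestor_copies=min_ancestor_copies)
    true_mean = obs.groupby("unit")["normalized"].mean()

    tips = tree.tips
    units = list(tip_values.columns)
    G = np.array([tree.terminal_branch(t)[1] for t in tips])
    true_parent = [tree.terminal_branch(t)[0] for t in tips]
    anc_internal = ancestors.loc[internal].to_numpy(float)  # internal x unit
    tip_mat = tip_values.loc[tips].to_numpy(float)
    choice_sets = [
        [j for j, lab in enumerate(internal) if include_true_parent or lab != tp]
        for tp in true_parent
    ]

    rand_means = np.empty((n_rand, len(units)))
    for r in range(n_rand):
        rows = np.array([cs[rng.integers(len(cs))] for cs in choice_sets])
        A = anc_internal[rows]  # tips x units
        with np.errstate(invalid="ignore", divide="ignore"):
            u = (tip_mat - A) / G[:, None]
            norm = np.where(A >= min_ancestor_copies, u / A, np.nan)
        with np.errstate(invalid="ignore"):
            rand_means[r] = np.nanmean(norm, axis=0)
    with np.errstate(invalid="ignore"):
        stat = np.nanmean(rand_means, axis=0)
    med = float(np.nanmedian(stat))
    mad = float(np.nanmedian(np.abs(stat - med)))
    scale = 1.4826 * mad
    z_crit = float(stats.norm.isf(null_fpr / 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (stat - med) / scale if scale > 0 else np.zeros_like(stat)
    out = pd.DataFrame({"unit": units})
    out["rand_mean"] = stat
    out["true_mean"] = true_mean.reindex(units).to_numpy()
    out["robust_z"] = z
    out["manual_flag"] = np.isfinite(z) & (np.abs(z) > z_crit) & (scale > 0)
    return out


def _clade_pattern(tree: GenerationTree, values: pd.Series) -> str:
    root = tree.root_index()
    kids = [i for i, p in enumerate(tree.parent) if p == root]
    parts = []
    children = tree.children_map()
    for k in kids:
        stack, members = [k], []
        while stack:
            j = stack.pop()
            if tree.is_tip[j]:
                members.append(tree.labels[j])
            stack.extend(children[j])
        parts.append((tree.labels[k], float(values.loc[members].mean())))
    parts.sort(key=lambda t: -t[1])
    return "; ".join(f"clade {lab}: mean {m:.4g}" for lab, m in parts)


def signal_scan(
    tree: GenerationTree,
    tip_values: pd.DataFrame,
    n_perm: int = 1000,
    n_rand: int = 200,
    seed: int = 0,
    null_fpr: float = 0.01,
) -> pd.DataFrame:
    """Run both detectors over all units.

    Columns: unit, K, p_perm, manual_flag, rand_mean, clade_pattern.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    manual = randomized_ancestor_test(
        tree, tip_values, n_rand=n_rand, seed=rng, null_fpr=null_fpr
    ).set_index("unit")
    rows = []
    for unit in tip_values.columns:
        k, p = blomberg_k_test(tree, tip_values[unit], n_perm=n_perm, seed=rng)
        flagged = bool(manual.at[unit, "manual_flag"])
        rows.append(
            {
                "unit": unit,
                "K": k,
                "p_perm": p,
                "manual_flag": flagged,
                "rand_mean": float(manual.at[unit, "rand_mean"]),
                "clade_pattern": _clade_pattern(tree, tip_values[unit]) if flagged else "",
            }
        )
    return pd.DataFrame(rows)
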