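"""Generation-scaled phylogeny, Brownian-motion ancestral states, and rates.

The mutation-accumulation design treats each inbred line as an independent
lineage; copy-number change per repeat unit is summarised per terminal
branch as

    u = (tip copies - ancestral copies) / G           [copies/generation]
    normalized = u / ancestral copies                 [copies/generation/copy]
    absolute = |u|

where the ancestral copy number at a tip's parent node is the
maximum-likelihood reconstruction under Brownian motion on the whole tree
(equivalently, the internal-node values minimising sum((dx)^2 / branch
length) over branches with tips held fixed).

Branch lengths are in generations.  Trees are built either from newick
(lengths already in generations) or from pedigree records of split ages in
years, converted at 4.33 generations/year.  The deep split between the two
clades is set from a config constant (the year-based estimate underestimates
it); that basal branch is used only to sharpen ancestral states, never as a
denominator G.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

GENERATIONS_PER_YEAR = 4.33
BASAL_SPLIT_GENERATIONS = 850.0


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def years_to_generations(years: float, per_year: float = GENERATIONS_PER_YEAR) -> int:
    """Convert a branch duration in years to whole generations (half-up)."""
    return round_half_up(years * per_year)


class GenerationTree:
    """Rooted phylogeny with branch lengths in generations.

    Nodes are indexed 0..n-1 in a parent-before-child order; ``parent[i]``
    is -1 for the root, ``length[i]`` the branch length from ``i`` to its
    parent (NaN at the root).  Tip labels are unique line names; internal
    nodes get stable synthetic labels unless named in the source tree.
    """

    def __init__(
        self,
        parent: np.ndarray,
        length: np.ndarray,
        labels: list[str],
        is_tip: np.ndarray,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        self.is_tip = np.asarray(is_tip, dtype=bool)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate node labels")
        nonroot = self.parent >= 0
        if np.any(self.length[nonroot] <= 0):
            bad = [self.labels[i] for i in np.nonzero(nonroot & (self.length <= 0))[0]]
            raise ValueError(f"non-positive branch lengths at: {bad}")
        if np.sum(~nonroot) != 1:
            raise ValueError("tree must have exactly one root")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "GenerationTree":
        nodes = list(tree.preorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        length = np.full(len(nodes), np.nan)
        labels: list[str] = []
        is_tip = np.zeros(len(nodes), dtype=bool)
        internal = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = idx[id(nd.parent_node)]
                length[i] = nd.edge.length if nd.edge.length is not None else np.nan
            if nd.is_leaf():
                is_tip[i] = True
                labels.append(nd.taxon.label if nd.taxon else f"tip{i}")
            else:
                lab = nd.label or f"node{internal}"
                internal += 1
                labels.append(lab)
        return cls(parent, length, labels, is_tip)

    @classmethod
    def from_newick(cls, newick: str) -> "GenerationTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def from_newick_file(cls, path) -> "GenerationTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        children = self.children_map()

        def render(i: int) -> str:
            if self.is_tip[i]:
                body = self.labels[i]
            else:
                body = "(" + ",".join(render(c) for c in children[i]) + ")" + self.labels[i]
            if self.parent[i] >= 0:
                body += f":{self.length[i]:.10g}"
            return body

        return render(self.root_index()) + ";"

    # -- accessors ----------------------------------------------------------

    def root_index(self) -> int:
        return int(np.nonzero(self.parent < 0)[0][0])

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def tips(self) -> list[str]:
        return [lab for lab, t in zip(self.labels, self.is_tip) if t]

    @property
    def internal_labels(self) -> list[str]:
        return [lab for lab, t in zip(self.labels, self.is_tip) if not t]

    def index(self, label: str) -> int:
        return self._index[label]

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def terminal_branch(self, tip: str) -> tuple[str, float]:
        """(parent node label, branch length in generations) for a tip."""
        i = self.index(tip)
        if not self.is_tip[i]:
            raise ValueError(f"{tip!r} is not a tip")
        return self.labels[self.parent[i]], float(self.length[i])

    def set_basal_split(self, total_generations: float = BASAL_SPLIT_GENERATIONS) -> None:
        """Set the root split to ``total_generations`` of separation.

        The root's child branches are assigned equal shares so the path
        between the two clades across the root equals the given total.
        """
        root = self.root_index()
        kids = [i for i, p in enumerate(self.parent) if p == root]
        if not kids:
            raise ValueError("root has no children")
        for k in kids:
            self.length[k] = total_generations / len(kids)

    def vcv(self) -> pd.DataFrame:
        """Brownian-motion covariance among tips: shared path length to root."""
        order = list(range(self.n_nodes))
        depth = np.zeros(self.n_nodes)
        for i in order:
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.length[i]
        tips = [i for i in order if self.is_tip[i]]
        # ancestor chains
        chains = []
        for t in tips:
            chain = set()
            j = t
            while j >= 0:
                chain.add(j)
                j = self.parent[j]
            chains.append(chain)
        n = len(tips)
        C = np.zeros((n, n))
        for a in range(n):
            for b in range(a, n):
                shared = chains[a] & chains[b]
                # depth of the MRCA = max depth among shared ancestors
                C[a, b] = C[b, a] = max(depth[j] for j in shared)
        labels = [self.labels[t] for t in tips]
        return pd.DataFrame(C, index=labels, columns=labels)


def build_tree(
    records: pd.DataFrame | None = None,
    newick: str | None = None,
    generations_per_year: float = GENERATIONS_PER_YEAR,
    basal_split_generations: float | None = BASAL_SPLIT_GENERATIONS,
) -> GenerationTree:
    """Build the generation-scaled tree from pedigree records or newick.

    ``records`` columns: child, parent, split_years_ago — the age (years
    before present) of the divergence node ``parent`` at which ``child``
    split off.  Tips have age 0; branch years = age(parent) - age(child),
    converted at ``generations_per_year`` and rounded half-up to whole
    generations.  Inconsistent records (a parent younger than its child)
    are rejected, not silently fixed.  Newick input passes through
    unchanged except for the basal-split override.
    """
    if (records is None) == (newick is None):
        raise ValueError("provide exactly one of records or newick")
    if newick is not None:
        tree = GenerationTree.from_newick(newick)
    else:
        required = {"child", "parent", "split_years_ago"}
        if not required <= set(records.columns):
            raise ValueError(f"pedigree records need columns {sorted(required)}")
        age: dict[str, float] = {}
        parent_of: dict[str, str] = {}
        for row in records.itertuples(index=False):
            parent_of[row.child] = row.parent
            prior = age.get(row.parent)
            if prior is not None and not math.isclose(prior, row.split_years_ago):
                raise ValueError(
                    f"inconsistent ages for node {row.parent!r}: "
                    f"{prior} vs {row.split_years_ago}"
                )
            age[row.parent] = float(row.split_years_ago)
        children = sorted(parent_of)
        parents = set(parent_of.values())
        roots = sorted(parents - set(children))
        if len(roots) != 1:
            raise ValueError(f"records imply {len(roots)} roots: {roots}")
        nodes = roots + [c for c in children]
        # parent-before-child order
        ordered: list[str] = []
        pending = set(nodes)
        while pending:
            progressed = False
            for nd in sorted(pending):
                if nd in roots or parent_of[nd] in ordered:
                    ordered.append(nd)
                    pending.discard(nd)
                    progressed = True
            if not progressed:
                raise ValueError("pedigree records contain a cycle")
        idx = {nd: i for i, nd in enumerate(ordered)}
        n = len(ordered)
        parent = np.full(n, -1, dtype=int)
        length = np.full(n, np.nan)
        is_tip = np.array([nd not in parents for nd in ordered])
        for nd in ordered:
            if nd in roots:
                continue
            p = parent_of[nd]
            child_age = age.get(nd, 0.0)
            years = age[p] - child_age
            if years <= 0:
                raise ValueError(
                    f"non-ultrametric record: node {nd!r} (age {child_age}) "
                    f"older than its parent {p!r} (age {age[p]})"
                )
            parent[idx[nd]] = idx[p]
            length[idx[nd]] = years_to_generations(years, generations_per_year)
        tree = GenerationTree(parent, length, ordered, is_tip)
    if basal_split_generations is not None:
        tree.set_basal_split(basal_split_generations)
    return tree


# ---------------------------------------------------------------------------
# ancestral reconstruction


def ancestral_bm(tree: GenerationTree, tip_values: pd.DataFrame) -> pd.DataFrame:
    """ML ancestral states under Brownian motion for every unit.

    ``tip_values``: DataFrame indexed by tip label, one column per unit.
    Returns a DataFrame over all node labels (tips carry their observed
    values exactly).  States are the minimisers of
    sum over branches of (state difference)^2 / branch length,
    obtained by solving the induced linear system on internal nodes.
    Reconstructions are not clamped at zero; near-zero ancestors are the
    caller's concern (normalized rates are reported NA below 1 copy).
    """
    missing = [t for t in tree.tips if t not in tip_values.index]
    if missing:
        raise ValueError(f"missing tip values for: {missing}")
    n = tree.n_nodes
    w = np.zeros(n)
    nonroot = tree.parent >= 0
    w[nonroot] = 1.0 / tree.length[nonroot]
    L = np.zeros((n, n))
    for i in np.nonzero(nonroot)[0]:
        p = tree.parent[i]
        L[i, i] += w[i]
        L[p, p] += w[i]
        L[i, p] -= w[i]
        L[p, i] -= w[i]
    tip_idx = np.nonzero(tree.is_tip)[0]
    int_idx = np.nonzero(~tree.is_tip)[0]
    X_T = tip_values.loc[[tree.labels[i] for i in tip_idx]].to_numpy(float)
    A = L[np.ix_(int_idx, int_idx)]
    B = L[np.ix_(int_idx, tip_idx)]
    X_I = np.linalg.solve(A, -B @ X_T)
    out = np.zeros((n, X_T.shape[1]))
    out[tip_idx] = X_T
    out[int_idx] = X_I
    return pd.DataFrame(out, index=tree.labels, columns=tip_values.columns)


# ---------------------------------------------------------------------------
# rates


@dataclass(frozen=True)
class RateRecord:
    """Copy-number change rates on one terminal branch for one unit."""

    line: str
    unit: str
    directional_rate: float  # copies/generation, signed
    normalized_rate: float  # copies/generation/copy; NaN when ancestor < 1
    absolute_rate: float
    generations: float
    ancestor: float


def branch_rates(
    tree: GenerationTree,
    tip_values: pd.DataFrame,
    ancestors: pd.DataFrame | None = None,
    min_ancestor_copies: float = 1.0,
) -> pd.DataFrame:
    """Per-(line, unit) directional/normalized/absolute change rates.

    Columns: line, unit, u, normalized, absolute, G, ancestor.  The
    normalized rate is NaN where the reconstructed ancestor is below
    ``min_ancestor_copies``.
    """
    if ancestors is None:
        ancestors = ancestral_bm(tree, tip_values)
    rows = []
    for tip in tree.tips:
        parent_label, G = tree.terminal_branch(tip)
        if G <= 0:
            raise ValueError(f"non-positive branch length at tip {tip!r}")
        for unit in tip_values.columns:
            anc = float(ancestors.at[parent_label, unit])
            u = (float(tip_values.at[tip, unit]) - anc) / G
            norm = u / anc if anc >= min_ancestor_copies else np.nan
            rows.append((tip, unit, u, norm, abs(u), G, anc))
    return pd.DataFrame(
        rows, columns=["line", "unit", "u", "normalized", "absolute", "G", "ancestor"]
    )


def sign_test(n_gain: int, n_loss: int) -> float:
    """Two-sided exact binomial sign test against p=0.5; zeros excluded."""
    n = n_gain + n_loss
    if n == 0:
        return float("nan")
    return float(stats.binomtest(n_gain, n, 0.5, alternative="two-sided").pvalue)


def per_line_summary(rates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-line mean rates, gain/loss counts and sign-test p-values.

    A line is "skewed" (hypermutator candidate) when the exact binomial
    sign test on gains vs losses rejects 50:50 at ``alpha``.
    """
    rows = []
    for line, grp in rates.groupby("line", sort=True):
        u = grp["u"].to_numpy(float)
        norm = grp["normalized"].to_numpy(float)
        n_gain = int((u > 0).sum())
        n_loss = int((u < 0).sum())
        n_zero = int((u == 0).sum())
        p = sign_test(n_gain, n_loss)
        rows.append(
            {
                "line": line,
                "mean_normalized": float(np.nanmean(norm)) if np.isfinite(norm).any() else np.nan,
                "mean_abs_normalized": float(np.nanmean(np.abs(norm)))
                if np.isfinite(norm).any()
                else np.nan,
                "n_gain": n_gain,
                "n_loss": n_loss,
                "n_zero": n_zero,
                "sign_p": p,
                "skewed": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)


def per_unit_summary(rates: pd.DataFrame) -> pd.DataFrame:
    """Per-unit distribution of normalized rates across lines, ranked.

    Rank 1 = highest mean absolute normalized rate (the fastest-changing
    unit); stable units rank last.
    """
    rows = []
    for unit, grp in rates.groupby("unit", sort=True):
        norm = grp["normalized"].to_numpy(float)
        ok = np.isfinite(norm)
        if ok.any():
            v = norm[ok]
            rows.append(
                {
                    "unit": unit,
                    "mean": float(v.mean()),
                    "median": float(np.median(v)),
                    "min": float(v.min()),
                    "max": float(v.max()),
                    "mean_abs": float(np.abs(v).mean()),
                    "n_lines": int(ok.sum()),
                }
            )
        else:
            rows.append(
                {
                    "unit": unit,
                    "mean": np.nan,
                    "median": np.nan,
                    "min": np.nan,
                    "max": np.nan,
                    "mean_abs": np.nan,
                    "n_lines": 0,
                }
            )
    df = pd.DataFrame(rows)
    df["rank"] = (
        df["mean_abs"].rank(ascending=False, method="min", na_option="bottom").astype(int)
    )
    return df.sort_values("rank").reset_index(drop=True)
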