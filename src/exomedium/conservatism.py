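"""Phylogenetic niche conservatism of metabolite utilization.

Relates how similar two isolates' exometabolite profiles are to how closely
related the isolates themselves are. Profile distance is the Euclidean
distance between log2 fold-change vectors; phylogenetic distance is the
patristic distance (sum of branch lengths on the leaf-to-leaf path) on a
rooted tree with branch lengths. The association is summarized by an
ordinary least-squares fit and a Spearman correlation over the
upper-triangle distance pairs; because those pairs are not independent, the
attached significance comes from a seeded Mantel-style permutation of one
matrix's labels, not from the regression.

A complementary group-level test asks whether isolates that share a
taxonomic label (family, genus) have more similar utilization profiles than
isolates that do not, by rank-sum comparison of within-group versus
between-group pairwise Spearman correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .exoprofile import FoldChangeMatrix


def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick tree (quoted labels, internal labels, polytomies ok)."""
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def _validate_tree(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # the root has no subtending branch
        if edge.length is None:
            raise ValueError(
                f"missing branch length above node {edge.head_node!r}; "
                "patristic distances need lengths on every edge"
            )
        if edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return labels


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf patristic distance matrix.

    Entry (i, j) is the sum of branch lengths on the unique path between
    leaves i and j: depth(i) + depth(j) - 2 depth(mrca). Computed by a
    single postorder pass that merges per-clade (leaf, distance-to-node)
    lists, crossing them at each internal node.
    """
    labels = _validate_tree(tree)
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    dist = np.zeros((n, n))
    below: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [(index[node.taxon.label], 0.0)]
            continue
        groups = []
        for child in node.child_nodes():
            length = child.edge.length or 0.0
            groups.append([(leaf, d + length) for leaf, d in below.pop(id(child))])
        for ga, gb in itertools.combinations(groups, 2):
            for i, di in ga:
                for j, dj in gb:
                    dist[i, j] = dist[j, i] = di + dj
        below[id(node)] = [pair for g in groups for pair in g]
    return pd.DataFrame(dist, index=labels, columns=labels)


def profile_distances(
    fc: FoldChangeMatrix | pd.DataFrame, pairwise_complete: bool = False
) -> pd.DataFrame:
    """Euclidean distances between isolate log2 fold-change profiles.

    With ``pairwise_complete``, each pair uses its shared unmasked
    metabolites, rescaled to the full metabolite count so distances stay
    comparable; otherwise any masked entry is an error.
    """
    if isinstance(fc, FoldChangeMatrix):
        values, masked = fc.log2, fc.masked
    else:
        values = fc
        masked = values.isna()
    isolates = list(values.columns)
    n_metab = len(values.index)
    if not pairwise_complete:
        if masked.to_numpy().any():
            raise ValueError(
                "fold-change matrix has masked entries; pass pairwise_complete=True"
            )
        arr = values.to_numpy(float).T
        from scipy.spatial.distance import pdist, squareform

        return pd.DataFrame(
            squareform(pdist(arr, metric="euclidean")), index=isolates, columns=isolates
        )
    dist = np.zeros((len(isolates), len(isolates)))
    for a, b in itertools.combinations(range(len(isolates)), 2):
        ok = ~(masked.iloc[:, a] | masked.iloc[:, b])
        k = int(ok.sum())
        if k == 0:
            raise ValueError(
                f"isolates {isolates[a]!r} and {isolates[b]!r} share no unmasked metabolites"
            )
        diff = values.loc[ok, isolates[a]] - values.loc[ok, isolates[b]]
        dist[a, b] = dist[b, a] = float(np.sqrt((diff**2).sum() * (n_metab / k)))
    return pd.DataFrame(dist, index=isolates, columns=isolates)


def _check_square(m: pd.DataFrame, name: str) -> None:
    arr = m.to_numpy(float)
    if arr.shape[0] != arr.shape[1] or list(m.index) != list(m.columns):
        raise ValueError(f"{name} must be square with matching labels")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")


@dataclass(frozen=True)
class AssociationResult:
    """OLS fit and Spearman rho over distance pairs, with a Mantel p."""

    slope: float
    intercept: float
    rho: float
    p_value: float
    n_pairs: int
    n_perm: int
    seed: int


def distance_association(
    phylo: pd.DataFrame,
    profile: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> AssociationResult:
    """Association between phylogenetic and profile distance matrices.

    Least squares (profile on phylo) and Spearman rho over the n(n-1)/2
    upper-triangle pairs; the one-sided p comes from ``n_perm`` seeded
    permutations of one matrix's labels:
    ``p = (#{perm rho >= observed} + 1) / (n_perm + 1)``.
    """
    _check_square(phylo, "phylo")
    _check_square(profile, "profile")
    if set(phylo.index) != set(profile.index):
        raise ValueError("distance matrices have mismatched labels")
    if len(phylo) < 4:
        raise ValueError("need at least 4 taxa for a meaningful permutation test")
    profile = profile.loc[phylo.index, phylo.columns]
    x_mat = phylo.to_numpy(float)
    y_mat = profile.to_numpy(float)
    n = x_mat.shape[0]
    iu = np.triu_indices(n, k=1)
    x, y = x_mat[iu], y_mat[iu]
    slope, intercept = np.polyfit(x, y, 1)
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = y_mat[np.ix_(perm, perm)][iu]
        if stats.spearmanr(x, y_perm).statistic >= rho:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return AssociationResult(
        slope=float(slope), intercept=float(intercept), rho=rho, p_value=p,
        n_pairs=len(x), n_perm=n_perm, seed=seed,
    )


def pairwise_profile_correlations(
    fc: FoldChangeMatrix | pd.DataFrame, min_shared: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman correlations between isolate fold-change profiles.

    Returns (rho matrix, Bonferroni-adjusted p matrix); adjusted
    p = min(1, p x number of pairs). Pairs with fewer than ``min_shared``
    shared unmasked metabolites, or a constant profile (undefined rho), are
    left NaN.
    """
    if isinstance(fc, FoldChangeMatrix):
        values, masked = fc.log2, fc.masked
    else:
        values, masked = fc, fc.isna()
    isolates = list(values.columns)
    m = len(isolates)
    n_pairs = m * (m - 1) // 2
    rho = pd.DataFrame(np.nan, index=isolates, columns=isolates)
    padj = pd.DataFrame(np.nan, index=isolates, columns=isolates)
    np.fill_diagonal(rho.values, 1.0)
    for a, b in itertools.combinations(isolates, 2):
        ok = ~(masked[a] | masked[b])
        if int(ok.sum()) < min_shared:
            continue
        xa, xb = values.loc[ok, a], values.loc[ok, b]
        if xa.nunique() < 2 or xb.nunique() < 2:
            continue  # constant profile: rho undefined
        res = stats.spearmanr(xa, xb)
        rho.loc[a, b] = rho.loc[b, a] = float(res.statistic)
        p = min(1.0, float(res.pvalue) * n_pairs)
        padj.loc[a, b] = padj.loc[b, a] = p
    return rho, padj


@dataclass(frozen=True)
class GroupConservatismResult:
    """One-sided within-vs-between rank-sum on pairwise profile correlations."""

    statistic: float
    p_value: float
    n_within: int
    n_between: int


def group_conservatism_test(
    fc: FoldChangeMatrix | pd.DataFrame, groups: dict[str, str]
) -> GroupConservatismResult:
    """Do same-group isolates have more similar profiles than cross-group ones?

    Pairwise Spearman correlations are split into within-group and
    between-group sets and compared by a one-sided rank-sum test
    (within > between).
    """
    rho, _ = pairwise_profile_correlations(fc)
    isolates = [i for i in rho.columns if i in groups]
    if len(set(groups[i] for i in isolates)) < 2:
        raise ValueError("need at least 2 groups")
    within, between = [], []
    for a, b in itertools.combinations(isolates, 2):
        r = rho.loc[a, b]
        if np.isnan(r):
            continue
        (within if groups[a] == groups[b] else between).append(float(r))
    if not within:
        raise ValueError("no within-group pairs")
    if not between:
        raise ValueError("no between-group pairs")
    stat, p = stats.ranksums(within, between, alternative="greater")
    return GroupConservatismResult(
        statistic=float(stat), p_value=float(p), n_within=len(within), n_between=len(between)
    )


def cophenetic_distances(linkage: np.ndarray, labels: list[str]) -> pd.DataFrame:
    """Cophenetic distances from a hierarchical-clustering linkage.

    The dendrogram-based alternative to raw Euclidean profile distances for
    the association analysis.
    """
    from scipy.cluster.hierarchy import cophenet
    from scipy.spatial.distance import squareform

    coph = cophenet(linkage)
    return pd.DataFrame(squareform(coph), index=labels, columns=labels)


def read_groups(path) -> dict[str, str]:
    """Groups TSV (isolate, family[, genus]) -> isolate -> family mapping."""
    df = pd.read_csv(path, sep="\t")
    missing = {"isolate", "family"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["isolate"].astype(str), df["family"].astype(str)))
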