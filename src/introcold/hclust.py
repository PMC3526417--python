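"""Average-linkage hierarchical clustering with centered correlation distance.

This is the classic gene-expression clustering recipe: per-gene
median-centered log2 profiles, dissimilarity ``d = 1 - Pearson(a, b)``
(range [0, 2]), and UPGMA agglomeration where the distance between two
clusters is the unweighted mean of all cross-pair leaf distances.  Ties in
the minimum inter-cluster distance are broken by the lexicographically
smallest pair of lowest leaf indices, making the merge sequence
deterministic.  Cutting the tree at *k* removes the k-1 highest merges.

The linkage records use the scipy convention (left, right, height, size)
with new nodes numbered n, n+1, ... in merge order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import ExpressionMatrix
from .sam_test import ContractError


def correlation_distance(profile_a, profile_b) -> float:
    """Centered correlation distance, 1 - Pearson r; in [0, 2]."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ContractError("profiles must be equal-length 1-D with >= 3 points")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ContractError("correlation undefined for a constant profile")
    r = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return 1.0 - r


def _distance_matrix(P: np.ndarray) -> np.ndarray:
    centered = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if (norms == 0).any():
        i = int(np.flatnonzero(norms == 0)[0])
        raise ContractError(f"profile {i} is constant; correlation undefined")
    R = np.clip((centered @ centered.T) / np.outer(norms, norms), -1.0, 1.0)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class ClusterTree:
    """Linkage records plus leaf identifiers."""

    linkage: np.ndarray  # (n-1) x 4: left, right, height, size
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def agglomerate_average(profiles, leaf_ids: list[str] | None = None) -> ClusterTree:
    """UPGMA tree over row profiles with correlation distance.

    The inter-cluster distance update uses the exact unweighted-mean
    (Lance-Williams average) recurrence, equivalent to averaging all
    cross-pair leaf distances.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ContractError("need >= 2 profiles")
    n = P.shape[0]
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    Dm = _distance_matrix(P).astype(float)
    np.fill_diagonal(Dm, np.inf)

    # slot bookkeeping: node id, cluster size, lowest original leaf index
    node_of = np.arange(n)
    size = np.ones(n, dtype=int)
    lowleaf = np.arange(n)
    alive = np.ones(n, dtype=bool)

    linkage = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best_d = Dm.min()
        # deterministic tie-breaking: lexicographically smallest pair of
        # lowest member leaf indices among all minimum-distance pairs
        ii, jj = np.nonzero(Dm <= best_d)
        best = None
        for i, j in zip(ii.tolist(), jj.tolist()):
            if i >= j:
                continue
            tie = tuple(sorted((int(lowleaf[i]), int(lowleaf[j]))))
            if best is None or tie < best[2]:
                best = (i, j, tie)
        i, j, _ = best
        left, right = sorted((int(node_of[i]), int(node_of[j])))
        linkage[step] = (left, right, Dm[i, j], size[i] + size[j])

        # unweighted-average update; merged cluster reuses slot i
        others = alive.copy()
        others[[i, j]] = False
        new_d = (size[i] * Dm[i, others] + size[j] * Dm[j, others]) / (size[i] + size[j])
        Dm[i, others] = new_d
        Dm[others, i] = new_d
        Dm[j, :] = np.inf
        Dm[:, j] = np.inf
        node_of[i] = n + step
        size[i] += size[j]
        lowleaf[i] = min(lowleaf[i], lowleaf[j])
        alive[j] = False
    return ClusterTree(linkage=linkage, leaf_ids=list(leaf_ids))


def cut_k(tree: ClusterTree, k: int) -> np.ndarray:
    """Cluster labels (0..k-1, by lowest member leaf index) from a k-cut.

    Removing the k-1 highest merges — the last k-1 linkage records, since
    average-linkage merge heights are non-decreasing — leaves k clusters.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ContractError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        left, right, _, _ = tree.linkage[step]
        new = n + step
        parent[find(int(left))] = new
        parent[find(int(right))] = new

    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        labels[leaf] = roots[r]
    return labels


# ----------------------------------------------------------------------
# profile construction and export


def median_center(log2_profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene median centering of log2 values (heat-map convention)."""
    return log2_profiles.sub(log2_profiles.median(axis=1), axis=0)


def expression_profiles(
    matrix: ExpressionMatrix, genes: list[str] | None = None, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Replicate-mean log2 time-course profiles for clustering.

    Columns are genotype x (control, then each cold timepoint) means; rows
    are median-centered.
    """
    work = matrix if genes is None else matrix.subset_genes(genes)
    log2 = work.log2_view(pseudocount).values
    cols = {}
    for genotype in ("recurrent", "introgression"):
        ctrl = work.select(genotype=genotype, condition="control")
        if not ctrl:
            continue
        cols[f"{genotype}_control"] = log2[ctrl].mean(axis=1)
        for t in work.timepoints():
            ids = work.select(genotype=genotype, condition="cold", time_h=t)
            if ids:
                cols[f"{genotype}_{t}h"] = log2[ids].mean(axis=1)
    prof = pd.DataFrame(cols, index=work.values.index)
    return median_center(prof)


def cluster_genes(
    matrix: ExpressionMatrix, genes: list[str], k: int, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, ClusterTree]:
    """Cluster the given genes' time-course profiles and cut at k."""
    prof = expression_profiles(matrix, genes, pseudocount)
    tree = agglomerate_average(prof.to_numpy(), list(prof.index))
    labels = cut_k(tree, k)
    assign = pd.DataFrame({"gene_id": prof.index, "cluster": labels + 1})
    return assign, tree


def export_cdt_gtr(tree: ClusterTree, profiles: pd.DataFrame, prefix: str) -> None:
    """Cluster-3.0 style CDT/GTR export for heat-map viewers."""
    n = tree.n_leaves
    # leaf order by depth-first traversal of the final merge
    children: dict[int, tuple[int, int]] = {}
    for step in range(n - 1):
        left, right, _, _ = tree.linkage[step]
        children[n + step] = (int(left), int(right))

    order: list[int] = []

    def walk(node: int) -> None:
        if node < n:
            order.append(node)
        else:
            l, r = children[node]
            walk(l)
            walk(r)

    walk(2 * n - 2)

    node_name = {i: f"GENE{i}X" for i in range(n)}
    with open(f"{prefix}.gtr", "w") as fh:
        for step in range(n - 1):
            left, right, height, _ = tree.linkage[step]
            name = f"NODE{step + 1}X"
            fh.write(
                "\t".join(
                    [
                        name,
                        node_name.get(int(left), f"NODE{int(left) - n + 1}X"),
                        node_name.get(int(right), f"NODE{int(right) - n + 1}X"),
                        f"{1.0 - height:.6f}",
                    ]
                )
                + "\n"
            )
    with open(f"{prefix}.cdt", "w") as fh:
        header = ["GID", "UNIQID", "NAME", "GWEIGHT", *profiles.columns]
        fh.write("\t".join(header) + "\n")
        for leaf in order:
            gene = tree.leaf_ids[leaf]
            row = profiles.loc[gene]
            fh.write(
                "\t".join(
                    [node_name[leaf], gene, gene, "1", *(f"{v:.6f}" for v in row)]
                )
                + "\n"
            )


def heatmap_png(profiles: pd.DataFrame, labels: np.ndarray, path: str) -> None:
    """Basic clustered heat map (genes ordered by cluster label)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(labels, kind="stable")
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(
        profiles.to_numpy()[order], aspect="auto", cmap="RdBu_r", interpolation="nearest"
    )
    ax.set_xticks(range(len(profiles.columns)))
    ax.set_xticklabels(profiles.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="median-centered log2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
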