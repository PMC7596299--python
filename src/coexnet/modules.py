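"""Module detection: clustering, tree cutting, eigengenes, merging.

Genes are clustered on the topological-overlap dissimilarity with
average-linkage (UPGMA) hierarchical clustering. The dendrogram is
decomposed into modules by an adaptive tree cut with a minimum module
size; each module is summarized by its eigengene (first principal
component of the standardized member rows), and modules whose
eigengenes are highly correlated are merged iteratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from coexnet.netcore import AdjacencyMatrix
from coexnet.types import (
    GREY,
    Eigengenes,
    ExpressionMatrix,
    ModulePartition,
    color_for_rank,
)

DEFAULT_MIN_MODULE_SIZE = 40
DEFAULT_MERGE_CUT_HEIGHT = 0.25


@dataclass
class Dendrogram:
    """UPGMA tree over genes: scipy linkage matrix plus leaf identifiers."""

    linkage: np.ndarray
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.leaf_ids[i] for i in order]


def average_linkage(diss: pd.DataFrame) -> Dendrogram:
    """UPGMA hierarchical clustering of a symmetric dissimilarity matrix.

    The merge height of two clusters is the mean pairwise dissimilarity
    between their members; scipy's implementation is deterministic
    (ties resolved by cluster index order).
    """
    arr = diss.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    condensed = arr[np.triu_indices_from(arr, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, leaf_ids=list(diss.index))


def _subtree_leaves(Z: np.ndarray, n: int) -> list[list[int]]:
    """Leaf index lists for every internal node (by merge row)."""
    leaves: list[list[int]] = []
    for row in range(Z.shape[0]):
        members = []
        for child in (int(Z[row, 0]), int(Z[row, 1])):
            members.extend([child] if child < n else leaves[child - n])
        leaves.append(members)
    return leaves


def dynamic_tree_cut(
    dend: Dendrogram,
    diss: pd.DataFrame,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    static_cut_frac: float = 0.99,
    core_gap: float = 0.10,
    reassign_grey: bool = True,
) -> ModulePartition:
    """Adaptive decomposition of the dendrogram into modules.

    Three stages:

    1. a static cut separates the coarse branches. Because topological
       overlap compresses join heights toward 1, the cut is placed at
       ``static_cut_frac`` of the span between the 5th percentile and
       the maximum of the join heights rather than of the absolute
       height;
    2. each branch below the cut is recursively split while both
       children have at least ``min_module_size`` leaves and a core
       (mean internal) dissimilarity at least ``core_gap`` below the
       parent's — the sensitivity knob: larger values split less;
    3. unassigned genes are adopted by the module with the smallest
       mean dissimilarity when that mean falls below the module's
       90th-percentile internal dissimilarity, else stay grey.

    Module labels come from the fixed color list by decreasing size
    (ties broken by the smallest member gene ID).
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    n = dend.n_leaves
    D = diss.to_numpy(dtype=float)
    if min_module_size > n:
        warnings.warn("min_module_size exceeds gene count; all genes grey")
        return ModulePartition(
            assignment=pd.Series(GREY, index=dend.leaf_ids), provenance="unmerged"
        )

    Z = dend.linkage
    node_leaves = _subtree_leaves(Z, n)
    h_lo = float(np.quantile(Z[:, 2], 0.05))
    cut_h = h_lo + static_cut_frac * (Z[:, 2].max() - h_lo)

    def core(members: list[int]) -> float:
        if len(members) < 2:
            return 0.0
        sub = D[np.ix_(members, members)]
        m = len(members)
        return float(sub.sum() / (m * (m - 1)))

    def decompose(node: int) -> list[list[int]]:
        if node < n:
            return []
        row = node - n
        members = node_leaves[row]
        h = Z[row, 2]
        left, right = int(Z[row, 0]), int(Z[row, 1])
        if h > cut_h:
            return decompose(left) + decompose(right)
        lm = [left] if left < n else node_leaves[left - n]
        rm = [right] if right < n else node_leaves[right - n]
        parent_core = core(members)
        if (
            len(lm) >= min_module_size
            and len(rm) >= min_module_size
            and core(lm) < (1.0 - core_gap) * parent_core
            and core(rm) < (1.0 - core_gap) * parent_core
        ):
            return decompose(left) + decompose(right)
        if len(members) >= min_module_size:
            return [members]
        return []

    branches = decompose(2 * n - 2)

    assignment = pd.Series(GREY, index=dend.leaf_ids)
    ids = np.array(dend.leaf_ids)
    branches.sort(key=lambda b: (-len(b), min(ids[b])))
    for rank, members in enumerate(branches):
        assignment.iloc[members] = color_for_rank(rank)

    if reassign_grey and branches:
        grey_idx = np.flatnonzero((assignment == GREY).to_numpy())
        mod_info = []
        for rank, members in enumerate(branches):
            sub = D[np.ix_(members, members)]
            internal = sub[np.triu_indices_from(sub, k=1)]
            mod_info.append(
                (color_for_rank(rank), members, float(np.quantile(internal, 0.9)))
            )
        for g in grey_idx:
            means = [D[g, members].mean() for _, members, _ in mod_info]
            best = int(np.argmin(means))
            if means[best] < mod_info[best][2]:
                assignment.iloc[g] = mod_info[best][0]
        # relabel by final size after adoption
        sizes = assignment[assignment != GREY].value_counts()
        order = sorted(
            sizes.index,
            key=lambda c: (-sizes[c], min(assignment.index[assignment == c])),
        )
        remap = {old: color_for_rank(i) for i, old in enumerate(order)}
        assignment = assignment.map(lambda c: remap.get(c, GREY))

    return ModulePartition(assignment=assignment, provenance="unmerged")


def module_eigengene(
    em: ExpressionMatrix, members: list[str]
) -> tuple[pd.Series, float]:
    """First principal component of a module's standardized expression.

    Member rows are z-scored per gene; the eigengene is the unit-norm
    first right singular vector, sign-oriented to correlate
    non-negatively with the module's mean standardized profile.
    Zero-variance members are excluded with a warning. Returns the
    eigengene (indexed by sample) and the fraction of variance it
    explains.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("a module needs at least 2 members")
    X = em.values.loc[members].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [m for m, k in zip(members, keep) if not k]
        warnings.warn(f"zero-variance members excluded from eigengene: {dropped}")
        X = X[keep]
    Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = Vt[0]
    var_explained = float(S[0] ** 2 / (S**2).sum())
    mean_profile = Xs.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=em.sample_ids), var_explained


def eigengene_table(em: ExpressionMatrix, part: ModulePartition) -> Eigengenes:
    """Eigengenes for every non-grey module of a partition."""
    rows, var = {}, {}
    for mod in part.modules:
        members = part.members(mod)
        if len(members) < 2:
            # single-gene module: its standardized profile is the eigengene
            x = em.values.loc[members[0]].to_numpy(dtype=float)
            x = (x - x.mean()) / np.linalg.norm(x - x.mean())
            rows[mod] = pd.Series(x, index=em.sample_ids)
            var[mod] = 1.0
            continue
        rows[mod], var[mod] = module_eigengene(em, members)
    values = pd.DataFrame(rows).T
    return Eigengenes(values=values, variance_explained=pd.Series(var))


def merge_modules(
    part: ModulePartition,
    em: ExpressionMatrix,
    merge_cut_height: float = DEFAULT_MERGE_CUT_HEIGHT,
) -> tuple[ModulePartition, Eigengenes]:
    """Iteratively merge modules with highly correlated eigengenes.

    Eigengenes are clustered with average linkage on 1 - cor(E_i, E_j);
    groups joined strictly below ``merge_cut_height`` merge (0.25 means
    merging modules with eigengene correlation above 0.75). Eigengenes
    are recomputed and the procedure repeats until no merge occurs.
    Grey never merges. Labels are re-drawn from the color list by
    merged size.
    """
    assignment = part.assignment.copy()
    if not (assignment != GREY).any():
        raise ValueError("no non-grey modules to merge")
    while True:
        current = ModulePartition(assignment=assignment, provenance="merged")
        mods = current.modules
        eg = eigengene_table(em, current)
        if len(mods) < 2:
            return current, eg
        E = eg.values.loc[mods].to_numpy()
        corr = np.corrcoef(E)
        diss = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(diss, 0.0)
        condensed = diss[np.triu_indices_from(diss, k=1)]
        Z = hierarchy.linkage(condensed, method="average")
        groups = hierarchy.fcluster(Z, t=merge_cut_height - 1e-12, criterion="distance")
        if len(set(groups)) == len(mods):
            return current, eg
        merged_members: list[list[str]] = []
        for gid in sorted(set(groups)):
            members: list[str] = []
            for mod, g in zip(mods, groups):
                if g == gid:
                    members.extend(current.members(mod))
            merged_members.append(members)
        merged_members.sort(key=lambda m: (-len(m), min(m)))
        assignment = pd.Series(GREY, index=assignment.index)
        for rank, members in enumerate(merged_members):
            assignment.loc[members] = color_for_rank(rank)


def hub_genes(
    a: AdjacencyMatrix, part: ModulePartition, top_n: int | None = None
) -> dict[str, pd.Series]:
    """Per-module genes ranked by intramodular connectivity.

    Intramodular connectivity is the sum of adjacency to same-module
    genes (self excluded). Ties break deterministically by gene ID.
    """
    out: dict[str, pd.Series] = {}
    arr = a.a
    for mod in part.modules:
        members = sorted(part.members(mod))
        sub = arr.loc[members, members].to_numpy().copy()
        np.fill_diagonal(sub, 0.0)
        kin = pd.Series(sub.sum(axis=1), index=members, name="k_intramodular")
        kin = kin.sort_values(ascending=False, kind="stable")
        out[mod] = kin.head(top_n) if top_n else kin
    return out


def module_density_summary(
    em: ExpressionMatrix, part: ModulePartition
) -> pd.DataFrame:
    """Quartiles of member-gene expression per module and sample.

    Returns a tidy table (module, sample, q25, median, q75) — the
    summary behind per-module expression density heatmaps.
    """
    records = []
    for mod in part.modules:
        sub = em.values.loc[part.members(mod)]
        q = sub.quantile([0.25, 0.5, 0.75], axis=0)
        for sample in em.sample_ids:
            records.append(
                {
                    "module": mod,
                    "sample": sample,
                    "q25": q.loc[0.25, sample],
                    "median": q.loc[0.5, sample],
                    "q75": q.loc[0.75, sample],
                }
            )
    return pd.DataFrame(records)


def mds_embedding(diss: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a dissimilarity matrix.

    Double-centers the squared dissimilarities and takes the top
    eigenvectors scaled by the square root of their eigenvalues.
    Deterministic up to axis sign; the sign is fixed so each axis's
    largest-magnitude coordinate is positive.
    """
    D = diss.to_numpy(dtype=float)
    n = D.shape[0]
    if dims > n - 1:
        raise ValueError(f"dims must be <= n - 1 = {n - 1}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    for d in range(dims):
        i = np.argmax(np.abs(coords[:, d]))
        if coords[i, d] < 0:
            coords[:, d] = -coords[:, d]
    return pd.DataFrame(
        coords, index=diss.index, columns=[f"mds_{d + 1}" for d in range(dims)]
    )
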