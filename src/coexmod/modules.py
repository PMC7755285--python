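"""Module detection on the TOM dissimilarity.

Average-linkage (UPGMA) clustering of ``1 − TOM``, a static or
dynamic-hybrid tree cut with a minimum module size, first-principal-
component module eigengenes, iterative merging of modules whose eigengenes
correlate above a threshold, and size-ranked color naming.

The dynamic-hybrid cut implements the core of the adaptive branch-cutting
idea: starting from the forest obtained by cutting at ``cut_height``, a
cluster is split at its top merge whenever both sub-branches are large
enough and their internal merge heights dip sufficiently far below the
joining height (the required dip shrinks as ``deep_split`` grows).  Genes
shed from small side-branches, and any cluster below the minimum size, are
then assigned to the nearest detected module by average dissimilarity when
they fall within that module's radius, and are left unassigned otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .data_io import ExpressionMatrix

__all__ = [
    "Dendrogram",
    "ModulePartition",
    "ModuleEigengenes",
    "UNASSIGNED",
    "STANDARD_COLORS",
    "average_linkage_cluster",
    "cut_tree",
    "module_eigengene",
    "module_eigengenes",
    "merge_close_modules",
    "assign_colors",
]

UNASSIGNED = "unassigned"

# canonical module color sequence, in descending-size order of use
STANDARD_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
)

# required dip of a sub-branch below its joining height, per deep_split level
_SPLIT_GAP = (0.15, 0.10, 0.05, 0.02)

# A gene belongs inside a module when its average dissimilarity to the
# module is either (a) clearly below its distance to the nearest *other*
# module (scale-free neighbor-ratio test) or (b) within the module radius,
# the _RADIUS_QUANTILE quantile of members' average intra-module
# dissimilarity.  The same rule trims loosely attached fringe and rescues
# leftover genes.
_RADIUS_QUANTILE = 0.9
_NEIGHBOR_RATIO = 0.97
_TRIM_PASSES = 2


@dataclass
class Dendrogram:
    """UPGMA merge history in scipy linkage format."""

    gene_ids: list[str]
    linkage: np.ndarray  # (n-1) × 4 scipy linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return hierarchy.leaves_list(self.linkage)


@dataclass
class ModulePartition:
    """Gene → module label map; ``unassigned`` is a reserved label."""

    assignment: dict[str, str]
    colors: dict[str, str] = field(default_factory=dict)

    def sizes(self) -> pd.Series:
        s = pd.Series(self.assignment, name="module").value_counts()
        return s.drop(UNASSIGNED, errors="ignore")

    @property
    def labels(self) -> list[str]:
        return list(self.sizes().index)

    def genes_in(self, label: str) -> list[str]:
        return [g for g, m in self.assignment.items() if m == label]


@dataclass
class ModuleEigengenes:
    """Samples × modules matrix; each column is the sign-oriented,
    unit-variance first principal component of its module."""

    values: pd.DataFrame  # index sample_id, columns module labels

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def module_labels(self) -> list[str]:
        return list(self.values.columns)


def _check_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix is not symmetric")
    return (d + d.T) / 2.0


def average_linkage_cluster(d: np.ndarray, gene_ids: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a dissimilarity matrix."""
    d = _check_dissimilarity(d)
    n = d.shape[0]
    if gene_ids is None:
        gene_ids = [str(i) for i in range(n)]
    dc = d.copy()
    np.fill_diagonal(dc, 0.0)
    condensed = dc[np.triu_indices(n, k=1)]
    z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(list(gene_ids), z)


# ---------------------------------------------------------------------------
# tree cutting


def _subtree_leaves(z: np.ndarray, n: int) -> list[list[int]]:
    """Leaf lists for every node (0..2n-2) of a linkage matrix."""
    leaves: list[list[int]] = [[i] for i in range(n)]
    for a, b in z[:, :2].astype(int):
        leaves.append(leaves[a] + leaves[b])
    return leaves


def _node_height(z: np.ndarray, n: int, node: int) -> float:
    return 0.0 if node < n else float(z[node - n, 2])


def _dynamic_branches(
    z: np.ndarray, n: int, root: int, min_size: int, gap: float, leaves: list[list[int]]
) -> tuple[list[list[int]], list[int]]:
    """Recursive branch detection; returns (module cores, leftover leaves)."""
    cores: list[list[int]] = []
    leftovers: list[int] = []

    def recurse(node: int) -> None:
        if node < n:
            leftovers.extend(leaves[node])
            return
        a, b = int(z[node - n, 0]), int(z[node - n, 1])
        h = _node_height(z, n, node)
        size_a, size_b = len(leaves[a]), len(leaves[b])
        dip_a = h - _node_height(z, n, a)
        dip_b = h - _node_height(z, n, b)
        big_a = size_a >= min_size and dip_a >= gap
        big_b = size_b >= min_size and dip_b >= gap
        if big_a and big_b:
            recurse(a)
            recurse(b)
        elif big_a and size_b < min_size:
            leftovers.extend(leaves[b])
            recurse(a)
        elif big_b and size_a < min_size:
            leftovers.extend(leaves[a])
            recurse(b)
        else:
            if len(leaves[node]) >= min_size:
                cores.append(leaves[node])
            else:
                leftovers.extend(leaves[node])

    recurse(root)
    return cores, leftovers


def _member_avg_dissim(d: np.ndarray, core: list[int]) -> np.ndarray:
    sub = d[np.ix_(core, core)]
    return sub.sum(axis=1) / max(len(core) - 1, 1)


def _core_radius(d: np.ndarray, core: list[int]) -> float:
    return float(np.quantile(_member_avg_dissim(d, core), _RADIUS_QUANTILE))


def _belongs(
    own: np.ndarray, nearest_other: np.ndarray | None, radius: float | np.ndarray
) -> np.ndarray:
    inside = own <= radius
    if nearest_other is not None:
        inside |= own < _NEIGHBOR_RATIO * nearest_other
    return inside


def _trim_fringe(
    d: np.ndarray, cores: list[list[int]], leftovers: list[int], min_size: int
) -> None:
    """Move each core's loosely attached fringe into the leftover pool,
    in place (fringe: fails both the neighbor-ratio and the radius test)."""
    for _ in range(_TRIM_PASSES):
        moved = False
        for ci, core in enumerate(cores):
            radius = _core_radius(d, core)
            own = _member_avg_dissim(d, core)
            others = [c for cj, c in enumerate(cores) if cj != ci]
            nearest_other = (
                np.min(
                    [d[np.ix_(core, o)].mean(axis=1) for o in others], axis=0
                )
                if others
                else None
            )
            keep = _belongs(own, nearest_other, radius)
            out = [g for g, ok in zip(core, keep) if not ok]
            if out and len(core) - len(out) >= min_size:
                for g in out:
                    core.remove(g)
                leftovers.extend(out)
                moved = True
        if not moved:
            break


def _assign_leftovers(
    d: np.ndarray, cores: list[list[int]], leftovers: list[int]
) -> tuple[list[list[int]], list[int]]:
    """Attach leftover genes to the nearest core they belong to."""
    if not cores or not leftovers:
        return cores, leftovers
    radii = np.array([_core_radius(d, core) for core in cores])
    mean_to_core = np.column_stack(
        [d[np.ix_(leftovers, core)].mean(axis=1) for core in cores]
    )
    order = np.argsort(mean_to_core, axis=1)
    nearest = order[:, 0]
    own = mean_to_core[np.arange(len(leftovers)), nearest]
    second = (
        mean_to_core[np.arange(len(leftovers)), order[:, 1]]
        if mean_to_core.shape[1] > 1
        else None
    )
    within = _belongs(own, second, radii[nearest])
    out_cores = [list(c) for c in cores]
    unassigned = []
    for i, g in enumerate(leftovers):
        if within[i]:
            out_cores[nearest[i]].append(g)
        else:
            unassigned.append(g)
    return out_cores, unassigned


def cut_tree(
    dend: Dendrogram,
    d: np.ndarray,
    min_size: int = 50,
    method: str = "dynamic_hybrid",
    cut_height: float = 0.995,
    deep_split: int = 2,
) -> ModulePartition:
    """Cut the dendrogram into modules of at least ``min_size`` genes.

    ``static`` cuts at ``cut_height`` and discards undersized clusters to
    ``unassigned``; ``dynamic_hybrid`` additionally splits branches
    adaptively and rescues leftover genes near a detected module (see the
    module docstring).
    """
    if min_size < 1:
        raise ValueError("min_size must be ≥ 1")
    if not (0.0 <= cut_height <= 1.0):
        raise ValueError(f"cut_height must be in [0, 1], got {cut_height}")
    if method not in ("static", "dynamic_hybrid"):
        raise ValueError(f"unknown cut method {method!r}")
    if not (0 <= deep_split <= 3):
        raise ValueError("deep_split must be in 0..3")
    d = _check_dissimilarity(d)
    z = dend.linkage
    n = len(dend.gene_ids)

    flat = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(flat):
        clusters.setdefault(int(c), []).append(i)

    if method == "static":
        cores = [idx for idx in clusters.values() if len(idx) >= min_size]
        unassigned = [g for idx in clusters.values() if len(idx) < min_size for g in idx]
    else:
        leaves = _subtree_leaves(z, n)
        parent_of = {}
        for j, (a, b) in enumerate(z[:, :2].astype(int)):
            parent_of[a] = n + j
            parent_of[b] = n + j
        # map each static cluster to its subtree root node
        roots = []
        for idx in clusters.values():
            members = set(idx)
            node = idx[0]
            # climb until the subtree covers the cluster
            while set(leaves[node]) != members:
                node = parent_of[node]
            roots.append(node)
        gap = _SPLIT_GAP[deep_split]
        cores, leftovers = [], []
        for root in roots:
            c, l = _dynamic_branches(z, n, root, min_size, gap, leaves)
            cores.extend(c)
            leftovers.extend(l)
        cores = [list(c) for c in cores]
        _trim_fringe(d, cores, leftovers, min_size)
        cores, _ = _assign_leftovers(d, cores, leftovers)
        cores = [c for c in cores if len(c) >= min_size]
        kept = {g for c in cores for g in c}
        unassigned = sorted(set(range(n)) - kept)

    # deterministic labels: modules ordered by size, ties by first gene id
    gene_ids = dend.gene_ids
    cores_sorted = sorted(
        cores, key=lambda c: (-len(c), min(gene_ids[g] for g in c))
    )
    assignment = {g: UNASSIGNED for g in gene_ids}
    for rank, core in enumerate(cores_sorted, start=1):
        for g in core:
            assignment[gene_ids[g]] = f"M{rank}"
    for g in unassigned:
        assignment[gene_ids[g]] = UNASSIGNED
    return ModulePartition(assignment)


# ---------------------------------------------------------------------------
# eigengenes


def _standardize_rows(v: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    sd = v.std(axis=1, ddof=1)
    bad = np.where(sd == 0)[0]
    if len(bad):
        raise ValueError(
            f"zero-variance gene {gene_ids[bad[0]]!r} inside module; filter first"
        )
    return (v - v.mean(axis=1, keepdims=True)) / sd[:, None]


def module_eigengene(x: ExpressionMatrix) -> pd.Series:
    """First principal component over samples of one module's expression.

    Genes are standardized across samples; the eigengene is the first right
    singular direction, scaled to unit sample variance and sign-oriented to
    correlate positively with the module's mean standardized expression.
    """
    v = x.values.to_numpy(dtype=float)
    n_genes, n_samples = v.shape
    if n_samples < 2:
        raise ValueError("eigengene needs ≥ 2 samples")
    zs = _standardize_rows(v, x.gene_ids)
    _, _, vt = np.linalg.svd(zs, full_matrices=False)
    me = vt[0]
    me = me / me.std(ddof=1)
    mean_profile = zs.mean(axis=0)
    if np.dot(me - me.mean(), mean_profile) < 0:
        me = -me
    return pd.Series(me, index=x.sample_ids, name="ME")


def module_eigengenes(x: ExpressionMatrix, p: ModulePartition) -> ModuleEigengenes:
    """Eigengene for every (non-unassigned) module of a partition."""
    cols = {}
    for label in sorted(p.labels):
        genes = p.genes_in(label)
        sub = ExpressionMatrix(x.values.loc[genes], x.sample_meta)
        cols[label] = module_eigengene(sub)
    return ModuleEigengenes(pd.DataFrame(cols, index=pd.Index(x.sample_ids, name="sample_id")))


def merge_close_modules(
    x: ExpressionMatrix, p: ModulePartition, similarity: float = 0.85
) -> tuple[ModulePartition, ModuleEigengenes]:
    """Iteratively merge module pairs whose eigengenes correlate above
    ``similarity``, recomputing eigengenes after each merge, until no pair
    exceeds the threshold.  The unassigned label never participates."""
    if not (0.0 < similarity < 1.0):
        raise ValueError("similarity must be in (0, 1)")
    assignment = dict(p.assignment)
    while True:
        part = ModulePartition(assignment)
        labels = part.labels
        me = module_eigengenes(x, part)
        if len(labels) < 2:
            return part, me
        corr = me.values[labels].corr().to_numpy()
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= similarity:
            return part, me
        keep, absorb = sorted((labels[i], labels[j]))
        assignment = {
            g: (keep if m == absorb else m) for g, m in assignment.items()
        }


def assign_colors(p: ModulePartition) -> ModulePartition:
    """Name modules by descending size from the standard color sequence;
    ties broken by first (lexicographically smallest) gene id; the
    unassigned label maps to grey."""
    first_gene = {}
    for g in sorted(p.assignment):
        m = p.assignment[g]
        first_gene.setdefault(m, g)
    sizes = p.sizes()
    ordered = sorted(sizes.index, key=lambda m: (-sizes[m], first_gene[m]))
    colors = {}
    for rank, label in enumerate(ordered):
        colors[label] = (
            STANDARD_COLORS[rank] if rank < len(STANDARD_COLORS) else f"module{rank + 1}"
        )
    colors[UNASSIGNED] = "grey"
    return ModulePartition(dict(p.assignment), colors)
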