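import numpy as np
import pandas as pd
import pytest

from coexmod import (
    ExpressionMatrix,
    STANDARD_COLORS,
    UNASSIGNED,
    assign_colors,
    average_linkage_cluster,
    cut_tree,
    log_transform,
    merge_close_modules,
    module_eigengene,
    module_eigengenes,
)
from coexmod.modules import ModulePartition
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from conftest import make_expression


# --- independent oracles -----------------------------------------------------

def upgma_naive(d: np.ndarray) -> np.ndarray:
    """O(n³) UPGMA returning the cophenetic distance matrix."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        for x in clusters[a]:
            for y in clusters[b]:
                coph[x, y] = coph[y, x] = h
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        new_dist = {}
        for (i, j), v in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(i, j)] = v
        for c, members in clusters.items():
            avg = np.mean([d[x, y] for x in merged for y in members])
            key = (min(c, next_id), max(c, next_id))
            new_dist[key] = avg
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    return coph


def power_iteration_pc1(z: np.ndarray, iters: int = 5000) -> np.ndarray:
    """First right singular direction of a row-standardized matrix by
    power iteration on zᵀz."""
    g = z.T @ z
    v = np.ones(g.shape[0]) / np.sqrt(g.shape[0])
    for _ in range(iters):
        v = g @ v
        v /= np.linalg.norm(v)
    return v


def block_dissimilarity(sizes, within=0.05, between=0.95, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = within
        start += s
    d += rng.uniform(0, 0.001, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


# --- clustering --------------------------------------------------------------

class TestAverageLinkage:
    def test_forced_first_merge(self):
        d = np.array([[0.0, 0.1, 0.8], [0.1, 0.0, 0.9], [0.8, 0.9, 0.0]])
        dend = average_linkage_cluster(d, ["a", "b", "c"])
        assert set(dend.linkage[0, :2].astype(int)) == {0, 1}
        assert dend.linkage[0, 2] == pytest.approx(0.1)

    def test_identical_genes_merge_at_zero(self):
        d = np.array([[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]])
        dend = average_linkage_cluster(d)
        assert dend.linkage[0, 2] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cophenetic_matches_naive_upgma(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.1, 1.0, size=(8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = average_linkage_cluster(d)
        coph = squareform(cophenet(dend.linkage, squareform(d))[1])
        assert np.allclose(coph, upgma_naive(d), atol=1e-10)

    def test_heights_nondecreasing(self):
        d = block_dissimilarity([10, 10], seed=3)
        h = average_linkage_cluster(d).heights
        assert (np.diff(h) >= -1e-12).all()

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 0.2], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage_cluster(d)


class TestCutTree:
    @pytest.mark.parametrize("method", ["static", "dynamic_hybrid"])
    def test_perfectly_separated_blocks(self, method):
        d = block_dissimilarity([20, 20, 20])
        dend = average_linkage_cluster(d)
        p = cut_tree(dend, d, min_size=10, method=method, cut_height=0.5)
        sizes = p.sizes()
        assert len(sizes) == 3
        assert (sizes == 20).all()
        assert UNASSIGNED not in set(p.assignment.values())

    def test_min_size_above_n_all_unassigned(self):
        d = block_dissimilarity([10, 10])
        dend = average_linkage_cluster(d)
        p = cut_tree(dend, d, min_size=50)
        assert set(p.assignment.values()) == {UNASSIGNED}

    def test_invalid_cut_height(self):
        d = block_dissimilarity([5, 5])
        dend = average_linkage_cluster(d)
        with pytest.raises(ValueError, match="cut_height"):
            cut_tree(dend, d, cut_height=1.5)

    def test_static_drops_small_clusters_to_unassigned(self):
        d = block_dissimilarity([30, 7])
        dend = average_linkage_cluster(d)
        p = cut_tree(dend, d, min_size=10, method="static", cut_height=0.5)
        assert len(p.sizes()) == 1
        assert sum(v == UNASSIGNED for v in p.assignment.values()) == 7


# --- eigengenes --------------------------------------------------------------

class TestEigengene:
    def test_single_gene_module_is_standardized_gene(self):
        v = np.array([[2.0, 4.0, 8.0, 6.0]])
        x = make_expression(v)
        me = module_eigengene(x)
        expected = (v[0] - v[0].mean()) / v[0].std(ddof=1)
        assert np.allclose(me.to_numpy(), expected, atol=1e-12)

    def test_rank_one_module_recovers_profile(self):
        profile = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        rows = [a * profile + b for a, b in [(1, 0), (2, 5), (0.5, -1), (3, 2)]]
        me = module_eigengene(make_expression(np.vstack(rows)))
        assert abs(np.corrcoef(me, profile)[0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(1, 10, size=(50, 12))
        x = make_expression(v)
        me = module_eigengene(x)
        z = (v - v.mean(1, keepdims=True)) / v.std(1, ddof=1, keepdims=True)
        oracle = power_iteration_pc1(z)
        c = abs(np.corrcoef(me, oracle)[0, 1])
        assert c >= 1 - 1e-10

    def test_unit_variance_zero_mean(self, default_dataset):
        x, truth = default_dataset
        genes = truth.module_genes(1)[:80]
        xl = log_transform(x)
        me = module_eigengene(ExpressionMatrix(xl.values.loc[genes], xl.sample_meta))
        assert abs(me.mean()) < 1e-8
        assert me.std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_sign_oriented_to_module_mean(self, default_dataset):
        x, truth = default_dataset
        xl = log_transform(x)
        for m in range(3):
            genes = truth.module_genes(m)
            sub = ExpressionMatrix(xl.values.loc[genes], xl.sample_meta)
            me = module_eigengene(sub)
            v = sub.values.to_numpy()
            z = (v - v.mean(1, keepdims=True)) / v.std(1, ddof=1, keepdims=True)
            assert np.corrcoef(me, z.mean(0))[0, 1] > 0


class TestMerge:
    def test_identical_eigengenes_merged(self):
        profile = np.linspace(0, 5, 9)
        rng = np.random.default_rng(0)
        rows = np.vstack([profile + rng.normal(0, 0.01, 9) for _ in range(20)])
        x = make_expression(rows)
        p = ModulePartition({f"g{i}": ("A" if i < 10 else "B") for i in range(20)})
        merged, me = merge_close_modules(x, p)
        assert len(merged.labels) == 1
        assert me.values.shape[1] == 1

    def test_distinct_modules_untouched(self, default_dataset):
        x, truth = default_dataset
        xl = log_transform(x)
        assignment = {
            g: (f"M{m}" if m >= 0 else UNASSIGNED)
            for g, m in truth.table["module"].items()
        }
        p = ModulePartition(assignment)
        merged, me = merge_close_modules(xl, p)
        assert sorted(merged.labels) == sorted(p.labels)
        corr = me.values.corr().to_numpy()
        assert (corr[~np.eye(len(corr), dtype=bool)] <= 0.85).all()

    def test_kme_split_module_remerged(self):
        # two labels carved out of one planted profile must merge back
        rng = np.random.default_rng(5)
        profile = np.sin(np.linspace(0, 3, 12))
        rows = np.vstack([
            0.9 * profile + 0.3 * rng.standard_normal(12) for _ in range(40)
        ])
        x = make_expression(rows + 5)
        p = ModulePartition({f"g{i}": ("lo" if i % 2 else "hi") for i in range(40)})
        merged, _ = merge_close_modules(x, p)
        assert len(merged.labels) == 1

    def test_merge_idempotent(self, default_dataset):
        x, truth = default_dataset
        xl = log_transform(x)
        assignment = {
            g: (f"M{m}" if m >= 0 else UNASSIGNED)
            for g, m in truth.table["module"].items()
        }
        once, _ = merge_close_modules(xl, ModulePartition(assignment))
        twice, _ = merge_close_modules(xl, once)
        assert once.assignment == twice.assignment


class TestColors:
    def test_published_size_vector_color_correspondence(self):
        # descending size rank must map onto the canonical color sequence
        sizes = [10378, 3166, 2958, 1305, 494, 439, 305, 293, 236, 62]
        assignment = {}
        gi = 0
        for rank, s in enumerate(sizes):
            for _ in range(s):
                assignment[f"g{gi:06d}"] = f"mod{rank}"
                gi += 1
        p = assign_colors(ModulePartition(assignment))
        expected = ["turquoise", "blue", "brown", "yellow", "green",
                    "red", "black", "pink", "magenta", "purple"]
        got = [p.colors[f"mod{r}"] for r in range(10)]
        assert got == expected

    def test_single_module_turquoise(self):
        p = assign_colors(ModulePartition({"g1": "A", "g2": "A"}))
        assert p.colors["A"] == "turquoise"

    def test_size_tie_broken_by_first_gene_id(self):
        p = ModulePartition({"a1": "X", "a2": "X", "b1": "Y", "b2": "Y"})
        colored = assign_colors(p)
        assert colored.colors["X"] == "turquoise"  # "a1" < "b1"
        assert colored.colors["Y"] == "blue"

    def test_unassigned_is_grey(self):
        p = assign_colors(ModulePartition({"g": UNASSIGNED}))
        assert p.colors[UNASSIGNED] == "grey"


class TestOrderInvariance:
    def test_partition_invariant_to_gene_order(self, default_dataset):
        from coexmod import correlation_matrix, soft_adjacency, tom_similarity

        x, _ = default_dataset
        xl = log_transform(x)
        sub = ExpressionMatrix(xl.values.iloc[:400], xl.sample_meta)
        perm = np.random.default_rng(1).permutation(400)
        sub_perm = ExpressionMatrix(sub.values.iloc[perm], sub.sample_meta)

        def run(xx):
            tom = tom_similarity(soft_adjacency(correlation_matrix(xx), 8))
            d = 1 - tom.values
            np.fill_diagonal(d, 0.0)
            dend = average_linkage_cluster(d, tom.gene_ids)
            return cut_tree(dend, d, min_size=30)

        p1, p2 = run(sub), run(sub_perm)
        # same co-membership structure, label names aside
        genes = sub.gene_ids
        m1 = pd.Series({g: p1.assignment[g] for g in genes})
        m2 = pd.Series({g: p2.assignment[g] for g in genes})
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(m1, m2) == pytest.approx(1.0)
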