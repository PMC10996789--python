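"""Network construction: adjacency, TOM (vs. brute force), modules, kME."""

import numpy as np
import pandas as pd
import pytest

from csfnet.containers import GREY, AbundanceMatrix, ModuleAssignment
from csfnet.network import (build_network, cluster_dendrogram, detect_modules,
                            enforce_kme_consistency, kme_table,
                            merge_close_modules, module_eigenproteins,
                            signed_adjacency, topological_overlap)

from conftest import ari


def tom_brute(a, denom="mean"):
    """Triple-loop evaluation of the topological overlap formula."""
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            d = (k[i] + k[j]) / 2 if denom == "mean" else min(k[i], k[j])
            t[i, j] = (l + a[i, j]) / (d + 1 - a[i, j])
    return t


class TestSignedAdjacency:
    def test_endpoints(self):
        cor = np.array([[1.0, 1.0, -1.0], [1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
        a = signed_adjacency(cor, beta=12)
        assert a[0, 1] == 1.0
        assert a[0, 2] == 0.0
        assert a[1, 2] == pytest.approx(0.5 ** 12)

    def test_zero_correlation_closed_form(self):
        cor = np.zeros((2, 2)); np.fill_diagonal(cor, 1.0)
        assert signed_adjacency(cor, 12)[0, 1] == pytest.approx(2.44140625e-4)

    def test_strictly_monotone(self):
        cors = np.linspace(-1, 1, 21)
        vals = ((1 + cors) / 2) ** 12
        assert np.all(np.diff(vals) > 0)

    def test_out_of_range_rejected(self):
        cor = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(ValueError):
            signed_adjacency(cor)


class TestTopologicalOverlap:
    def test_complete_graph_is_all_ones(self):
        a = np.ones((4, 4))
        assert np.allclose(topological_overlap(a), 1.0)

    def test_star_graph_leaf_leaf_overlap(self):
        # hub 0 connected to 3 leaves with weight 1, leaves unconnected:
        # leaf-leaf TOM = (1*1 + 0) / ((1+1)/2 + 1 - 0) = 0.5
        a = np.eye(4)
        a[0, 1:] = a[1:, 0] = 1.0
        t = topological_overlap(a)
        assert t[1, 2] == pytest.approx(0.5)
        assert t[2, 3] == pytest.approx(0.5)

    @pytest.mark.parametrize("denom", ["mean", "min"])
    def test_matches_brute_force(self, denom):
        rng = np.random.default_rng(42)
        c = rng.uniform(-1, 1, (6, 6))
        c = (c + c.T) / 2; np.fill_diagonal(c, 1.0)
        a = signed_adjacency(c, beta=2)
        assert np.allclose(topological_overlap(a, denom), tom_brute(a, denom),
                           atol=1e-12)

    def test_larger_instance_matches_brute_force(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((30, 20))
        a = signed_adjacency(np.corrcoef(x), beta=6)
        assert np.allclose(topological_overlap(a), tom_brute(a), atol=1e-12)

    def test_asymmetric_rejected(self):
        a = np.eye(3); a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)


class TestDendrogramAndDetection:
    def test_merge_heights_non_decreasing(self, network_result):
        heights = network_result["linkage"][:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_two_blocks_merge_within_blocks_first(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((2, 30))
        x = np.vstack([f[0] + 0.05 * rng.standard_normal((5, 30)),
                       f[1] + 0.05 * rng.standard_normal((5, 30))])
        m = AbundanceMatrix(x, [f"P{i}" for i in range(10)],
                            [f"P{i}" for i in range(10)],
                            [f"S{j}" for j in range(30)])
        net = build_network(m)
        linkage, _ = cluster_dendrogram(net.tom)
        # the first 8 merges must join members of the same block
        for left, right, *_ in linkage[:8]:
            if left < 10 and right < 10:
                assert (left < 5) == (right < 5)

    def test_planted_modules_recovered(self, planted_small):
        matrix, _, truth = planted_small
        net = build_network(matrix)
        linkage, d = cluster_dendrogram(net.tom)
        a = detect_modules(linkage, d, matrix.protein_ids)
        score = ari([truth.membership[p] for p in matrix.protein_ids],
                    [a[p] for p in matrix.protein_ids])
        assert len(a.modules()) == 3
        assert score >= 0.9

    def test_tiny_planted_module_never_becomes_own_module(self):
        rng = np.random.default_rng(5)
        f = rng.standard_normal((2, 60))
        blocks = [0.8 * f[0] + rng.standard_normal((40, 60)),
                  0.8 * f[1] + rng.standard_normal((10, 60)),
                  rng.standard_normal((100, 60))]
        x = np.vstack(blocks)
        ids = [f"P{i}" for i in range(150)]
        m = AbundanceMatrix(x, ids, ids, [f"S{j}" for j in range(60)])
        net = build_network(m)
        linkage, d = cluster_dendrogram(net.tom)
        a = detect_modules(linkage, d, ids, min_module_size=30)
        tiny = [a[f"P{i}"] for i in range(40, 50)]
        own = {lab for lab in tiny
               if lab != GREY and all(p.startswith("P4") for p in a.members(lab))}
        assert not own  # grey or absorbed, never an own module

    def test_pure_noise_mostly_grey(self, noise_matrix):
        net = build_network(noise_matrix)
        linkage, d = cluster_dendrogram(net.tom)
        a = detect_modules(linkage, d, noise_matrix.protein_ids)
        assert a.grey_fraction() >= 0.9

    def test_bad_deep_split_rejected(self, noise_matrix):
        net = build_network(noise_matrix)
        linkage, d = cluster_dendrogram(net.tom)
        with pytest.raises(ValueError, match="deep_split"):
            detect_modules(linkage, d, noise_matrix.protein_ids, deep_split=5)


class TestEigenproteins:
    def _matrix(self, x):
        n, s = x.shape
        return AbundanceMatrix(x, [f"P{i}" for i in range(n)],
                               [f"P{i}" for i in range(n)],
                               [f"S{j}" for j in range(s)])

    def test_identical_proteins_give_rank_one_module(self):
        profile = np.sin(np.arange(20.0))
        x = np.vstack([profile] * 4 + [np.cos(np.arange(20.0))] * 4)
        m = self._matrix(x)
        a = ModuleAssignment({f"P{i}": "M1" if i < 4 else "M2" for i in range(8)})
        eig = module_eigenproteins(m, a)
        z = (profile - profile.mean()) / profile.std()
        assert eig.pve["M1"] == pytest.approx(1.0)
        assert np.allclose(eig.values.loc["M1"], z, atol=1e-8)

    def test_sign_orientation_flips_with_members(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30) + 0.1 * rng.standard_normal((6, 30))
        m1, m2 = self._matrix(x), self._matrix(-x)
        a = ModuleAssignment({f"P{i}": "M1" for i in range(6)})
        e1 = module_eigenproteins(m1, a).values.loc["M1"]
        e2 = module_eigenproteins(m2, a).values.loc["M1"]
        assert np.allclose(e1, -e2, atol=1e-8)

    def test_noiseless_factor_recovers_planted_factor(self, planted_small):
        matrix, _, truth = planted_small
        members = truth.module_proteins(1)
        a = ModuleAssignment({p: ("M1" if truth.membership[p] == 1 else GREY)
                              for p in matrix.protein_ids})
        eig = module_eigenproteins(matrix, a)
        f = truth.factors.iloc[0].to_numpy()
        r = np.corrcoef(eig.values.loc["M1"], f)[0, 1]
        assert abs(r) >= 0.95  # noisy loadings, still strongly aligned
        assert r > 0  # orientation follows the members, which load positively

    def test_single_protein_module_rejected(self):
        m = self._matrix(np.random.default_rng(0).standard_normal((3, 10)))
        a = ModuleAssignment({"P0": "M1", "P1": GREY, "P2": GREY})
        with pytest.raises(ValueError, match="fewer than 2"):
            module_eigenproteins(m, a)


class TestKME:
    def test_kme_matches_direct_bicor(self, planted_small):
        from csfnet.correlation import bicor

        matrix, _, truth = planted_small
        sub = matrix.select_proteins(matrix.protein_ids[:20])
        a = ModuleAssignment({p: "M1" if truth.membership[p] == 1 else GREY
                              for p in sub.protein_ids})
        eig = module_eigenproteins(sub, a)
        kme = kme_table(sub, eig)
        e = eig.values.loc["M1"].to_numpy()
        for i, p in enumerate(sub.protein_ids):
            assert kme.kme.loc[p, "M1"] == pytest.approx(
                bicor(sub.values[i], e), abs=1e-10)

    def test_kme_bounded_and_own_module_largest_for_members(self, network_result):
        kme = kme_table(network_result["matrix"],
                        module_eigenproteins(network_result["matrix"],
                                             network_result["final"]))
        assert (kme.kme.abs() <= 1.0 + 1e-12).all().all()

    def test_sample_mismatch_rejected(self, planted_small):
        matrix, _, _ = planted_small
        a = ModuleAssignment({p: "M1" for p in matrix.protein_ids[:5]}
                             | {p: GREY for p in matrix.protein_ids[5:]})
        eig = module_eigenproteins(matrix, a)
        shrunk = matrix.select_samples(matrix.sample_ids[:30])
        with pytest.raises(ValueError, match="samples"):
            kme_table(shrunk, eig)


class TestMergeAndReassign:
    def test_duplicate_factor_modules_merge(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal(50)
        x = np.vstack([f + 0.05 * rng.standard_normal((8, 50)),
                       f + 0.05 * rng.standard_normal((8, 50))])
        ids = [f"P{i}" for i in range(16)]
        m = AbundanceMatrix(x, ids, ids, [f"S{j}" for j in range(50)])
        a = ModuleAssignment({ids[i]: "M1" if i < 8 else "M2" for i in range(16)})
        merged = merge_close_modules(m, a, cut_height=0.07)
        assert len(merged.modules()) == 1

    def test_orthogonal_modules_unchanged(self, planted_small):
        matrix, _, truth = planted_small
        a = ModuleAssignment({
            p: f"M{truth.membership[p]}" if truth.membership[p] else GREY
            for p in matrix.protein_ids})
        merged = merge_close_modules(matrix, a, cut_height=0.07)
        assert len(merged.modules()) == 3

    def test_zero_cut_height_never_merges(self, planted_small):
        matrix, _, truth = planted_small
        a = ModuleAssignment({
            p: f"M{truth.membership[p]}" if truth.membership[p] else GREY
            for p in matrix.protein_ids})
        assert merge_close_modules(matrix, a, cut_height=0.0) \
            .sizes() == a.relabel_by_size().sizes()

    def test_scrambled_labels_restored(self, planted_small):
        matrix, _, truth = planted_small
        rng = np.random.default_rng(9)
        labels = {p: f"M{truth.membership[p]}" if truth.membership[p] else GREY
                  for p in matrix.protein_ids}
        module_ps = [p for p in matrix.protein_ids if truth.membership[p]]
        scrambled = rng.choice(module_ps, size=int(0.1 * len(module_ps)),
                               replace=False)
        for p in scrambled:
            labels[p] = f"M{rng.integers(1, 4)}"
        fixed = enforce_kme_consistency(matrix, ModuleAssignment(labels))
        # map recovered labels to truth modules by majority vote
        restored = 0
        for p in scrambled:
            mod = fixed[p]
            if mod == GREY:
                continue
            mates = fixed.members(mod)
            votes = pd.Series([truth.membership[q] for q in mates]).mode()
            if votes.iloc[0] == truth.membership[p]:
                restored += 1
        assert restored / len(scrambled) >= 0.95

    def test_consistent_assignment_is_fixed_point(self, network_result):
        final = network_result["final"]
        again = enforce_kme_consistency(network_result["matrix"], final)
        assert again.labels == final.labels

    def test_grey_member_of_planted_module_rescued(self, planted_small):
        matrix, _, truth = planted_small
        labels = {p: f"M{truth.membership[p]}" if truth.membership[p] else GREY
                  for p in matrix.protein_ids}
        victim = truth.module_proteins(1)[0]
        labels[victim] = GREY
        fixed = enforce_kme_consistency(matrix, ModuleAssignment(labels))
        mates = set(fixed.members(fixed[victim]))
        assert fixed[victim] != GREY
        assert len(mates & set(truth.module_proteins(1))) > len(mates) / 2

    def test_grey_fraction_decreases_after_reassignment(self, network_result):
        assert network_result["final"].grey_fraction() \
            < network_result["merged"].grey_fraction() + 1e-12


def test_pipeline_determinism_same_seed_same_assignment(planted_small):
    matrix, _, _ = planted_small
    results = []
    for _ in range(2):
        net = build_network(matrix)
        linkage, d = cluster_dendrogram(net.tom)
        a = detect_modules(linkage, d, matrix.protein_ids)
        results.append(enforce_kme_consistency(matrix, a).labels)
    assert results[0] == results[1]
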