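import io
import math

import numpy as np
import pytest

from hydbeta import (
    DistanceMatrix,
    distance_matrix,
    is_monophyletic,
    neighbor_joining,
    pairwise_distance,
    star_alignment,
    tree_path_distances,
    trim_columns,
)
from hydbeta.synth import generate_clade_dataset

from oracles import random_additive_tree


class TestTrimColumns:
    def test_gapless_block_unchanged(self):
        seqs = ["MKV", "MKV", "MLV"]
        trimmed, kept = trim_columns(seqs, 1.0)
        assert trimmed == seqs and kept == [0, 1, 2]

    def test_half_gapped_column_removed(self):
        seqs = ["M-V", "MKV"]  # middle column 50% occupied
        trimmed, kept = trim_columns(seqs, 0.6)
        assert trimmed == ["MV", "MV"] and kept == [0, 2]

    def test_zero_threshold_is_identity(self):
        seqs = ["M--", "-K-", "--V"]
        trimmed, kept = trim_columns(seqs, 0.0)
        assert trimmed == seqs

    def test_survivors_match_counting_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            nseq, ncol = int(rng.integers(2, 8)), int(rng.integers(5, 40))
            block = [
                "".join("-" if rng.random() < 0.3 else "A" for _ in range(ncol))
                for _ in range(nseq)
            ]
            thr = float(rng.uniform(0.1, 0.9))
            try:
                _, kept = trim_columns(block, thr)
            except ValueError:
                kept = []
            expected = [
                j for j in range(ncol)
                if sum(row[j] != "-" for row in block) >= thr * nseq - 1e-12
            ]
            assert kept == expected or (kept == [] and expected == [])

    def test_all_columns_removed_is_error(self):
        with pytest.raises(ValueError):
            trim_columns(["--", "--"], 0.5)


class TestDistances:
    def test_identical_sequences_zero(self):
        for model in ("p", "poisson"):
            assert pairwise_distance("MKV", "MKV", model) == 0.0

    def test_poisson_closed_form(self):
        # p = 0.5 -> -ln(0.5)
        d = pairwise_distance("AAAA", "AATT", "poisson")
        assert d == pytest.approx(-math.log(0.5), rel=1e-12)

    def test_p_distance_counting_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(4, 50))
            a = "".join(rng.choice(list("AC-"), size=n))
            b = "".join(rng.choice(list("AC-"), size=n))
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not shared:
                with pytest.raises(ValueError):
                    pairwise_distance(a, b, "p")
                continue
            expected = sum(x != y for x, y in shared) / len(shared)
            assert pairwise_distance(a, b, "p") == pytest.approx(expected)

    def test_saturated_poisson_is_error(self):
        with pytest.raises(ValueError):
            pairwise_distance("AAAA", "TTTT", "poisson")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids=("a", "b", "c"), d=d))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> distances by path sums
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        dm = DistanceMatrix(ids=("a", "b", "c", "d"), d=d)
        tree = neighbor_joining(dm)
        assert frozenset(["a", "b"]) in tree.bipartitions()
        back = tree_path_distances(tree)
        idx = {t: k for k, t in enumerate(back.ids)}
        for i, ti in enumerate(dm.ids):
            for j, tj in enumerate(dm.ids):
                assert back.d[idx[ti], idx[tj]] == pytest.approx(d[i, j], abs=1e-12)

    def test_additive_matrices_recovered_exactly(self):
        """NJ inverts tree -> distance-matrix construction, 4-10 taxa."""
        rng = np.random.default_rng(17)
        for trial in range(10):
            n = int(rng.integers(4, 11))
            ids, d, true_bips = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(ids=tuple(ids), d=d))
            assert tree.bipartitions() == true_bips
            back = tree_path_distances(tree)
            order = [back.ids.index(t) for t in ids]
            assert np.allclose(back.d[np.ix_(order, order)], d, atol=1e-9)

    def test_permutation_invariance_up_to_isomorphism(self):
        rng = np.random.default_rng(23)
        ids, d, _ = random_additive_tree(7, rng)
        tree1 = neighbor_joining(DistanceMatrix(ids=tuple(ids), d=d))
        perm = rng.permutation(len(ids))
        ids2 = tuple(ids[k] for k in perm)
        d2 = d[np.ix_(perm, perm)]
        tree2 = neighbor_joining(DistanceMatrix(ids=ids2, d=d2))
        assert tree1.bipartitions() == tree2.bipartitions()

    def test_matches_dendropy_on_noisy_matrix(self):
        """Independent cross-check against dendropy's NJ implementation."""
        import dendropy
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(29)
        ids, d, _ = random_additive_tree(8, rng)
        d = d + rng.uniform(0, 0.05, size=d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        mine = neighbor_joining(DistanceMatrix(ids=tuple(ids), d=d))

        csv = "," + ",".join(ids) + "\n"
        for i, t in enumerate(ids):
            csv += t + "," + ",".join(f"{x:.12f}" for x in d[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=",")
        ref = pdm.nj_tree()
        mine_dp = dendropy.Tree.get(data=mine.newick(), schema="newick",
                                    taxon_namespace=pdm.taxon_namespace)
        ref.encode_bipartitions()
        mine_dp.encode_bipartitions()
        assert treecompare.symmetric_difference(ref, mine_dp) == 0

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(ids=("a", "b"), d=np.zeros((2, 2))))

    def test_newick_output_parses(self):
        import dendropy
        rng = np.random.default_rng(31)
        ids, d, _ = random_additive_tree(6, rng)
        tree = neighbor_joining(DistanceMatrix(ids=tuple(ids), d=d))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(ids)


class TestMonophyly:
    def _simple_tree(self):
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        return neighbor_joining(DistanceMatrix(ids=("a", "b", "c", "d"), d=d))

    def test_singleton_always_monophyletic(self):
        tree = self._simple_tree()
        flag, side = is_monophyletic(tree, {"a"})
        assert flag and side == frozenset({"a"})

    def test_split_pair_not_monophyletic(self):
        tree = self._simple_tree()
        flag, side = is_monophyletic(tree, {"a", "c"})
        assert not flag and side is None

    def test_cherry_is_monophyletic(self):
        tree = self._simple_tree()
        assert is_monophyletic(tree, {"a", "b"})[0]

    def test_unknown_label_is_error(self):
        tree = self._simple_tree()
        with pytest.raises(ValueError):
            is_monophyletic(tree, {"zzz"})

    def test_nonbf_clade_on_synthetic_classes(self, blosum):
        """Diverged synthetic classes yield a separate non-BF clade."""
        records, labels, reference = generate_clade_dataset(
            n_bf=5, n_nonbf=5, seed=101)
        rows = star_alignment(records, reference, blosum)
        rows.pop(reference.id)
        trimmed, _ = trim_columns(list(rows.values()), 0.5)
        dm = distance_matrix(dict(zip(rows.keys(), trimmed)), model="poisson")
        tree = neighbor_joining(dm)
        nonbf = {i for i, c in labels.items() if c == "nonBF"}
        assert is_monophyletic(tree, nonbf)[0]


def test_star_alignment_row_lengths(scaffold, blosum):
    from hydbeta.synth import plant_sequence
    recs = [plant_sequence(scaffold, "BF", background_identity=0.8, seed=s)[0]
            for s in (1, 2)]
    rows = star_alignment(recs, scaffold.record, blosum)
    assert set(len(r) for r in rows.values()) == {len(scaffold.record)}
    assert rows[scaffold.record.id] == scaffold.record.residues
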