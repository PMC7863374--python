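import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microbeta import diversity as dv
from microbeta.io_formats import OtuTable, TaxonomyMap

import oracles


class TestAlpha:
    def test_shannon_single_otu(self):
        assert dv.shannon([7]) == 0.0

    def test_shannon_uniform(self):
        assert dv.shannon([5, 5, 5, 5]) == pytest.approx(math.log(4))

    def test_shannon_532(self):
        # hand evaluation of -sum p ln p for p = .5, .3, .2
        assert dv.shannon([5, 3, 2]) == pytest.approx(1.0296530140645737)

    def test_shannon_zero_padding_invariant(self):
        assert dv.shannon([5, 3, 2, 0, 0]) == dv.shannon([5, 3, 2])

    def test_shannon_all_zero_errors(self):
        with pytest.raises(ValueError):
            dv.shannon([0, 0])

    def test_berger_parker_cases(self):
        assert dv.berger_parker([9]) == 1.0
        assert dv.berger_parker([2, 2, 2, 2]) == pytest.approx(0.25)
        assert dv.berger_parker([5, 3, 2]) == pytest.approx(0.5)

    def test_opposite_movement_on_skew(self):
        # two-OTU profiles: as skew grows shannon falls, berger-parker rises
        shannons, bps = [], []
        for hi in (5, 6, 8, 9):
            shannons.append(dv.shannon([hi, 10 - hi]))
            bps.append(dv.berger_parker([hi, 10 - hi]))
        assert shannons == sorted(shannons, reverse=True)
        assert bps == sorted(bps)

    def test_alpha_diversity_table(self, small_table):
        res = dv.alpha_diversity(small_table)
        assert [r.sample_id for r in res] == list(small_table.sample_ids)
        r3 = res[2]  # uniform over 4 OTUs
        assert r3.shannon == pytest.approx(math.log(4))
        assert r3.richness == 4
        for r in res:
            assert 0 <= r.shannon <= math.log(r.richness) + 1e-12
            assert 0 < r.berger_parker <= 1


class TestWeightedUnifrac:
    def test_identical_profiles_zero(self, quartet_table, four_leaf_tree):
        assert dv.weighted_unifrac(quartet_table, four_leaf_tree, "sa", "sa") == 0.0

    def test_disjoint_subtrees_saturate(self, quartet_table, four_leaf_tree):
        # hand summation: raw 4, normalizer 4
        assert dv.weighted_unifrac(quartet_table, four_leaf_tree, "sa", "sc") == pytest.approx(1.0)

    def test_sister_leaves_half(self, quartet_table, four_leaf_tree):
        # hand summation: raw 2, normalizer 4
        assert dv.weighted_unifrac(quartet_table, four_leaf_tree, "sa", "sb") == pytest.approx(0.5)

    def test_partial_overlap_quarter(self, quartet_table, four_leaf_tree):
        # hand summation: raw 1 (A 0.5 + B 0.5), normalizer 4
        assert dv.weighted_unifrac(quartet_table, four_leaf_tree, "sa", "sab") == pytest.approx(0.25)

    def test_scaling_invariance(self, four_leaf_tree):
        t1 = OtuTable(("x", "y"), ("A", "B", "C", "D"), np.array([[3, 1, 0, 0], [0, 0, 2, 2]]))
        t2 = OtuTable(("x", "y"), ("A", "B", "C", "D"), np.array([[30, 10, 0, 0], [0, 0, 20, 20]]))
        d1 = dv.weighted_unifrac(t1, four_leaf_tree, "x", "y")
        d2 = dv.weighted_unifrac(t2, four_leaf_tree, "x", "y")
        assert d1 == pytest.approx(d2)

    def test_missing_leaf_errors(self, four_leaf_tree):
        table = OtuTable(("x", "y"), ("A", "E"), np.array([[1, 1], [2, 0]]))
        with pytest.raises(ValueError, match="E"):
            dv.weighted_unifrac(table, four_leaf_tree, "x", "y")

    def test_range_on_random_profiles(self, four_leaf_tree):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = rng.integers(0, 20, size=(2, 4))
            if counts.sum(axis=1).min() == 0:
                continue
            table = OtuTable(("x", "y"), ("A", "B", "C", "D"), counts)
            d = dv.weighted_unifrac(table, four_leaf_tree, "x", "y")
            assert 0 <= d <= 1 + 1e-12

    def test_zero_iff_identical(self, four_leaf_tree):
        table = OtuTable(("x", "y"), ("A", "B", "C", "D"), np.array([[2, 4, 0, 1], [4, 8, 0, 2]]))
        assert dv.weighted_unifrac(table, four_leaf_tree, "x", "y") == pytest.approx(0.0, abs=1e-12)
        table2 = OtuTable(("x", "y"), ("A", "B", "C", "D"), np.array([[2, 4, 0, 1], [2, 4, 1, 0]]))
        assert dv.weighted_unifrac(table2, four_leaf_tree, "x", "y") > 0

    def test_against_scikit_bio(self, default_dataset, tmp_path):
        """Independent implementation oracle on real-sized data."""
        skbio = pytest.importorskip("skbio")

        from microbeta.io_formats import write_tree

        ds = default_dataset
        table = ds.table.select_samples(ds.table.sample_ids[:6])
        tree_path = tmp_path / "tree.nwk"
        write_tree(ds.tree, tree_path)
        sk_tree = skbio.TreeNode.read(str(tree_path))
        ours = dv.distance_matrix(table, "wunifrac", tree=ds.tree)
        for i in range(3):
            for j in range(i + 1, 4):
                theirs = skbio.diversity.beta.weighted_unifrac(
                    table.counts[i],
                    table.counts[j],
                    taxa=list(table.otu_ids),
                    tree=sk_tree,
                    normalized=True,
                )
                assert ours.values[i, j] == pytest.approx(theirs, abs=1e-10)


class TestHistogramEncoding:
    def _two_phyla(self):
        counts = np.array([[10, 9, 8, 7, 6, 5, 4, 3]])
        otus = tuple(f"o{i}" for i in range(8))
        table = OtuTable(("s",), otus, counts)
        tax = TaxonomyMap(
            {o: ("Bacteria", "Firmicutes" if i < 4 else "Proteobacteria") for i, o in enumerate(otus)}
        )
        return table, tax

    def test_bijection_when_bins_cover_otus(self, default_dataset):
        table, tax = default_dataset.table, default_dataset.taxonomy
        nonzero = int((table.otu_totals() > 0).sum())
        enc = dv.build_histogram_encoding(table, tax, n_bins=min(69, nonzero))
        assert enc.n_bins == min(69, nonzero)
        if nonzero <= 69:
            assert len(set(enc.bin_of_otu.values())) == nonzero

    def test_intra_below_inter_separation(self):
        table, tax = self._two_phyla()
        enc = dv.build_histogram_encoding(table, tax, n_bins=8)
        gd = dv.ground_distance(enc)
        blocks = list(enc.phylum_bins.values())
        intra = max(
            gd[i, j] for block in blocks for i in block for j in block if i != j
        )
        inter = min(gd[i, j] for i in blocks[0] for j in blocks[1])
        assert intra < inter

    def test_all_zero_otu_ignored(self):
        table, tax = self._two_phyla()
        enc1 = dv.build_histogram_encoding(table, tax, n_bins=8)
        counts2 = np.hstack([table.counts, [[0]]])
        table2 = OtuTable(("s",), table.otu_ids + ("zzz",), counts2)
        tax2 = TaxonomyMap({**{o: tax[o] for o in tax}, "zzz": ("Bacteria", "Firmicutes")})
        enc2 = dv.build_histogram_encoding(table2, tax2, n_bins=8)
        assert enc1.bin_of_otu == enc2.bin_of_otu
        np.testing.assert_array_equal(enc1.colors, enc2.colors)

    def test_no_white_bin(self, default_dataset):
        enc = dv.build_histogram_encoding(default_dataset.table, default_dataset.taxonomy)
        dist_to_white = np.linalg.norm(enc.colors - 1.0, axis=1)
        assert (dist_to_white > 0.3).all()

    def test_too_few_bins_errors(self):
        table, tax = self._two_phyla()
        with pytest.raises(ValueError, match="phyla"):
            dv.build_histogram_encoding(table, tax, n_bins=1)

    def test_bin_profile_normalized(self, default_dataset):
        table, tax = default_dataset.table, default_dataset.taxonomy
        enc = dv.build_histogram_encoding(table, tax)
        h = enc.bin_profile(table.counts[0], table.otu_ids)
        assert h.sum() == pytest.approx(1.0)
        assert (h >= 0).all()


class TestEmd:
    def test_identical_zero(self):
        gd = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert dv.emd([0.5, 0.5], [0.5, 0.5], gd) == pytest.approx(0.0)

    def test_point_masses_cost_gd(self):
        gd = np.array([[0.0, 0.3, 0.9], [0.3, 0.0, 0.4], [0.9, 0.4, 0.0]])
        assert dv.emd([1, 0, 0], [0, 0, 1], gd) == pytest.approx(0.9)

    def test_three_bin_oracle(self):
        gd = np.array([[0.0, 0.2, 1.0], [0.2, 0.0, 0.7], [1.0, 0.7, 0.0]])
        ours = dv.emd([0.5, 0.5, 0.0], [0.0, 0.5, 0.5], gd)
        oracle = oracles.emd_bruteforce([2, 2, 0], [0, 2, 2], gd, denom=4)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_uniform_gd_is_total_variation(self):
        rng = np.random.default_rng(0)
        gd = 1.0 - np.eye(5)
        for _ in range(20):
            a = rng.dirichlet(np.ones(5))
            b = rng.dirichlet(np.ones(5))
            tv = 0.5 * np.abs(a - b).sum()
            assert dv.emd(a, b, gd) == pytest.approx(tv, abs=1e-8)

    def test_metric_axioms_sampled(self):
        rng = np.random.default_rng(2)
        pts = rng.random((6, 3))
        gd = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        for _ in range(60):
            a, b, c = (rng.dirichlet(np.ones(6)) for _ in range(3))
            dab = dv.emd(a, b, gd)
            dba = dv.emd(b, a, gd)
            dac = dv.emd(a, c, gd)
            dcb = dv.emd(c, b, gd)
            assert dab >= 0
            assert dab == pytest.approx(dba, abs=1e-8)
            assert dab <= dac + dcb + 1e-8

    def test_sanity_envelope(self):
        rng = np.random.default_rng(3)
        gd = np.array([[0.0, 0.2, 0.5], [0.2, 0.0, 0.3], [0.5, 0.3, 0.0]])
        min_pos = 0.2
        for _ in range(20):
            a = rng.dirichlet(np.ones(3))
            b = rng.dirichlet(np.ones(3))
            d = dv.emd(a, b, gd)
            tv = 0.5 * np.abs(a - b).sum()
            assert tv * min_pos - 1e-9 <= d <= gd.max() + 1e-9

    def test_unnormalized_rejected(self):
        gd = 1.0 - np.eye(2)
        with pytest.raises(ValueError, match="sum to 1"):
            dv.emd([0.7, 0.7], [0.5, 0.5], gd)


class TestDistanceMatrix:
    def test_pair_count_46(self, default_dataset):
        table = default_dataset.table
        dm = dv.distance_matrix(table, "wunifrac", tree=default_dataset.tree)
        assert table.n_samples == 46
        assert len(dm.condensed()) == 1035

    def test_two_sample_matrix(self, quartet_table, four_leaf_tree):
        pair = quartet_table.select_samples(["sa", "sb"])
        dm = dv.distance_matrix(pair, "wunifrac", tree=four_leaf_tree)
        d = dm.values[0, 1]
        np.testing.assert_allclose(dm.values, [[0, d], [d, 0]])

    def test_relabeling_equivariance(self, default_dataset):
        table = default_dataset.table.select_samples(default_dataset.table.sample_ids[:6])
        dm = dv.distance_matrix(table, "wunifrac", tree=default_dataset.tree)
        perm = [3, 1, 0, 5, 4, 2]
        permuted = table.select_samples([table.sample_ids[i] for i in perm])
        dm2 = dv.distance_matrix(permuted, "wunifrac", tree=default_dataset.tree)
        np.testing.assert_allclose(dm2.values, dm.values[np.ix_(perm, perm)], atol=1e-12)

    def test_emd_matrix_symmetric_zero_diag(self, small_generator_config):
        from microbeta.synthetic_data import generate_dataset

        ds = generate_dataset(small_generator_config)
        dm = dv.distance_matrix(ds.table, "emd", taxonomy=ds.taxonomy)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)

    def test_missing_companions_error(self, small_table):
        with pytest.raises(ValueError):
            dv.distance_matrix(small_table, "wunifrac")
        with pytest.raises(ValueError):
            dv.distance_matrix(small_table, "emd")


class TestSaturationSummary:
    def _dm(self, vals):
        from microbeta.io_formats import DistanceMatrix

        return DistanceMatrix(tuple("abcd"), np.asarray(vals))

    def test_all_zero(self):
        dm = self._dm(np.zeros((4, 4)))
        assert dv.saturation_summary(dm, 0.9) == (0.0, 0.0, 0, 0.0)

    def test_hand_counted(self):
        vals = np.zeros((4, 4))
        pairs = {(0, 1): 0.95, (0, 2): 0.5, (0, 3): 0.91, (1, 2): 0.2, (1, 3): 0.9, (2, 3): 0.99}
        for (i, j), v in pairs.items():
            vals[i, j] = vals[j, i] = v
        dm = self._dm(vals)
        mean, sd, above, frac = dv.saturation_summary(dm, 0.9)
        data = list(pairs.values())
        assert mean == pytest.approx(np.mean(data))
        assert sd == pytest.approx(np.std(data, ddof=1))
        assert above == 3  # 0.95, 0.91, 0.99; 0.90 is not strictly above
        assert frac == pytest.approx(0.5)

    def test_threshold_zero_on_positive(self):
        vals = np.full((4, 4), 0.4)
        np.fill_diagonal(vals, 0)
        dm = self._dm(vals)
        *_, frac = dv.saturation_summary(dm, 0.0)
        assert frac == 1.0
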