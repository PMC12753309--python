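import numpy as np
import pandas as pd
import pytest

import sedabench as sb
from sedabench.beta_diversity import (rf_proximity_distance, unifrac_matrix,
                                      _interaction_adjusted)
from sedabench.datatypes import TransformedMatrix

import _oracles as oracle

FORMULA_INDICES = ["euclidean", "bray", "canberra", "kulczynski", "horn",
                   "gower", "alt_gower", "pearson", "spearman"]
BOUNDED_INDICES = ["bray", "canberra", "kulczynski", "horn", "chao",
                   "tina_w", "pina_w", "w_unifrac", "g_unifrac_05",
                   "vaw_unifrac"]


def _dist(counts, index, **kwargs):
    tm = TransformedMatrix(counts.astype(float), method="raw")
    return sb.distance(tm, sb.DistanceOptions(index=index, **kwargs))


class TestHandValues:
    def test_bray_example(self):
        frame = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["x", "y"],
                             columns=list("abc"))
        assert np.isclose(_dist(frame, "bray").data[0, 1], 1 / 3)

    def test_canberra_disjoint(self):
        frame = pd.DataFrame([[1, 0], [0, 1]], index=["x", "y"],
                             columns=list("ab"))
        assert np.isclose(_dist(frame, "canberra").data[0, 1], 1.0)

    def test_identical_samples_zero(self):
        frame = pd.DataFrame([[2, 5, 9], [2, 5, 9]], index=["x", "y"],
                             columns=list("abc"))
        for index in ("bray", "euclidean", "horn", "kulczynski", "canberra"):
            assert _dist(frame, "bray").data[0, 1] == 0

    def test_pearson_perfect_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        frame = pd.DataFrame([x, 2 * x + 1], index=["x", "y"],
                             columns=list("abcd"))
        assert np.isclose(_dist(frame, "pearson").data[0, 1], 0.0, atol=1e-12)

    def test_weighted_unifrac_two_tip_star(self):
        from skbio import TreeNode
        import io
        tree = TreeNode.read(io.StringIO("(t0:1.0,t1:1.0);"))
        x = np.array([[10.0, 0.0], [0.0, 5.0]])
        d = unifrac_matrix(x, ["t0", "t1"], tree, variant="weighted")
        assert np.isclose(d[0, 1], 1.0)
        # cross-check against the closed form on the two-branch tree
        expected = oracle.weighted_unifrac_two_tips(
            np.array([1.0, 0.0]), np.array([0.0, 1.0]), 1.0, 1.0)
        assert np.isclose(d[0, 1], expected)


class TestOracleEquivalence:
    @pytest.mark.parametrize("index", FORMULA_INDICES)
    def test_formula_indices_match_bruteforce(self, small_counts, index):
        mine = _dist(small_counts, index).data
        x = small_counts.to_numpy().astype(float)
        fns = {"euclidean": lambda a, b: np.sqrt(((a - b) ** 2).sum()),
               "bray": oracle.bray, "canberra": oracle.canberra,
               "kulczynski": oracle.kulczynski, "horn": oracle.horn,
               "alt_gower": oracle.alt_gower, "pearson": oracle.pearson_dist,
               "spearman": oracle.spearman_dist}
        if index == "gower":
            ref = oracle.gower_matrix(x)
        else:
            ref = oracle.pair_matrix(x, fns[index])
        assert np.allclose(mine, ref, atol=1e-8)

    def test_vegan_frozen_values(self, small_counts):
        """Spot-frozen vegdist values (vegan 2.7) for the fixture matrix."""
        expected = {"bray": 0.32692308, "canberra": 0.43748709,
                    "kulczynski": 0.29735758, "horn": 0.18364861,
                    "gower": 0.45890000, "chao": 0.0}
        for index, value in expected.items():
            d = _dist(small_counts, index, raw_counts=small_counts)
            assert np.isclose(d.data[1, 0], value, atol=1e-7), index

    def test_live_vegan_crosscheck(self, small_counts, tmp_path):
        import subprocess

        mat = tmp_path / "m.tsv"
        np.savetxt(mat, small_counts.to_numpy(), fmt="%d", delimiter="\t")
        script = (
            'suppressMessages(library(vegan));'
            f'x <- as.matrix(read.table("{mat}"));'
            'for (m in c("bray","canberra","kulczynski","horn","altGower","chao"))'
            '{d <- as.matrix(vegdist(x, method=m));'
            'cat(m, sprintf("%.10f", d[2,1]), sprintf("%.10f", d[5,3]), "\\n")}')
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True, check=True)
        name_map = {"altGower": "alt_gower"}
        for line in proc.stdout.strip().splitlines():
            rname, v21, v53 = line.split()
            index = name_map.get(rname, rname)
            d = _dist(small_counts, index, raw_counts=small_counts).data
            assert np.isclose(d[1, 0], float(v21), atol=1e-8), index
            assert np.isclose(d[4, 2], float(v53), atol=1e-8), index

    def test_weighted_unifrac_matches_skbio(self, small_counts, annotations_10):
        from skbio.diversity import beta_diversity

        x = small_counts.to_numpy(dtype=float)
        mine = unifrac_matrix(x, list(small_counts.columns), annotations_10.tree)
        ref = beta_diversity("weighted_unifrac", x,
                             ids=list(small_counts.index),
                             taxa=list(small_counts.columns),
                             tree=annotations_10.tree, normalized=True).data
        assert np.allclose(mine, ref, atol=1e-10)


class TestUniFracProperties:
    def test_generalized_alpha_one_equals_weighted(self, small_counts,
                                                   annotations_10):
        x = small_counts.to_numpy(dtype=float) + 1.0
        w = unifrac_matrix(x, list(small_counts.columns), annotations_10.tree,
                           variant="weighted")
        g = unifrac_matrix(x, list(small_counts.columns), annotations_10.tree,
                           variant="generalized", alpha=1.0)
        assert np.allclose(w, g, atol=1e-8)

    @pytest.mark.parametrize("variant", ["weighted", "generalized", "vaw"])
    def test_identical_relative_abundances_give_zero(self, annotations_10,
                                                     variant):
        row = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        x = np.vstack([row, 2 * row, 5 * row])
        d = unifrac_matrix(x, [f"t{j}" for j in range(10)], annotations_10.tree,
                           variant=variant)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_missing_taxon_reported(self, small_counts, annotations_10):
        frame = small_counts.rename(columns={"t0": "mystery"})
        with pytest.raises(ValueError, match="mystery"):
            _dist(frame, "w_unifrac", tree=annotations_10.tree)


class TestAssociationAndInteraction:
    def test_abundance_association_properties(self, small_counts):
        tm = TransformedMatrix(small_counts.astype(float), method="raw")
        assoc = sb.taxon_association_matrix(tm, "abundance")
        a = assoc.to_numpy()
        assert np.allclose(np.diag(a), 1.0)
        assert np.allclose(a, a.T)
        assert a.min() >= 0 and a.max() <= 1

    def test_identical_profiles_association_one(self):
        frame = pd.DataFrame({"ta": [1, 5, 9], "tb": [2, 10, 18],
                              "tc": [9, 2, 4]},
                             index=["s0", "s1", "s2"]).astype(float)
        assoc = sb.taxon_association_matrix(
            TransformedMatrix(frame, method="raw"), "abundance")
        assert np.isclose(assoc.loc["ta", "tb"], 1.0)

    def test_constant_taxon_warns_and_gets_half(self):
        frame = pd.DataFrame({"ta": [1.0, 2, 3], "tb": [4.0, 4, 4],
                              "tc": [3.0, 1, 2]}, index=["s0", "s1", "s2"])
        with pytest.warns(UserWarning, match="constant"):
            assoc = sb.taxon_association_matrix(
                TransformedMatrix(frame, method="raw"), "abundance")
        assert np.isclose(assoc.loc["ta", "tb"], 0.5)

    def test_phylogenetic_endpoints(self, annotations_10):
        assoc = sb.taxon_association_matrix(None, "phylogenetic",
                                            tree=annotations_10.tree)
        a = assoc.to_numpy()
        assert np.allclose(np.diag(a), 1.0)
        off = a[~np.eye(a.shape[0], dtype=bool)]
        assert np.isclose(off.min(), 0.0)  # the most distant pair maps to 0

    def test_tina_identity_association_reduces_to_cosine(self, small_counts):
        x = small_counts.to_numpy(dtype=float) + 1.0
        d = _interaction_adjusted(x, np.eye(x.shape[1]))
        ref = oracle.pair_matrix(x, oracle.tina_identity)
        assert np.allclose(d, ref, atol=1e-10)

    def test_tina_identity_disjoint_taxa_distance_one(self):
        x = np.array([[5.0, 7, 0, 0], [0, 0, 3, 4]])
        d = _interaction_adjusted(x, np.eye(4))
        assert np.isclose(d[0, 1], 1.0)


class TestGeneralProperties:
    @pytest.mark.parametrize("index", FORMULA_INDICES + BOUNDED_INDICES)
    def test_symmetry_zero_diagonal_nonnegative(self, small_counts,
                                                annotations_10, index):
        d = _dist(small_counts, index, tree=annotations_10.tree,
                  raw_counts=small_counts, rf_trees=20).data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all()
        if index in BOUNDED_INDICES:
            assert d.max() <= 1.0 + 1e-9

    def test_rf_proximity_deterministic_under_seed(self, small_counts):
        x = small_counts.to_numpy(dtype=float)
        a = rf_proximity_distance(x, n_trees=30, seed=1)
        b = rf_proximity_distance(x, n_trees=30, seed=1)
        c = rf_proximity_distance(x, n_trees=30, seed=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_negative_input_rejected_for_nonneg_indices(self, small_counts):
        tm = sb.transform(small_counts, sb.TransformOptions(method="clr"))
        with pytest.raises(ValueError, match="nonnegative"):
            sb.distance(tm, sb.DistanceOptions(index="bray"))

    def test_compatibility_table(self):
        assert sb.is_compatible("prop", "bray")
        assert not sb.is_compatible("clr", "bray")
        assert not sb.is_compatible("kmer", "w_unifrac")
        assert sb.is_compatible("clr", "euclidean")
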