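import dendropy
import numpy as np
import pandas as pd
import pytest

from precocity import (
    bladj_calibrate,
    build_taxonomy_tree,
    lambda_transform,
    phylo_covariance,
    resolve_polytomies,
    simulate_yule_tree,
)
from precocity.errors import (
    CalibrationConflictError,
    DomainError,
    TaxonomyLookupError,
)
from precocity.phylogeny import is_ultrametric, node_depths, tree_to_newick


def get_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )


def mini_traits(rows):
    df = pd.DataFrame(rows, columns=["species", "family"])
    df["genus"] = df["species"].str.split("_").str[0]
    return df


class TestTaxonomyGrafting:
    def test_study_tree_has_30_tips(self, study_table, study_tree):
        tips = {leaf.taxon.label for leaf in study_tree.leaf_node_iter()}
        assert tips == set(study_table["species"])

    def test_lauraceae_subtree(self, study_tree):
        node = next(
            n
            for n in study_tree.preorder_node_iter()
            if n.label == "Lauraceae" or (n.taxon and n.taxon.label == "Lauraceae")
        )
        tips = [l.taxon.label for l in node.leaf_iter()]
        assert len(tips) == 5
        genera = {t.split("_")[0] for t in tips}
        assert genera == {"Neolitsea", "Litsea", "Machilus", "Cinnamomum"}

    def test_single_species_family_collapses_to_tip(self, study_tree):
        # Schisandraceae contributes one species: no internal family node
        labels = {
            n.label for n in study_tree.preorder_internal_node_iter() if n.label
        }
        assert "Schisandraceae" not in labels
        tips = {leaf.taxon.label for leaf in study_tree.leaf_node_iter()}
        assert "Illicium_anisatum" in tips

    def test_single_species_input_gives_single_tip(self):
        backbone = get_tree("((FamA,FamB)inner,FamC)root;")
        tree = build_taxonomy_tree(mini_traits([("X_y", "FamB")]), backbone)
        leaves = tree.leaf_nodes()
        assert len(leaves) == 1
        assert leaves[0].taxon.label == "X_y"

    def test_unmatched_family_is_reported(self):
        backbone = get_tree("((FamA,FamB)inner,FamC)root;")
        with pytest.raises(TaxonomyLookupError, match="FamZ"):
            build_taxonomy_tree(mini_traits([("X_y", "FamZ")]), backbone)


class TestBladjCalibration:
    def test_even_spacing_along_uncalibrated_chain(self):
        tree = get_tree("(((A)n2)n1,B)root;")
        out = bladj_calibrate(tree, {"root": 90.0})
        ages = {n.label: n.age for n in out.preorder_node_iter() if n.label}
        assert ages["n1"] == pytest.approx(60.0)
        assert ages["n2"] == pytest.approx(30.0)

    def test_spacing_below_a_fixed_interior_node(self):
        tree = get_tree("(((A)n2)n1,B)root;")
        out = bladj_calibrate(tree, {"root": 90.0, "n1": 45.0})
        ages = {n.label: n.age for n in out.preorder_node_iter() if n.label}
        assert ages["n1"] == pytest.approx(45.0)
        assert ages["n2"] == pytest.approx(22.5)

    def test_calibration_round_trip(self, study_tree):
        # node ages recomputed from the branch lengths reproduce the inputs
        from precocity import load_node_ages

        ages = load_node_ages()
        depths = node_depths(study_tree)
        root_age = max(d for n, d in depths.items() if n.is_leaf())
        for node, depth in depths.items():
            name = node.label or (node.taxon.label if node.taxon else None)
            if name in ages and not node.is_leaf():
                assert root_age - depth == pytest.approx(ages[name], abs=1e-9)

    def test_result_is_ultrametric(self, study_tree):
        assert is_ultrametric(study_tree)

    def test_child_older_than_parent_conflicts(self):
        tree = get_tree("((A,B)n1,C)root;")
        with pytest.raises(CalibrationConflictError, match="n1"):
            bladj_calibrate(tree, {"root": 90.0, "n1": 95.0})


class TestPolytomyResolution:
    def test_resolution_is_binary_with_zero_length_insertions(self):
        tree = bladj_calibrate(get_tree("(A,B,C,D)root;"), {"root": 10.0})
        out = resolve_polytomies(tree, seed=1)
        for node in out.preorder_internal_node_iter():
            assert len(node.child_nodes()) == 2
        assert is_ultrametric(out)

    def test_deterministic_given_seed(self):
        tree = bladj_calibrate(get_tree("(A,B,C,D,E)root;"), {"root": 10.0})
        n1 = tree_to_newick(resolve_polytomies(tree, seed=7))
        n2 = tree_to_newick(resolve_polytomies(tree, seed=7))
        assert n1 == n2

    def test_binary_tree_unchanged(self):
        tree = bladj_calibrate(get_tree("((A,B)n1,C)root;"), {"root": 10.0})
        assert tree_to_newick(resolve_polytomies(tree, seed=1)) == tree_to_newick(
            tree
        )

    def test_covariance_invariant_under_resolution(self, study_table):
        unresolved = bladj_calibrate(
            build_taxonomy_tree(study_table), {"angiosperms": 100.0}
        )
        c0 = phylo_covariance(unresolved)
        c1 = phylo_covariance(resolve_polytomies(unresolved, seed=3)).reorder(
            list(c0.taxa)
        )
        np.testing.assert_allclose(c1.matrix, c0.matrix, atol=1e-12)


class TestCovariance:
    def test_cherry_from_root(self):
        C = phylo_covariance(get_tree("(A:2.5,B:2.5)root;"))
        np.testing.assert_allclose(C.matrix, 2.5 * np.eye(2))

    def test_three_taxon_path_arithmetic(self):
        C = phylo_covariance(get_tree("((A:1,B:1)n:1,C:2)root;")).reorder(
            ["A", "B", "C"]
        )
        np.testing.assert_allclose(
            C.matrix, [[2, 1, 0], [1, 2, 0], [0, 0, 2]], atol=1e-12
        )

    def test_star_tree_is_scaled_identity(self):
        C = phylo_covariance(get_tree("(A:3,B:3,C:3,D:3)root;"))
        np.testing.assert_allclose(C.matrix, 3.0 * np.eye(4))

    def test_reorder_permutes_consistently(self, study_cov):
        perm = list(reversed(study_cov.taxa))
        C2 = study_cov.reorder(perm)
        idx = [study_cov.taxa.index(t) for t in perm]
        np.testing.assert_array_equal(
            C2.matrix, study_cov.matrix[np.ix_(idx, idx)]
        )


class TestLambdaTransform:
    def test_identity_at_one(self, study_cov):
        np.testing.assert_array_equal(
            lambda_transform(study_cov, 1.0).matrix, study_cov.matrix
        )

    def test_diagonal_at_zero(self, study_cov):
        np.testing.assert_array_equal(
            lambda_transform(study_cov, 0.0).matrix,
            np.diag(np.diag(study_cov.matrix)),
        )

    def test_out_of_range_rejected(self, study_cov):
        with pytest.raises(DomainError):
            lambda_transform(study_cov, 1.2)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0])
    def test_positive_semidefinite_on_random_ultrametric_trees(self, seed, lam):
        C = phylo_covariance(simulate_yule_tree(12, seed=seed))
        eig = np.linalg.eigvalsh(lambda_transform(C, lam).matrix)
        assert eig.min() > -1e-9 * eig.max()


class TestNewickIO:
    def test_write_read_write_idempotent(self, study_tree, tmp_path):
        from precocity import read_tree, write_tree

        p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
        write_tree(study_tree, p1)
        t2 = read_tree(p1)
        write_tree(t2, p2)
        assert p1.read_text() == p2.read_text()
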