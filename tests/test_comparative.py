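"""Cross-species matrices, Spearman clustering and segregation."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from pancscan.comparative import (
    average_linkage,
    build_joint_matrix,
    segregation_score,
    spearman_matrix,
)
from pancscan.pairing import LACKING, PARTNERED, OrthologTable

SPECIES = ["sp1", "sp2", "sp3"]
TISSUES = ["heart", "liver"]


def toy_world(partnered_in=None):
    """Three species, five ortholog groups (one incomplete)."""
    rng = np.random.default_rng(3)
    wide = pd.DataFrame({sp: [f"g{i}_{sp}" for i in range(5)]
                         for sp in SPECIES})
    wide.loc[4, "sp2"] = np.nan
    orth = OrthologTable.from_groups(wide)
    expr, classes = {}, {}
    for sp in SPECIES:
        genes = [f"g{i}_{sp}" for i in range(5)]
        expr[sp] = pd.DataFrame(rng.random((5, 2)) + 0.1,
                                index=genes, columns=TISSUES)
        lab = [PARTNERED if (partnered_in or {}).get(i) == sp else LACKING
               for i in range(5)]
        classes[sp] = pd.DataFrame({"gene_id": genes, "r": 0.0, "p": 1.0,
                                    "klass": lab})
    return orth, expr, classes


class TestJointMatrix:
    def test_incomplete_groups_dropped(self):
        orth, expr, _ = toy_world()
        joint = build_joint_matrix(expr, orth, mode="mrna")
        assert joint.shape == (4, 6)
        assert not joint.isna().any().any()

    def test_panc_any_includes_single_species_partnering(self):
        orth, expr, classes = toy_world(partnered_in={0: "sp1"})
        joint = build_joint_matrix(expr, orth, mode="panc_any",
                                   classes_by_species=classes)
        assert joint.shape[0] == 1  # only the group partnered somewhere

    def test_conserved_subset_of_any(self):
        part = {i: sp for i, sp in enumerate(SPECIES)}
        orth, expr, classes = toy_world(partnered_in=part)
        any_m = build_joint_matrix(expr, orth, "panc_any", classes)
        cons = build_joint_matrix(expr, orth, "panc_conserved", classes)
        assert set(cons.index) <= set(any_m.index)

    def test_missing_tissue_rejected(self):
        orth, expr, _ = toy_world()
        expr["sp2"] = expr["sp2"][["heart"]]
        with pytest.raises(ValueError, match="sp2"):
            build_joint_matrix(expr, orth, mode="mrna")


class TestSpearman:
    def test_matches_rank_then_pearson_oracle(self, rng):
        joint = pd.DataFrame(rng.random((6, 4)), columns=list("wxyz"))
        out = spearman_matrix(joint)
        oracle, _ = spearmanr(joint.to_numpy())
        assert np.allclose(out.to_numpy(), oracle, atol=1e-12)

    def test_duplicate_and_reversed_samples(self):
        base = pd.Series([1.0, 3, 2, 5, 4])
        joint = pd.DataFrame({"a": base, "b": base,
                              "c": base.max() - base + 1})
        out = spearman_matrix(joint)
        assert out.loc["a", "b"] == pytest.approx(1.0)
        assert out.loc["a", "c"] == pytest.approx(-1.0)

    def test_constant_column_flagged_undefined(self):
        joint = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        out = spearman_matrix(joint)
        assert np.isnan(out.loc["a", "b"])
        assert out.loc["b", "b"] == 1.0

    def test_invariant_under_monotone_transform(self, rng):
        joint = pd.DataFrame(rng.random((30, 4)), columns=list("wxyz"))
        warped = joint.copy()
        warped["x"] = np.exp(5 * warped["x"])   # strictly increasing
        a = spearman_matrix(joint)
        b = spearman_matrix(warped)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


def corr_from_dist(d: dict, labels: list) -> pd.DataFrame:
    n = len(labels)
    mat = pd.DataFrame(np.ones((n, n)), index=labels, columns=labels)
    for (a, b), dist in d.items():
        mat.loc[a, b] = mat.loc[b, a] = 1 - dist
    return mat


class TestAverageLinkage:
    def test_three_leaf_hand_computed(self):
        corr = corr_from_dist({("A", "B"): 0.1, ("A", "C"): 0.4,
                               ("B", "C"): 0.4}, ["A", "B", "C"])
        dend = average_linkage(corr)
        assert dend.heights == pytest.approx([0.1, 0.4])
        assert dend.to_newick() == "((A:0.1,B:0.1):0.3,C:0.4);"

    def test_four_leaf_hand_computed(self):
        # AB merge at 0.1; C joins at mean(0.3, 0.5) = 0.4; D at 0.8
        corr = corr_from_dist(
            {("A", "B"): 0.1, ("A", "C"): 0.3, ("B", "C"): 0.5,
             ("A", "D"): 0.8, ("B", "D"): 0.8, ("C", "D"): 0.8},
            ["A", "B", "C", "D"])
        dend = average_linkage(corr)
        assert dend.heights == pytest.approx([0.1, 0.4, 0.8])

    def test_identical_samples_star_at_zero(self):
        corr = corr_from_dist({("A", "B"): 0.0, ("A", "C"): 0.0,
                               ("B", "C"): 0.0}, ["A", "B", "C"])
        dend = average_linkage(corr)
        assert dend.heights == pytest.approx([0.0, 0.0])

    def test_input_order_does_not_change_tree(self, rng):
        labels = list("ABCDEF")
        d = {}
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                d[(a, b)] = round(float(rng.random()), 3)
        corr = corr_from_dist(d, labels)
        ref = average_linkage(corr)
        perm = list(labels)
        rng.shuffle(perm)
        out = average_linkage(corr.loc[perm, perm])
        assert out.to_newick() == ref.to_newick()
        assert out.heights == pytest.approx(ref.heights)

    def test_heights_bounded_by_distance_range(self, rng):
        labels = list("ABCDE")
        d = {}
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                d[(a, b)] = float(rng.uniform(0.2, 0.9))
        dend = average_linkage(corr_from_dist(d, labels))
        assert min(d.values()) <= min(dend.heights)
        assert max(dend.heights) <= max(d.values())

    def test_newick_round_trips_through_biopython(self):
        from Bio import Phylo

        corr = corr_from_dist(
            {("A", "B"): 0.2, ("A", "C"): 0.6, ("B", "C"): 0.4},
            ["A", "B", "C"])
        dend = average_linkage(corr)
        tree = Phylo.read(io.StringIO(dend.to_newick()), "newick")
        leaves = sorted(t.name for t in tree.get_terminals())
        assert leaves == ["A", "B", "C"]
        # ultrametric: every leaf sits at the root height
        depths = tree.depths()
        leaf_depths = {t.name: d for t, d in depths.items() if t.name}
        assert np.allclose(list(leaf_depths.values()), max(dend.heights))

    def test_undefined_correlations_rejected(self):
        corr = corr_from_dist({("A", "B"): np.nan}, ["A", "B"])
        with pytest.raises(ValueError):
            average_linkage(corr)


class TestSegregation:
    def labels(self, pairs):
        return pd.DataFrame(pairs, columns=["species", "tissue"],
                            index=[f"{s}.{t}" for s, t in pairs])

    def block_corr(self, pairs, key):
        idx = [f"{s}.{t}" for s, t in pairs]
        n = len(pairs)
        mat = np.full((n, n), 0.1)
        for i in range(n):
            for j in range(n):
                if pairs[i][key] == pairs[j][key]:
                    mat[i, j] = 0.9
        np.fill_diagonal(mat, 1.0)
        return pd.DataFrame(mat, index=idx, columns=idx)

    def test_block_diagonal_by_species(self):
        pairs = [(s, t) for s in ("sp1", "sp2") for t in ("heart", "liver")]
        corr = self.block_corr(pairs, key=0)
        out = segregation_score(corr, self.labels(pairs))
        assert out["by_species"] == 1.0

    def test_block_diagonal_by_tissue(self):
        pairs = [(s, t) for s in ("sp1", "sp2") for t in ("heart", "liver")]
        corr = self.block_corr(pairs, key=1)
        out = segregation_score(corr, self.labels(pairs))
        assert out["by_tissue"] == 1.0

    def test_single_species_rejected(self):
        pairs = [("sp1", "heart"), ("sp1", "liver")]
        corr = self.block_corr(pairs, key=0)
        with pytest.raises(ValueError):
            segregation_score(corr, self.labels(pairs))
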