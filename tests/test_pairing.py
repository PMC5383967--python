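"""Pearson pairing, tissue-specificity index and species-level calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pancscan.matrix import ExpressionMatrix, sample_table
from pancscan.pairing import (
    INTERMEDIATE,
    LACKING,
    PARTNERED,
    UNDEFINED,
    OrthologTable,
    class_summary,
    classify_pairs,
    conserved_pancrna,
    pearson,
    species_specific,
    tissue_means,
    tsi,
    tsi_frame,
)

TISSUES = list("abcde")


def means_frame(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=TISSUES)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson(x, 2 * x + 1)[0] == 1.0
        assert pearson(x, -0.5 * x + 3)[0] == -1.0

    def test_matches_scipy_on_fixture(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        r, p = pearson(x, y)
        r_sp, p_sp = stats.pearsonr(x, y)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, abs=1e-12)
        assert r == pytest.approx(0.8219949365267863)

    def test_p_value_from_t_distribution(self):
        # r = 0.7 at n = 5 gives t = 1.698 on 3 df, two-sided p ~ 0.188
        r = 0.7
        n = 5
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        p = 2 * stats.t.sf(t, n - 2)
        assert p == pytest.approx(0.1881, abs=2e-4)

    def test_zero_variance_is_undefined_not_an_error(self):
        r, p = pearson([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])


class TestClassification:
    def test_threshold_classes(self):
        x = [1.0, 2, 3, 4, 10]
        mrna = means_frame({"hi": x, "lo": x, "mid": x, "zero": x, "flat": x})
        panc = means_frame({
            "hi": [1.1, 2, 3.2, 4, 9.5],          # r > 0.7
            "lo": [5, 1, 4, 2, 3],                # r ~ 0
            "mid": [4, 3, 2, 1, 7],               # between thresholds
            "zero": [0, 0, 0, 0, 0],              # no pancRNA at all
            "flat": [2, 2, 2, 2, 2],              # undefined r, nonzero panc
        })
        out = classify_pairs(mrna, panc).set_index("gene_id")
        assert out.loc["hi", "klass"] == PARTNERED
        assert out.loc["lo", "klass"] == LACKING
        assert out.loc["mid", "klass"] == INTERMEDIATE
        assert out.loc["zero", "klass"] == LACKING
        assert math.isnan(out.loc["zero", "r"])
        assert out.loc["flat", "klass"] == UNDEFINED

    def test_exact_threshold_falls_to_intermediate(self):
        # with r_high = 1 even a perfect correlation is not strictly above
        x = [1.0, 2, 3, 4, 5]
        mrna = means_frame({"g": x})
        panc = means_frame({"g": [2.0, 4, 6, 8, 10]})
        out = classify_pairs(mrna, panc, r_high=1.0, r_low=-1.0)
        assert out["klass"].iloc[0] == INTERMEDIATE

    def test_classes_partition_random_data(self, rng):
        mrna = pd.DataFrame(rng.random((200, 5)), columns=TISSUES)
        panc = pd.DataFrame(rng.random((200, 5)), columns=TISSUES)
        panc.iloc[:40] = 0.0
        out = classify_pairs(mrna, panc)
        assert len(out) == 200
        assert out["klass"].isin([PARTNERED, INTERMEDIATE, LACKING,
                                  UNDEFINED]).all()

    def test_mismatched_gene_sets_rejected(self):
        mrna = means_frame({"a": [1, 2, 3, 4, 5]})
        panc = means_frame({"b": [1, 2, 3, 4, 5]})
        with pytest.raises(ValueError, match="mismatched ids.*'a'"):
            classify_pairs(mrna, panc)

    def test_negative_tally_reported(self):
        x = [1.0, 2, 3, 4, 10]
        mrna = means_frame({"neg": x})
        panc = means_frame({"neg": [10.0, 5, 3, 2, 1]})
        out = classify_pairs(mrna, panc)
        assert class_summary(out)["n_negative"] == 1


class TestTissueMeans:
    def test_replicates_averaged_by_label(self):
        samples = sample_table([("sp", "cortex", "1"), ("sp", "cortex", "2"),
                                ("sp", "liver", "1")])
        values = pd.DataFrame([[4.0, 6.0, 10.0]], index=["g"],
                              columns=samples.index)
        mat = ExpressionMatrix(values, samples)
        out = tissue_means(mat)
        assert out.loc["g", "cortex"] == 5.0
        assert out.loc["g", "liver"] == 10.0  # single replicate passthrough
        assert list(out.columns) == ["cortex", "liver"]


class TestTsi:
    @pytest.mark.parametrize("vec,expected", [
        ([5, 5, 5, 5, 5], 0.0),
        ([10, 0, 0, 0, 0], 1.0),
        ([8, 2, 2, 2, 2], 0.75),
    ])
    def test_known_values(self, vec, expected):
        assert tsi(vec) == pytest.approx(expected)

    def test_all_zero_is_undefined(self):
        assert math.isnan(tsi([0, 0, 0]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=8),
           st.floats(1e-3, 1e3))
    def test_invariant_under_positive_scaling(self, vec, c):
        if max(vec) == 0:
            return
        v = np.asarray(vec)
        assert tsi(c * v) == pytest.approx(tsi(v), abs=1e-9)

    def test_frame_matches_scalar_and_argmax(self, rng):
        means = pd.DataFrame(rng.random((50, 5)), columns=TISSUES)
        frame = tsi_frame(means).set_index("gene_id")
        for g in [0, 7, 49]:
            assert frame["tsi"].iloc[g] == pytest.approx(tsi(means.iloc[g]))
        assert (frame["argmax_tissue"].to_numpy()
                == means.columns[means.to_numpy().argmax(axis=1)]).all()


def toy_classes(labels: dict) -> pd.DataFrame:
    return pd.DataFrame({"gene_id": list(labels), "r": 0.0, "p": 1.0,
                         "klass": list(labels.values())})


def toy_orthologs(n: int, species: list[str]) -> OrthologTable:
    wide = pd.DataFrame({sp: [f"g{i}_{sp}" for i in range(n)]
                         for sp in species})
    return OrthologTable.from_groups(wide)


class TestSpeciesSpecific:
    species = ["sp1", "sp2", "sp3", "sp4", "sp5"]

    def build(self, labels_by_gene):
        classes = {}
        for k, sp in enumerate(self.species):
            classes[sp] = toy_classes({
                f"g{i}_{sp}": labels[k] for i, labels in
                enumerate(labels_by_gene)})
        return classes

    def test_strict_all_lacking_rule(self):
        # g0: gained in sp1 only; g1: partnered twice; g2: one ortholog
        # merely intermediate -> excluded by the strict rule
        table = [
            [PARTNERED, LACKING, LACKING, LACKING, LACKING],
            [PARTNERED, LACKING, PARTNERED, LACKING, LACKING],
            [PARTNERED, INTERMEDIATE, LACKING, LACKING, LACKING],
        ]
        classes = self.build(table)
        orth = toy_orthologs(3, self.species)
        out = species_specific(classes, orth)
        assert out["gain"]["sp1"] == {"g0_sp1"}
        assert all(not out["gain"][sp] for sp in self.species[1:])

    def test_loss_side(self):
        table = [[LACKING, PARTNERED, PARTNERED, PARTNERED, PARTNERED]]
        out = species_specific(self.build(table), toy_orthologs(1, self.species))
        assert out["loss"]["sp1"] == {"g0_sp1"}

    def test_gain_sets_disjoint_across_species(self, rng):
        labels = rng.choice([PARTNERED, LACKING, INTERMEDIATE],
                            size=(60, 5), p=[0.4, 0.4, 0.2])
        out = species_specific(self.build(labels.tolist()),
                               toy_orthologs(60, self.species))
        seen = set()
        for sp in self.species:
            grp = {g.split("_")[0] for g in out["gain"][sp]}
            assert not (seen & grp)
            seen |= grp

    def test_incomplete_group_excluded(self):
        wide = pd.DataFrame({sp: [f"g0_{sp}"] for sp in self.species})
        wide.loc[0, "sp3"] = np.nan
        orth = OrthologTable.from_groups(wide)
        table = [[PARTNERED, LACKING, LACKING, LACKING, LACKING]]
        out = species_specific(self.build(table), orth)
        assert not out["gain"]["sp1"]


class TestConservedPanc:
    def test_requires_all_five(self):
        species = ["sp1", "sp2", "sp3", "sp4", "sp5"]
        table = [
            [PARTNERED] * 5,
            [PARTNERED] * 4 + [LACKING],
        ]
        classes = {}
        for k, sp in enumerate(species):
            classes[sp] = toy_classes({
                f"g{i}_{sp}": labels[k] for i, labels in enumerate(table)})
        out = conserved_pancrna(classes, toy_orthologs(2, species))
        assert len(out) == 1
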