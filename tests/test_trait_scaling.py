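"""Species summarisation rules and ecoregion-scale aggregation."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from antiherbiome import trait_scaling as ts


def records(*rows):
    return pd.DataFrame(rows, columns=["species_id", "trait", "value"])


class TestSummarizeSpecies:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ([("a", "WD", 0.5), ("a", "WD", 0.7)], 0.6),  # continuous -> mean
            ([("a", "StemSpines", 0), ("a", "StemSpines", 1), ("a", "StemSpines", 0)], 1.0),
            ([("a", "LeafSize", 12.5)], 12.5),  # single record unchanged
            ([("a", "Latex", 0), ("a", "Latex", 0)], 0.0),
        ],
    )
    def test_rules(self, rows, expected):
        out = ts.summarize_species(records(*rows))
        assert len(out) == 1
        assert out["value"].iloc[0] == expected
        assert out["n_records"].iloc[0] == len(rows)

    def test_negative_continuous_rejected_with_warning(self, caplog):
        rec = records(("a", "WD", 0.5), ("a", "WD", -0.2))
        with caplog.at_level(logging.WARNING):
            out = ts.summarize_species(rec)
        assert out["value"].iloc[0] == 0.5
        assert "negative" in caplog.text

    def test_binary_outside_01_raises(self):
        with pytest.raises(ValueError, match="binary"):
            ts.summarize_species(records(("a", "StemSpines", 0.5)))

    def test_unknown_trait_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            ts.summarize_species(records(("a", "Height", 3.0)))


def simple_world():
    occ = pd.DataFrame(
        {"A": [2, 0], "B": [1, 4]}, index=pd.Index(["e1", "e2"], name="ecoregion_id")
    )
    traits = pd.DataFrame(
        [("A", "WD", 0.4, 1), ("B", "WD", 0.7, 1),
         ("A", "StemSpines", 1.0, 1), ("B", "StemSpines", 0.0, 1)],
        columns=["species_id", "trait", "value", "n_records"],
    )
    return occ, traits


class TestWeightedMean:
    def test_hand_example(self):
        occ, traits = simple_world()
        out = ts.ecoregion_weighted_mean(occ, traits, "WD")
        assert out["e1"] == pytest.approx((2 * 0.4 + 1 * 0.7) / 3)
        assert out["e2"] == pytest.approx(0.7)

    def test_identical_values_invariant_to_abundance(self):
        occ, _ = simple_world()
        traits = pd.DataFrame(
            [("A", "WD", 0.9, 1), ("B", "WD", 0.9, 1)],
            columns=["species_id", "trait", "value", "n_records"],
        )
        out = ts.ecoregion_weighted_mean(occ, traits, "WD")
        assert (out == 0.9).all()

    def test_binary_trait_redirected(self):
        occ, traits = simple_world()
        with pytest.raises(ValueError, match="binary"):
            ts.ecoregion_weighted_mean(occ, traits, "StemSpines")

    def test_zero_coverage_is_missing(self):
        occ = pd.DataFrame({"A": [0, 3]}, index=pd.Index(["e1", "e2"], name="ecoregion_id"))
        traits = pd.DataFrame(
            [("A", "WD", 0.4, 1)], columns=["species_id", "trait", "value", "n_records"]
        )
        out = ts.ecoregion_weighted_mean(occ, traits, "WD")
        assert np.isnan(out["e1"]) and out["e2"] == pytest.approx(0.4)


class TestBinaryCounts:
    def test_hand_example(self):
        occ = pd.DataFrame({"A": [3], "B": [2]}, index=pd.Index(["e"], name="ecoregion_id"))
        traits = pd.DataFrame(
            [("A", "StemSpines", 1.0, 1), ("B", "StemSpines", 0.0, 1)],
            columns=["species_id", "trait", "value", "n_records"],
        )
        out = ts.ecoregion_binary_counts(occ, traits, "StemSpines")
        assert out.loc["e", "StemSpines_presences"] == 3
        assert out.loc["e", "StemSpines_absences"] == 2

    def test_no_spiny_species_boundary(self):
        occ = pd.DataFrame({"A": [5], "B": [2]}, index=pd.Index(["e"], name="ecoregion_id"))
        traits = pd.DataFrame(
            [("A", "Latex", 0.0, 1), ("B", "Latex", 0.0, 1)],
            columns=["species_id", "trait", "value", "n_records"],
        )
        out = ts.ecoregion_binary_counts(occ, traits, "Latex")
        assert out.loc["e", "Latex_presences"] == 0
        assert out.loc["e", "Latex_absences"] == 7


class TestPresenceFraction:
    def test_abundance_collapsed(self):
        occ = pd.DataFrame({"P1": [100], "P2": [1]}, index=pd.Index(["e"], name="ecoregion_id"))
        traits = pd.DataFrame(
            [("P1", "LeafSpines", 1.0, 1), ("P2", "LeafSpines", 0.0, 1)],
            columns=["species_id", "trait", "value", "n_records"],
        )
        out = ts.ecoregion_presence_fraction(occ, traits)
        assert out.loc["e", "LeafSpines_present_species"] == 1
        assert out.loc["e", "LeafSpines_absent_species"] == 1

    def test_no_palm_ecoregion_flagged(self):
        occ = pd.DataFrame(
            {"P1": [3, 0], "Q": [0, 5]}, index=pd.Index(["e1", "e2"], name="ecoregion_id")
        )
        traits = pd.DataFrame(
            [("P1", "LeafSpines", 1.0, 1)], columns=["species_id", "trait", "value", "n_records"]
        )
        out = ts.ecoregion_presence_fraction(occ, traits)
        assert out.loc["e2", "has_palms"] == False  # noqa: E712
        assert out.loc["e1", "has_palms"] == True  # noqa: E712

    def test_non_palms_excluded_and_logged(self, caplog):
        occ = pd.DataFrame({"P1": [2], "X1": [9]}, index=pd.Index(["e"], name="ecoregion_id"))
        traits = pd.DataFrame(
            [("P1", "LeafSpines", 1.0, 1), ("X1", "LeafSpines", 1.0, 1)],
            columns=["species_id", "trait", "value", "n_records"],
        )
        with caplog.at_level(logging.WARNING):
            out = ts.ecoregion_presence_fraction(occ, traits, palm_species={"P1"})
        assert "non-palm" in caplog.text
        assert out.loc["e", "LeafSpines_present_species"] == 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_cells", [1, 3])
    @pytest.mark.parametrize("seed", range(5))
    def test_random_fixture_matches_brute_force(self, seed, n_cells, occurrence_fixture, oracles):
        rng = np.random.default_rng(seed)
        occ, traits = occurrence_fixture(rng, n_eco=5, n_sp=8, n_cells=n_cells)
        got = ts.ecoregion_weighted_mean(occ, traits, "WD")
        want = oracles["weighted_mean"](occ, traits, "WD")
        pd.testing.assert_series_equal(
            got.sort_index(), want.sort_index(), check_names=False, check_index_type=False
        )
        counts = ts.ecoregion_binary_counts(occ, traits, "StemSpines")
        brute = oracles["binary_counts"](occ, traits, "StemSpines")
        assert (counts["StemSpines_presences"].sort_index().to_numpy()
                == brute["presences"].sort_index().to_numpy()).all()
        assert (counts["StemSpines_absences"].sort_index().to_numpy()
                == brute["absences"].sort_index().to_numpy()).all()
        pres = ts.ecoregion_presence_fraction(occ, traits)
        bp = oracles["presence_counts"](occ, traits)
        assert (pres["LeafSpines_present_species"].sort_index().to_numpy()
                == bp["present"].sort_index().to_numpy()).all()


class TestInvariants:
    def test_conservation(self, occurrence_fixture):
        rng = np.random.default_rng(42)
        occ, traits = occurrence_fixture(rng, n_eco=6, n_sp=10)
        counts = ts.ecoregion_binary_counts(occ, traits, "Latex")
        covered = occ.columns.intersection(
            traits.loc[traits["trait"] == "Latex", "species_id"]
        )
        total = occ[covered].sum(axis=1)
        assert (
            counts["Latex_presences"] + counts["Latex_absences"] == total
        ).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(k=hst.integers(min_value=1, max_value=9), seed=hst.integers(0, 100))
    def test_scale_equivariance(self, k, seed):
        rng = np.random.default_rng(seed)
        occ, traits = make_fixture_for_hypothesis(rng)
        base_mean = ts.ecoregion_weighted_mean(occ, traits, "WD")
        base_counts = ts.ecoregion_binary_counts(occ, traits, "StemSpines")
        scaled_mean = ts.ecoregion_weighted_mean(occ * k, traits, "WD")
        scaled_counts = ts.ecoregion_binary_counts(occ * k, traits, "StemSpines")
        pd.testing.assert_series_equal(base_mean, scaled_mean)
        assert (scaled_counts.to_numpy() == base_counts.to_numpy() * k).all()

    def test_single_index_equals_one_cell_multiindex(self, occurrence_fixture):
        rng = np.random.default_rng(7)
        occ, traits = occurrence_fixture(rng, n_eco=4, n_sp=6)
        multi = occ.copy()
        multi.index = pd.MultiIndex.from_arrays(
            [occ.index, [0] * len(occ)], names=["ecoregion_id", "cell"]
        )
        for trait in ("WD", "LeafSize"):
            pd.testing.assert_series_equal(
                ts.ecoregion_weighted_mean(occ, traits, trait),
                ts.ecoregion_weighted_mean(multi, traits, trait),
                check_index_type=False,
            )


def make_fixture_for_hypothesis(rng):
    from conftest import make_occurrence_fixture

    return make_occurrence_fixture(rng, n_eco=4, n_sp=6)
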