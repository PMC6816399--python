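import math

import numpy as np
import pytest

from rtshift.class_profiles import (
    LOW_ABUNDANCE_LABEL,
    ConditionProfile,
    aggregate_to_class,
    collapse_low_abundance,
    condition_profiles,
    diversity_indices,
    profiles_frame,
)
from rtshift.io_formats import OtuTable, TaxonomyMap
from tests.conftest import make_metadata


class TestAggregateToClass:
    def test_sums_member_otus(self, toy_table, toy_taxonomy):
        # OTU1, OTU2 -> Bacilli; OTU3 lacks a class rank -> Unclassified
        ct = aggregate_to_class(toy_table, toy_taxonomy)
        df = ct.to_frame()
        assert df.loc["S1", "Bacilli"] == 5 and df.loc["S1", "Unclassified"] == 3
        assert df.loc["S2", "Bacilli"] == 10 and df.loc["S2", "Unclassified"] == 2

    def test_reads_conserved_exactly(self, toy_table, toy_taxonomy):
        ct = aggregate_to_class(toy_table, toy_taxonomy)
        assert np.array_equal(ct.counts.sum(axis=1), toy_table.sample_totals())

    def test_single_class_collapses_to_row_sums(self):
        t = OtuTable(["S1"], ["a", "b"], np.array([[3, 4]]))
        tax = TaxonomyMap({o: ("B", "F", "Bacilli") for o in "ab"})
        ct = aggregate_to_class(t, tax)
        assert ct.class_labels == ["Bacilli"] and ct.counts.tolist() == [[7]]

    def test_no_phantom_zero_classes(self):
        t = OtuTable(["S1"], ["a", "b"], np.array([[3, 0]]))
        tax = TaxonomyMap({"a": ("B", "F", "Bacilli"), "b": ("B", "F", "Clostridia")})
        assert aggregate_to_class(t, tax).class_labels == ["Bacilli"]

    def test_missing_taxonomy_is_an_error(self, toy_table):
        tax = TaxonomyMap({"OTU1": ("B", "F", "Bacilli")})
        with pytest.raises(ValueError, match="OTU2"):
            aggregate_to_class(toy_table, tax)


class TestConditionProfiles:
    def test_mean_and_sample_sd_across_replicates(self, toy_taxonomy):
        # class fractions 0.2 and 0.4 across the two replicates
        t = OtuTable(["S1", "S2"], ["OTU1", "OTU3"], np.array([[2, 8], [4, 6]]))
        tax = TaxonomyMap({"OTU1": ("B", "F", "Bacilli"), "OTU3": ("B", "P")})
        meta = make_metadata({("E", 42): ["S1", "S2"]})
        profs = condition_profiles(aggregate_to_class(t, tax), meta)
        bac = next(p for p in profs if p.class_label == "Bacilli")
        assert bac.mean_rel_abund == pytest.approx(0.3)
        assert bac.sd_rel_abund == pytest.approx(np.std([0.2, 0.4], ddof=1))
        assert bac.n_replicates == 2

    def test_means_sum_to_one_within_condition(self, four_condition_meta):
        rng = np.random.default_rng(0)
        ids = list(four_condition_meta.enzyme)
        t = OtuTable(ids, [f"O{j}" for j in range(6)], rng.integers(1, 100, (16, 6)))
        tax = TaxonomyMap({f"O{j}": ("B", "P", f"C{j % 3}") for j in range(6)})
        profs = condition_profiles(aggregate_to_class(t, tax), four_condition_meta)
        sums: dict = {}
        for p in profs:
            sums[p.condition] = sums.get(p.condition, 0.0) + p.mean_rel_abund
        assert all(abs(s - 1) < 1e-9 for s in sums.values())

    def test_scale_free_in_each_sample(self):
        t1 = OtuTable(["S1", "S2"], ["a", "b"], np.array([[2, 8], [5, 5]]))
        t2 = OtuTable(["S1", "S2"], ["a", "b"], np.array([[20, 80], [5, 5]]))
        tax = TaxonomyMap({"a": ("B", "P", "X"), "b": ("B", "P", "Y")})
        meta = make_metadata({("E", 42): ["S1", "S2"]})
        p1 = profiles_frame(condition_profiles(aggregate_to_class(t1, tax), meta))
        p2 = profiles_frame(condition_profiles(aggregate_to_class(t2, tax), meta))
        assert np.allclose(p1["mean_rel_abund"], p2["mean_rel_abund"])

    def test_single_replicate_requires_opt_in(self):
        t = OtuTable(["S1"], ["a"], np.array([[5]]))
        tax = TaxonomyMap({"a": ("B", "P", "X")})
        meta = make_metadata({("E", 42): ["S1"]})
        ct = aggregate_to_class(t, tax)
        with pytest.raises(ValueError, match="single replicate"):
            condition_profiles(ct, meta)
        profs = condition_profiles(ct, meta, allow_single=True)
        assert profs[0].sd_rel_abund == 0.0


def _uniform_profiles(n_classes, cond=("E", 42.0)):
    return [
        ConditionProfile(cond, f"C{i:02d}", 1.0 / n_classes, 0.01, 4) for i in range(n_classes)
    ]


class TestCollapseLowAbundance:
    def _graded_profiles(self, k, with_unclassified=True):
        means = np.arange(k, 0, -1, dtype=float)
        means = means / means.sum()
        profs = [
            ConditionProfile(("E", 42.0), f"C{i:02d}", float(means[i]), 0.01, 4)
            for i in range(k)
        ]
        if with_unclassified:
            profs = [
                ConditionProfile(("E", 42.0), cls, p.mean_rel_abund * 0.98, p.sd_rel_abund, 4)
                for p, cls in zip(profs, [p.class_label for p in profs])
            ]
            profs.append(ConditionProfile(("E", 42.0), "Unclassified", 0.02, 0.005, 4))
        return profs

    def test_top_15_percent_of_20_classes_keeps_3(self):
        out = collapse_low_abundance(self._graded_profiles(20), top_fraction=0.15)
        labels = {p.class_label for p in out}
        assert labels == {"C00", "C01", "C02", LOW_ABUNDANCE_LABEL, "Unclassified"}

    def test_top_fraction_one_is_identity(self):
        profs = self._graded_profiles(20)
        assert collapse_low_abundance(profs, top_fraction=1.0) == profs

    def test_mass_conserved_per_condition(self):
        profs = self._graded_profiles(20)
        out = collapse_low_abundance(profs, top_fraction=0.15)
        assert sum(p.mean_rel_abund for p in out) == pytest.approx(
            sum(p.mean_rel_abund for p in profs), abs=1e-12
        )

    def test_pooled_sd_is_root_sum_square(self):
        profs = self._graded_profiles(20, with_unclassified=False)
        out = collapse_low_abundance(profs, top_fraction=0.15)
        pooled = next(p for p in out if p.class_label == LOW_ABUNDANCE_LABEL)
        members = [p for p in profs if p.class_label not in {"C00", "C01", "C02"}]
        assert pooled.sd_rel_abund == pytest.approx(
            math.sqrt(sum(p.sd_rel_abund**2 for p in members))
        )

    def test_cutoff_ties_break_lexicographically(self):
        out = collapse_low_abundance(_uniform_profiles(10), top_fraction=0.2)
        kept = {p.class_label for p in out} - {LOW_ABUNDANCE_LABEL}
        assert kept == {"C00", "C01"}


class TestDiversity:
    def test_uniform_four_otus(self):
        t = OtuTable(["S1"], list("abcd"), np.array([[5, 5, 5, 5]]))
        d = diversity_indices(t)
        assert d.loc["S1", "richness"] == 4
        assert d.loc["S1", "shannon"] == pytest.approx(math.log(4))
        assert d.loc["S1", "pielou"] == pytest.approx(1.0)

    def test_single_otu_has_zero_entropy_and_missing_evenness(self):
        t = OtuTable(["S1"], ["a", "b"], np.array([[7, 0]]))
        d = diversity_indices(t)
        assert d.loc["S1", "shannon"] == 0.0
        assert math.isnan(d.loc["S1", "pielou"])

    def test_direct_formula_value(self):
        t = OtuTable(["S1"], list("abc"), np.array([[1, 1, 2]]))
        expected = -(0.25 * math.log(0.25) * 2 + 0.5 * math.log(0.5))
        assert diversity_indices(t).loc["S1", "shannon"] == pytest.approx(expected)

    def test_matches_scikit_bio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(3, 12))
        counts[:, 0] += 1
        t = OtuTable(["S1", "S2", "S3"], [f"O{j}" for j in range(12)], counts)
        with pytest.warns(UserWarning, match="unequal"):
            d = diversity_indices(t)
        for i, s in enumerate(t.sample_ids):
            assert d.loc[s, "shannon"] == pytest.approx(
                float(skbio_alpha.shannon(counts[i], base=math.e))
            )
            assert d.loc[s, "pielou"] == pytest.approx(float(skbio_alpha.pielou_e(counts[i])))

    def test_pielou_bounded_and_one_iff_even(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 40, size=(5, 8))
        t = OtuTable([f"S{i}" for i in range(5)], [f"O{j}" for j in range(8)], counts)
        d = diversity_indices(t)
        assert ((d["pielou"] >= 0) & (d["pielou"] <= 1)).all()

    def test_zero_total_sample_is_an_error(self):
        t = OtuTable(["S1", "S2"], ["a"], np.array([[0], [3]]))
        with pytest.raises(ValueError, match="S1"):
            diversity_indices(t)
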