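"""Promiscuity statistics: distributions, increases, comparisons."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as hst

from promiscuitrack.curation import consolidate_measurements
from promiscuitrack.stats import (
    compare_profiles,
    family_promiscuity,
    increase_histogram,
    increase_histogram_from_values,
    interval_distribution,
    potency_distribution,
    promiscuity_increase,
    top_increases,
)
from promiscuitrack.temporal import build_cumulative_profile
from conftest import make_record


def profile(years: dict[str, int], drug_id="D"):
    return build_cumulative_profile(drug_id=drug_id, target_first_years=years)


def flat_profile(n_targets: int, year=2000, drug_id="D"):
    return profile({f"T{i}": year for i in range(n_targets)}, drug_id=drug_id)


class TestIntervalDistribution:
    def test_five_number_summary_and_mean(self):
        profiles = [
            flat_profile(r, drug_id=f"d{i}") for i, r in enumerate([1, 1, 2, 10])
        ]
        s = interval_distribution(profiles, ">2012")
        assert (s.median, s.mean) == (1.5, 3.5)
        assert (s.min, s.max) == (1, 10)

    def test_heavy_tail_pulls_mean_not_median(self):
        """90 one-target drugs plus 10 twenty-target drugs: the median
        stays at 1 while the mean is dragged to 2.9 — a small highly
        promiscuous subset dominates averages."""
        profiles = [flat_profile(1, drug_id=f"a{i}") for i in range(90)]
        profiles += [flat_profile(20, drug_id=f"b{i}") for i in range(10)]
        s = interval_distribution(profiles, "2000")
        assert s.median == 1 and s.mean == pytest.approx(2.9)

    def test_single_drug_degenerate(self):
        s = interval_distribution([flat_profile(3)], "2005")
        assert (s.min, s.lower_quartile, s.median, s.upper_quartile, s.max, s.mean) == (
            3, 3, 3, 3, 3, 3,
        )

    def test_drugs_absent_before_entry(self):
        profiles = [flat_profile(1, year=2000), flat_profile(5, year=2010, drug_id="E")]
        assert interval_distribution(profiles, "2005").n_drugs == 1
        assert interval_distribution(profiles, "2010").n_drugs == 2

    def test_no_entered_drugs_is_an_error(self):
        with pytest.raises(ValueError):
            interval_distribution([flat_profile(1, year=2010)], "2003")


class TestPromiscuityIncrease:
    def test_worked_example_increase_is_two(self):
        assert promiscuity_increase(profile({"I": 2001, "II": 2005, "III": 2009})) == 2

    def test_constant_single_target_drug(self):
        assert promiscuity_increase(flat_profile(1)) == 0

    def test_kinase_inhibitor_like_growth(self):
        # one target in 2002 growing to 24 by >2012 → increase 23
        years = {"T0": 2002}
        years.update({f"T{i}": 2013 for i in range(1, 24)})
        assert promiscuity_increase(profile(years)) == 23


class TestIncreaseHistogram:
    def test_zero_increase_share_to_one_decimal(self):
        # 282 of 518 drugs without any increase → 54.4%
        values = [0] * 282 + [1] * 236
        hist = increase_histogram_from_values(values)
        assert hist.as_mapping()["0"] == (282, 54.4)

    def test_all_zero(self):
        hist = increase_histogram_from_values([0, 0, 0])
        assert hist.as_mapping()["0"] == (3, 100.0)

    def test_upper_bin_pools_large_increases(self):
        hist = increase_histogram_from_values([11, 40, 2], upper=10)
        assert hist.as_mapping()[">10"] == (2, 66.7)

    def test_configurable_upper_bound(self):
        hist = increase_histogram_from_values([6, 3], upper=5)
        assert hist.bins[-1] == ">5" and hist.as_mapping()[">5"][0] == 1

    def test_from_profiles(self):
        profiles = [profile({"I": 2001, "II": 2005, "III": 2009})]
        assert increase_histogram(profiles).as_mapping()["2"] == (1, 100.0)


@settings(derandomize=True, max_examples=60)
@given(values=hst.lists(hst.integers(0, 30), min_size=1, max_size=200))
def test_histogram_counts_conserve_n(values):
    hist = increase_histogram_from_values(values)
    assert sum(hist.counts) == hist.n == len(values)
    assert abs(sum(hist.percentages) - 100.0) < 0.5  # rounding slack


class TestFamilyPromiscuity:
    IMATINIB_FAMILIES = [
        "ATP binding cassette transporters",
        "Carbonic anhydrases",
        "Multi antimicrobial extrusion (MATE) transporters",
        "NAD(P)H dehydrogenases (quinone)",
        "Organic cation transporters",
        "Ser_Thr protein kinases",
        "Tyr protein kinases",
    ]

    def test_kinase_inhibitor_profile_spans_seven_families(self):
        # 24 targets cycling over the seven-family list → 7 distinct
        family_map = {
            f"T{i}": self.IMATINIB_FAMILIES[i % 7] for i in range(24)
        }
        years = {"T0": 2002}
        years.update({f"T{i}": 2010 for i in range(1, 24)})
        fp = family_promiscuity(profile(years), family_map)
        assert len(fp.final_families) == 7

    def test_single_family_increase_zero_despite_target_growth(self):
        years = {"T0": 2001, "T1": 2008, "T2": 2012}
        fp = family_promiscuity(profile(years), {t: "Monoamine GPCRs" for t in years})
        assert fp.family_increase == 0
        assert promiscuity_increase(profile(years)) == 2

    def test_first_record_family_flagged(self):
        years = {"T0": 2001, "T1": 2008}
        family_map = {"T0": "Monoamine GPCRs", "T1": "Tyr protein kinases"}
        fp = family_promiscuity(profile(years), family_map)
        assert fp.first_record_families == {"Monoamine GPCRs"}

    def test_unmapped_targets_fall_into_unassigned(self):
        fp = family_promiscuity(flat_profile(2), {})
        assert fp.final_families == {"unassigned"}

    @settings(derandomize=True, max_examples=40)
    @given(
        years=hst.dictionaries(
            hst.sampled_from([f"P{i}" for i in range(10)]),
            hst.integers(1995, 2015),
            min_size=1,
        ),
        data=hst.data(),
    )
    def test_family_count_never_exceeds_target_count(self, years, data):
        family_map = {
            t: data.draw(hst.sampled_from(["f1", "f2", "f3"])) for t in years
        }
        fp = family_promiscuity(profile(years), family_map)
        p = profile(years)
        for i in range(14):
            assert fp.family_counts[i] <= len(p.target_sets[i])


class TestCompareProfiles:
    def test_annotation_surplus(self):
        c = compare_profiles("d", [f"a{i}" for i in range(10)], [f"a{i}" for i in range(6)])
        assert (c.n_db_targets, c.n_activity_targets, c.delta) == (10, 6, 4)

    def test_identical_sets(self):
        c = compare_profiles("d", {"x", "y"}, {"x", "y"})
        assert c.delta == 0 and c.n_common == 2

    def test_disjoint_sets_share_nothing(self):
        c = compare_profiles("d", {"A", "B"}, {"C"})
        assert c.n_common == 0 and c.delta == 1

    @settings(derandomize=True, max_examples=80)
    @given(
        db=hst.frozensets(hst.integers(0, 30)),
        act=hst.frozensets(hst.integers(0, 30)),
    )
    def test_common_bounded_by_smaller_set(self, db, act):
        c = compare_profiles("d", map(str, db), map(str, act))
        assert c.n_common <= min(c.n_db_targets, c.n_activity_targets)
        assert c.delta == c.n_db_targets - c.n_activity_targets


def interaction_with_potency(nM, mtype="Ki", compound="C", target="P1"):
    return consolidate_measurements(
        [make_record(compound, target_id=target, measurement_type=mtype, value=nM)],
        "high",
    )


class TestPotencyDistribution:
    def test_zero_iqr_puts_far_value_outside_whiskers(self):
        # p-scale values {5,5,5,5,12}: IQR 0 ⇒ whiskers collapse to 5
        # and 12 is an outlier
        interactions = [
            interaction_with_potency(10 ** (9 - v), target=f"P{i}")
            for i, v in enumerate([5, 5, 5, 5, 12])
        ]
        d = potency_distribution(interactions)
        assert d.lower_whisker == d.upper_whisker == pytest.approx(5.0)
        assert len(d.outliers) == 1 and d.outliers[0] == pytest.approx(12.0)

    def test_median_of_symmetric_values(self):
        interactions = [
            interaction_with_potency(10 ** (9 - v), target=f"P{i}")
            for i, v in enumerate([4, 5, 6, 7, 8])
        ]
        assert potency_distribution(interactions).median == pytest.approx(6.0)

    def test_single_value_degenerate(self):
        d = potency_distribution([interaction_with_potency(100.0)])
        assert d.lower_whisker == d.median == d.upper_whisker == pytest.approx(7.0)
        assert not d.outliers

    def test_non_concentration_interactions_are_ineligible(self):
        record = make_record(measurement_type="%max", value=80, units="")
        interaction = consolidate_measurements([record], "low1")
        with pytest.raises(ValueError):
            potency_distribution([interaction])


class TestTopIncreases:
    def test_ranked_by_increase(self):
        profiles = [
            profile({"I": 2001, "II": 2005, "III": 2009}, drug_id="mid"),
            flat_profile(1, drug_id="flat"),
            profile({f"T{i}": (2002 if i == 0 else 2013) for i in range(24)}, drug_id="big"),
        ]
        top = top_increases(profiles, k=2)
        assert [t[0] for t in top] == ["big", "mid"]
        assert top[0][1] == 23
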