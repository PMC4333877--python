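"""PRR computation, contingency tabulation, and per-pair summaries."""

import random

import pytest
from hypothesis import given, strategies as st

from vaerslink import (
    ALL_YEARS,
    ContingencyCounts,
    ReportCollection,
    Sex,
    SignalSpec,
    SimConfig,
    contingency,
    extract_pairs,
    join_reports,
    occurrence_frame,
    prr,
    significant_associations,
    simulate_dataset,
    summaries_to_frame,
    summarize_associations,
)
from vaerslink.rdf import format_float7


def collection(records):
    """records: (rid, year, sex, age, vaccines, symptoms)"""
    return ReportCollection.from_records(records)


# --- pair extraction -------------------------------------------------------

def test_extract_pairs_cross_product():
    coll = collection([("1", 2000, Sex.FEMALE, 30.0, {"A", "B"}, {"x", "y", "z"})])
    pairs = list(extract_pairs(coll))
    assert len(pairs) == 6
    assert {(p.vaccine, p.symptom) for p in pairs} == {
        (v, s) for v in "AB" for s in "xyz"
    }


def test_report_without_symptoms_yields_nothing():
    coll = collection([("1", 2000, Sex.MALE, 5.0, {"A"}, set())])
    assert list(extract_pairs(coll)) == []


def test_distinct_pair_count_matches_bruteforce(small_collection, small_summaries):
    expected = set()
    for entry in small_collection:
        for v in entry.vaccines:
            for s in entry.symptoms:
                expected.add((v, s))
    assert set(small_summaries) == expected


# --- contingency -----------------------------------------------------------

def test_contingency_singleton():
    coll = collection([("1", 2000, Sex.MALE, 1.0, {"A"}, {"x"})])
    c = contingency(extract_pairs(coll), "A", "x")
    assert (c.n_vs, c.n_v, c.n_s, c.n_total) == (1, 1, 1, 1)


HAND_FIXTURE = [
    ("1", 2000, Sex.FEMALE, 1.0, {"A"}, {"x"}),
    ("2", 2000, Sex.MALE, 2.0, {"A"}, {"x"}),
    ("3", 2000, Sex.FEMALE, 3.0, {"A"}, {"y"}),
    ("4", 2000, Sex.MALE, 4.0, {"B"}, {"x"}),
    ("5", 2000, Sex.FEMALE, 5.0, {"B"}, {"y"}),
    ("6", 2000, Sex.MALE, 6.0, {"B"}, {"y"}),
    ("7", 2000, Sex.FEMALE, 7.0, {"A", "B"}, {"x", "y"}),
    ("8", 2000, Sex.MALE, 8.0, {"C"}, {"z"}),
    ("9", 2000, Sex.FEMALE, 9.0, {"C"}, {"x"}),
    ("10", 2000, Sex.MALE, 10.0, {"A"}, {"z"}),
]


def test_contingency_matches_hand_tabulation():
    # by hand: occurrences = 6 singles + 4 (report 7) + 3 = 13;
    # (A,x) occurs in reports 1, 2, 7; A in 1,2,3,7(x2),10; x in 1,2,4,7(x2),9
    pairs = list(extract_pairs(collection(HAND_FIXTURE)))
    c = contingency(pairs, "A", "x")
    assert (c.n_vs, c.n_v, c.n_s, c.n_total) == (3, 6, 6, 13)
    assert prr(c) == pytest.approx((3 / 6) / (6 / 13))


def test_contingency_empty_scope():
    coll = collection([("1", 2000, Sex.MALE, 1.0, {"A"}, {"x"})])
    c = contingency(extract_pairs(coll), "A", "x", scope=1990)
    assert (c.n_vs, c.n_v, c.n_s, c.n_total) == (0, 0, 0, 0)
    assert prr(c) is None


def test_inconsistent_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyCounts(n_vs=5, n_v=3, n_s=10, n_total=20)
    with pytest.raises(ValueError):
        ContingencyCounts(n_vs=-1, n_v=3, n_s=10, n_total=20)


# --- PRR -------------------------------------------------------------------

def test_prr_hand_computed_ratio():
    c = ContingencyCounts(n_vs=5, n_v=10, n_s=20, n_total=100)
    assert prr(c, mode="paper") == pytest.approx(2.5)
    # classic excludes the index vaccine: (5/10) / (15/90)
    assert prr(c, mode="classic") == pytest.approx(3.0)


def test_single_vaccine_dataset_gives_prr_one():
    # with one vaccine, n_v = n_total and n_s = n_vs for every pair
    coll = collection(
        [(str(i), 2000, Sex.MALE, 1.0, {"A"}, {random.Random(i).choice("xyz")}) for i in range(30)]
    )
    summaries = summarize_associations(coll)
    assert summaries
    for summary in summaries.values():
        assert summary.overall_prr == pytest.approx(1.0)
    assert significant_associations(summaries).pairs == frozenset()


def test_classic_undefined_when_symptom_unique_to_vaccine():
    c = ContingencyCounts(n_vs=4, n_v=10, n_s=4, n_total=100)
    assert prr(c, mode="classic") is None
    assert prr(c, mode="paper") is not None


def test_unknown_mode_rejected():
    with pytest.raises(ValueError):
        prr(ContingencyCounts(1, 1, 1, 1), mode="weird")


@given(
    n_total=st.integers(10_000, 1_000_000),
    v_frac=st.floats(1e-4, 0.01),
    s_frac=st.floats(0.001, 0.5),
    vs_frac=st.floats(1e-4, 0.01),
)
def test_paper_and_classic_agree_in_small_fraction_limit(n_total, v_frac, s_frac, vs_frac):
    """When the index vaccine is a small fraction of all occurrences and the
    pair a small fraction of the symptom's, the pooled and index-excluded
    forms differ by at most 5%."""
    n_v = max(1, int(n_total * v_frac))
    n_s = max(100, int(n_total * s_frac))
    n_vs = max(1, min(n_v, int(n_s * vs_frac)))
    c = ContingencyCounts(n_vs=n_vs, n_v=n_v, n_s=n_s, n_total=n_total)
    p = prr(c, mode="paper")
    k = prr(c, mode="classic")
    assert k is not None
    assert abs(p / k - 1) <= 0.05


# --- summaries -------------------------------------------------------------

def _pnc_2009_collection():
    """63 reports in 2009, all (PNC, Intussusception), 31 male / 32 female,
    every patient under one year old."""
    records = []
    for i in range(63):
        sex = Sex.MALE if i < 31 else Sex.FEMALE
        records.append((f"r{i:03d}", 2009, sex, 0.5, {"PNC"}, {"Intussusception"}))
    return collection(records)


def test_gender_percentage_to_seven_significant_digits():
    summaries = summarize_associations(_pnc_2009_collection())
    summary = summaries[("PNC", "Intussusception")]
    cell = summary.gender_detail[(2009, "MALE")]
    assert cell.count == 31
    assert format_float7(cell.percentage) == "0.4920635"


def test_age_group_full_year_percentage():
    summaries = summarize_associations(_pnc_2009_collection())
    summary = summaries[("PNC", "Intussusception")]
    cell = summary.age_detail[(2009, "LESS_THAN_ONE")]
    assert cell.count == 63
    assert format_float7(cell.percentage) == "1.0"
    assert summary.yearly[2009].count == 63


def test_group_counts_sum_to_yearly_count_across_replicates():
    """Conservation: per year, age counts and gender counts each sum to the
    yearly pair count (100 seeded datasets)."""
    for seed in range(100):
        config = SimConfig(n_reports=60, n_vaccines=4, n_symptoms=8, year_range=(1990, 1993), seed=seed)
        summaries = summarize_associations(join_reports(simulate_dataset(config)))
        for summary in summaries.values():
            summary.validate()  # raises if any year's sums disagree


def test_pair_occurrence_conservation(small_collection, small_summaries):
    occ = occurrence_frame(small_collection)
    total_from_pairs = sum(
        detail.count for s in small_summaries.values() for detail in s.yearly.values()
    )
    assert total_from_pairs == len(occ)
    for year in occ["year"].unique():
        year_total = sum(
            d.count for s in small_summaries.values() for y, d in s.yearly.items() if y == year
        )
        assert year_total == (occ["year"] == year).sum()


def test_summaries_invariant_to_report_order(small_collection):
    reordered = ReportCollection(
        entries=dict(sorted(small_collection.entries.items(), reverse=True)),
        orphan_vaccine_rows=small_collection.orphan_vaccine_rows,
        orphan_symptom_rows=small_collection.orphan_symptom_rows,
    )
    assert summarize_associations(small_collection) == summarize_associations(reordered)


def test_yearly_entries_only_for_years_with_occurrences(small_summaries, small_collection):
    occ = occurrence_frame(small_collection)
    for (v, s), summary in small_summaries.items():
        observed_years = set(
            occ.loc[(occ["vaccine"] == v) & (occ["symptom"] == s), "year"]
        )
        assert set(summary.yearly) == observed_years


def test_screening_filters():
    coll = collection(HAND_FIXTURE)
    everything = summarize_associations(coll)
    filtered = summarize_associations(coll, min_count=3)
    assert set(filtered) < set(everything)
    assert all(sum(d.count for d in s.yearly.values()) >= 3 for s in filtered.values())


# --- significance ----------------------------------------------------------

def test_overall_rule_is_strict():
    coll = collection(
        [(str(i), 2000, Sex.MALE, 1.0, {"A"}, {"x"}) for i in range(5)]
    )
    summaries = summarize_associations(coll)
    assert summaries[("A", "x")].overall_prr == pytest.approx(1.0)
    assert significant_associations(summaries, rule="overall").pairs == frozenset()


def test_injected_signal_recovered_overall(signal_dataset_5000):
    config, tables = signal_dataset_5000
    summaries = summarize_associations(join_reports(tables))
    result = significant_associations(summaries, rule="overall")
    assert ("V001", "SYM0005") in result.pairs


def test_any_year_is_not_superset_of_overall():
    """Two-year counterexample, verified by hand: pooled PRR
    (45/100)/(55/200) = 18/11 > 1, but 1990's yearly PRR is exactly 1 and
    the pair never occurs in 1991."""
    records = []
    rid = iter(range(10_000))
    def add(year, vaccine, symptom, n):
        for _ in range(n):
            records.append((f"r{next(rid):05d}", year, Sex.MALE, 30.0, {vaccine}, {symptom}))
    add(1990, "V", "S", 45)
    add(1990, "V", "T", 45)
    add(1990, "W", "S", 5)
    add(1990, "W", "T", 5)
    add(1991, "V", "T", 10)
    add(1991, "W", "S", 5)
    add(1991, "W", "T", 85)
    summaries = summarize_associations(collection(records))
    target = summaries[("V", "S")]
    assert target.overall_prr == pytest.approx(18 / 11)
    assert target.yearly[1990].prr == pytest.approx(1.0)
    assert 1991 not in target.yearly
    overall = significant_associations(summaries, rule="overall")
    any_year = significant_associations(summaries, rule="any_year")
    assert ("V", "S") in overall.pairs
    assert ("V", "S") not in any_year.pairs


def test_pair_year_tally_reported_for_both_rules(small_summaries):
    a = significant_associations(small_summaries, rule="overall")
    b = significant_associations(small_summaries, rule="any_year")
    assert a.pair_year_count == b.pair_year_count
    expected = sum(
        1
        for s in small_summaries.values()
        for d in s.yearly.values()
        if d.prr is not None and d.prr > 1
    )
    assert a.pair_year_count == expected


# --- flat export -----------------------------------------------------------

def test_flat_frame_pair_count_and_conservation(small_summaries):
    frame = summaries_to_frame(small_summaries)
    assert frame.groupby(["vaccine", "symptom"]).ngroups == len(small_summaries)
    gender = frame[frame["group_type"] == "GENDER"]
    sums = gender.groupby(["vaccine", "symptom", "year"])["group_count"].sum()
    counts = gender.groupby(["vaccine", "symptom", "year"])["yearly_count"].first()
    assert (sums == counts).all()
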