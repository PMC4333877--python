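"""Vaccine-symptom disproportionality statistics.

The counting unit throughout is the *pair occurrence*: one distinct
(report, vaccine, symptom) triple. A report listing j vaccines and k
symptoms contributes j*k occurrences; duplicates within a report were
already collapsed at join time, so a pair is counted at most once per
report.

For a vaccine v and symptom s the proportional reporting ratio compares
how often s is reported with v against how often s is reported overall::

    PRR(v, s) = (n_vs / n_v) / (n_s / n_total)            ("paper" mode)
    PRR(v, s) = (n_vs / n_v) / ((n_s - n_vs) / (n_total - n_v))   ("classic")

where n_vs counts occurrences of the pair, n_v all occurrences of v,
n_s all occurrences of s, and n_total all occurrences in scope. "paper"
mode pools every vaccine, including v itself, into the comparator, and is
the default; "classic" is the index-excluded 2x2 form (Evans' PRR). The
two agree closely whenever v contributes a small fraction of all
occurrences. A PRR above 1 flags the symptom as relatively over-reported
for that vaccine; it is a screening signal, not evidence of causation.

Yearly PRRs restrict every count to a single calendar year's occurrences.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Iterator, Literal, NamedTuple

import pandas as pd

from .io import ReportCollection, Sex

#: scope sentinel: pool every year
ALL_YEARS = "ALL_YEARS"

PrrMode = Literal["paper", "classic"]


class PairOccurrence(NamedTuple):
    report_id: str
    vaccine: str
    symptom: str
    year: int
    sex: Sex
    age_years: float | None


@dataclasses.dataclass(frozen=True)
class ContingencyCounts:
    """The four frequencies feeding one PRR evaluation."""

    n_vs: int
    n_v: int
    n_s: int
    n_total: int
    scope: int | str = ALL_YEARS

    def __post_init__(self) -> None:
        if min(self.n_vs, self.n_v, self.n_s, self.n_total) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n_vs > min(self.n_v, self.n_s) or max(self.n_v, self.n_s) > self.n_total:
            raise ValueError(
                f"inconsistent counts n_vs={self.n_vs} n_v={self.n_v} n_s={self.n_s} n_total={self.n_total}"
            )


class YearlyDetail(NamedTuple):
    prr: float | None
    count: int


class GroupCell(NamedTuple):
    count: int
    percentage: float  # fraction in [0, 1] of that year's pair count


@dataclasses.dataclass
class AgeBins:
    """Half-open age bins [low, high) with labels; missing age -> unknown_label."""

    bins: tuple[tuple[str, float, float], ...]
    unknown_label: str = "UNKNOWN"

    def label(self, age_years: float | None) -> str:
        if age_years is None:
            return self.unknown_label
        for name, low, high in self.bins:
            if low <= age_years < high:
                return name
        return self.unknown_label


DEFAULT_AGE_BINS = AgeBins(
    bins=(
        ("LESS_THAN_ONE", 0.0, 1.0),
        ("ONE_TO_FIVE", 1.0, 6.0),
        ("SIX_TO_SEVENTEEN", 6.0, 18.0),
        ("EIGHTEEN_TO_SIXTYFOUR", 18.0, 65.0),
        ("SIXTYFIVE_PLUS", 65.0, math.inf),
    )
)


@dataclasses.dataclass
class AssociationSummary:
    """Everything reported for one vaccine-symptom pair.

    ``yearly`` maps year -> (yearly PRR, report count); ``age_detail`` and
    ``gender_detail`` map (year, group label) -> (count, fraction of that
    year's pair count). Per year, the age counts and the gender counts
    each sum to the yearly count.
    """

    vaccine: str
    symptom: str
    overall_prr: float | None
    yearly: dict[int, YearlyDetail]
    age_detail: dict[tuple[int, str], GroupCell]
    gender_detail: dict[tuple[int, str], GroupCell]

    def validate(self) -> None:
        for detail, kind in ((self.age_detail, "age"), (self.gender_detail, "gender")):
            per_year: dict[int, int] = {}
            for (year, _label), cell in detail.items():
                per_year[year] = per_year.get(year, 0) + cell.count
            for year, total in per_year.items():
                expected = self.yearly[year].count
                if total != expected:
                    raise ValueError(
                        f"pair ({self.vaccine},{self.symptom}) year {year}: "
                        f"{kind} counts sum to {total}, yearly count is {expected}"
                    )
        for (year, _label), cell in list(self.age_detail.items()) + list(self.gender_detail.items()):
            if not 0.0 <= cell.percentage <= 1.0:
                raise ValueError(f"percentage {cell.percentage} outside [0, 1]")


def extract_pairs(collection: ReportCollection) -> Iterator[PairOccurrence]:
    """Stream one occurrence per (report, vaccine, symptom) triple.

    Deterministic order: reports by ID, then vaccines and symptoms
    lexicographically.
    """
    for rid in sorted(collection.entries):
        entry = collection.entries[rid]
        rep = entry.report
        for vaccine in sorted(entry.vaccines):
            for symptom in sorted(entry.symptoms):
                yield PairOccurrence(rid, vaccine, symptom, rep.year, rep.sex, rep.age_years)


def occurrence_frame(collection: ReportCollection) -> pd.DataFrame:
    """Pair occurrences as a DataFrame (columns report_id, vaccine, symptom, year, sex, age_years)."""
    return pd.DataFrame(
        list(extract_pairs(collection)),
        columns=["report_id", "vaccine", "symptom", "year", "sex", "age_years"],
    )


def contingency(
    pairs: Iterable[PairOccurrence],
    vaccine: str,
    symptom: str,
    scope: int | str = ALL_YEARS,
) -> ContingencyCounts:
    """Tabulate the four counts for one pair within a scope (a year or ALL_YEARS)."""
    n_vs = n_v = n_s = n_total = 0
    for occ in pairs:
        if scope != ALL_YEARS and occ.year != scope:
            continue
        n_total += 1
        is_v = occ.vaccine == vaccine
        is_s = occ.symptom == symptom
        n_v += is_v
        n_s += is_s
        n_vs += is_v and is_s
    return ContingencyCounts(n_vs=n_vs, n_v=n_v, n_s=n_s, n_total=n_total, scope=scope)


def prr(counts: ContingencyCounts, mode: PrrMode = "paper") -> float | None:
    """The proportional reporting ratio, or None where it is undefined.

    Undefined when the pair has no occurrences in scope (n_vs = 0), and in
    classic mode additionally when the comparator cell is empty (every
    occurrence of the symptom involves the index vaccine, or every
    occurrence in scope involves it).
    """
    if counts.n_vs == 0:
        return None
    observed = counts.n_vs / counts.n_v
    if mode == "paper":
        return observed / (counts.n_s / counts.n_total)
    if mode == "classic":
        rest_total = counts.n_total - counts.n_v
        rest_s = counts.n_s - counts.n_vs
        if rest_total == 0 or rest_s == 0:
            return None
        return observed / (rest_s / rest_total)
    raise ValueError(f"unknown PRR mode {mode!r}")


def _prr_from_counts(n_vs: int, n_v: int, n_s: int, n_total: int, mode: PrrMode) -> float | None:
    return prr(ContingencyCounts(n_vs, n_v, n_s, n_total), mode=mode)


def summarize_associations(
    collection: ReportCollection,
    age_bins: AgeBins = DEFAULT_AGE_BINS,
    mode: PrrMode = "paper",
    min_count: int = 0,
    min_prr: float | None = None,
) -> dict[tuple[str, str], AssociationSummary]:
    """Compute one :class:`AssociationSummary` per observed pair.

    The overall PRR pools every year; each yearly PRR uses only that
    year's occurrences, and yearly entries exist only for years where the
    pair occurred. Age and gender breakdowns are per (year, group) counts
    with percentages relative to that year's pair count.

    ``min_count`` / ``min_prr`` are optional screening filters on the
    pair's total occurrence count and overall PRR (both off by default).
    """
    occ = occurrence_frame(collection)
    if occ.empty:
        return {}
    occ = occ.assign(
        sex_label=[s.value for s in occ["sex"]],
        age_group=[age_bins.label(a) for a in occ["age_years"]],
    )

    n_total = len(occ)
    n_v = occ.groupby("vaccine").size().to_dict()
    n_s = occ.groupby("symptom").size().to_dict()
    n_vs = occ.groupby(["vaccine", "symptom"]).size()

    year_total = occ.groupby("year").size().to_dict()
    n_vy = occ.groupby(["vaccine", "year"]).size().to_dict()
    n_sy = occ.groupby(["symptom", "year"]).size().to_dict()
    n_vsy = occ.groupby(["vaccine", "symptom", "year"]).size()
    gender_counts = occ.groupby(["vaccine", "symptom", "year", "sex_label"]).size()
    age_counts = occ.groupby(["vaccine", "symptom", "year", "age_group"]).size()

    yearly_by_pair: dict[tuple[str, str], dict[int, int]] = {}
    for (v, s, year), count in n_vsy.items():
        yearly_by_pair.setdefault((v, s), {})[year] = int(count)
    gender_by_pair: dict[tuple[str, str], dict[tuple[int, str], int]] = {}
    for (v, s, year, label), count in gender_counts.items():
        gender_by_pair.setdefault((v, s), {})[(year, label)] = int(count)
    age_by_pair: dict[tuple[str, str], dict[tuple[int, str], int]] = {}
    for (v, s, year, label), count in age_counts.items():
        age_by_pair.setdefault((v, s), {})[(year, label)] = int(count)

    summaries: dict[tuple[str, str], AssociationSummary] = {}
    for (v, s), pair_total in n_vs.items():
        pair_total = int(pair_total)
        if pair_total < min_count:
            continue
        overall = _prr_from_counts(pair_total, n_v[v], n_s[s], n_total, mode)
        if min_prr is not None and (overall is None or overall < min_prr):
            continue
        yearly = {
            year: YearlyDetail(
                prr=_prr_from_counts(count, n_vy[(v, year)], n_sy[(s, year)], year_total[year], mode),
                count=count,
            )
            for year, count in sorted(yearly_by_pair[(v, s)].items())
        }
        gender_detail = {
            (year, label): GroupCell(count, count / yearly[year].count)
            for (year, label), count in sorted(gender_by_pair[(v, s)].items())
        }
        age_detail = {
            (year, label): GroupCell(count, count / yearly[year].count)
            for (year, label), count in sorted(age_by_pair[(v, s)].items())
        }
        summaries[(v, s)] = AssociationSummary(
            vaccine=v,
            symptom=s,
            overall_prr=overall,
            yearly=yearly,
            age_detail=age_detail,
            gender_detail=gender_detail,
        )
    return summaries


@dataclasses.dataclass(frozen=True)
class SignificanceResult:
    """Pairs passing the PRR > 1 screen, plus the (pair, year) tally.

    ``pair_year_count`` counts (pair, year) combinations whose yearly PRR
    exceeds 1, regardless of the rule used for ``pairs``; published
    headline tallies of "significant associations" can refer to either
    reading, so both are always reported.
    """

    rule: str
    pairs: frozenset[tuple[str, str]]
    pair_year_count: int


def significant_associations(
    summaries: dict[tuple[str, str], AssociationSummary],
    rule: Literal["overall", "any_year"] = "overall",
) -> SignificanceResult:
    """Screen pairs by strict PRR > 1.

    ``overall``: pairs whose pooled PRR exceeds 1. ``any_year``: pairs
    with a yearly PRR above 1 in at least one year. The two sets are not
    nested in general: pooling across years can push a pair's PRR above 1
    even when no single year does (and vice versa).
    """
    overall = frozenset(
        pair for pair, s in summaries.items() if s.overall_prr is not None and s.overall_prr > 1
    )
    any_year = frozenset(
        pair
        for pair, s in summaries.items()
        if any(d.prr is not None and d.prr > 1 for d in s.yearly.values())
    )
    pair_year_count = sum(
        1
        for s in summaries.values()
        for d in s.yearly.values()
        if d.prr is not None and d.prr > 1
    )
    if rule == "overall":
        pairs = overall
    elif rule == "any_year":
        pairs = any_year
    else:
        raise ValueError(f"unknown significance rule {rule!r}")
    return SignificanceResult(rule=rule, pairs=pairs, pair_year_count=pair_year_count)


def summaries_to_frame(summaries: dict[tuple[str, str], AssociationSummary]) -> pd.DataFrame:
    """Flatten summaries for CSV export.

    One row per (pair, year, group type, group label); the pair's overall
    PRR and the year's PRR/count repeat on every row of that year.
    """
    rows = []
    for (v, s) in sorted(summaries):
        summary = summaries[(v, s)]
        for year, detail in summary.yearly.items():
            for group_type, cells in (("AGE", summary.age_detail), ("GENDER", summary.gender_detail)):
                for (cell_year, label), cell in cells.items():
                    if cell_year != year:
                        continue
                    rows.append({
                        "vaccine": v,
                        "symptom": s,
                        "overall_prr": summary.overall_prr,
                        "year": year,
                        "yearly_prr": detail.prr,
                        "yearly_count": detail.count,
                        "group_type": group_type,
                        "group_label": label,
                        "group_count": cell.count,
                        "group_percentage": cell.percentage,
                    })
    return pd.DataFrame(
        rows,
        columns=[
            "vaccine", "symptom", "overall_prr", "year", "yearly_prr",
            "yearly_count", "group_type", "group_label", "group_count", "group_percentage",
        ],
    )
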