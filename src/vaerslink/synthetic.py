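"""Synthetic VAERS-like report generator with injected disproportionality signals.

Emulates the three-table spontaneous-report layout (Data / Vaccine /
Symptom) with configurable report counts, vaccine and symptom vocabularies,
demographics, and a list of vaccine-symptom *signals*: pairs whose symptom
weight is multiplied by a known enrichment factor whenever the vaccine is
present on a report. Because the enrichment is known, every downstream
stage (PRR estimation, significance filtering, network construction) has a
ground truth to recover.

The generated tables are returned as :class:`~vaerslink.io.RawTables` and
round-trip exactly through :func:`~vaerslink.io.write_raw_tables` /
:func:`~vaerslink.io.read_raw_tables`.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    DATA_COLUMNS,
    MAX_SYMPTOMS_PER_ROW,
    SYMPTOM_COLUMNS,
    VAX_COLUMNS,
    RawTables,
    write_raw_tables,  # noqa: F401  (re-exported: the generator's file emitter)
)

__all__ = [
    "AgeComponent",
    "AgeModel",
    "ConfigError",
    "SignalSpec",
    "SimConfig",
    "simulate_dataset",
    "write_raw_tables",
]


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclasses.dataclass(frozen=True)
class SignalSpec:
    """An injected vaccine-symptom association.

    When ``vaccine`` appears on a report (and the report's year is in
    ``years``, if given), the baseline weight of ``symptom`` is multiplied
    by ``enrichment`` before the report's symptoms are drawn, and the
    weight vector is renormalized. ``enrichment`` must be >= 1; 1 is a
    no-op.
    """

    vaccine: str
    symptom: str
    enrichment: float
    years: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ConfigError(f"signal ({self.vaccine},{self.symptom}): enrichment {self.enrichment} < 1")

    def active(self, year: int) -> bool:
        return self.years is None or year in self.years


@dataclasses.dataclass(frozen=True)
class AgeComponent:
    """One uniform age band of the mixture: weight, [low, high) in years."""

    weight: float
    low: float
    high: float


@dataclasses.dataclass(frozen=True)
class AgeModel:
    """Mixture model for patient age, with a missing-age probability.

    Component weights are conditional on the age being recorded and must
    sum to 1; ``missing_prob`` is the separate chance the field is blank.
    Default bands roughly follow the age structure of spontaneous
    vaccine-report systems (heavy paediatric tail, adult bulk, smaller
    elderly component) with 10% of reports lacking an age.
    """

    missing_prob: float = 0.10
    components: tuple[AgeComponent, ...] = (
        AgeComponent(0.25, 0.0, 2.0),
        AgeComponent(0.20, 2.0, 18.0),
        AgeComponent(0.45, 18.0, 65.0),
        AgeComponent(0.10, 65.0, 90.0),
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ConfigError(f"missing_prob {self.missing_prob} outside [0, 1]")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"age component weights sum to {total}, not 1")
        for c in self.components:
            if c.low < 0 or c.high <= c.low:
                raise ConfigError(f"invalid age band [{c.low}, {c.high})")


_STATES = (
    "CA", "TX", "NY", "FL", "PA", "IL", "OH", "MI", "GA", "NC",
    "WA", "MA", "VA", "NJ", "MN", "CO", "AZ", "WI", "MD", "MO",
)
_MANUFACTURERS = ("MERCK & CO. INC.", "PFIZER\\WYETH", "GLAXOSMITHKLINE BIOLOGICALS", "SANOFI PASTEUR", "NOVARTIS")
_ROUTES = ("IM", "SC", "PO", "ID")
_SITES = ("LA", "RA", "LL", "RL", "")


def _zipf_weights(n: int) -> np.ndarray:
    # MedDRA term frequencies in spontaneous reports are heavily skewed;
    # a 1/rank law is a reasonable stand-in
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic dataset.

    Defaults describe a desk-scale study: 5,000 reports over 1990-2013
    drawn from 25 vaccine codes and 150 symptom terms, 1-3 vaccines and
    1-5 symptoms per report, Zipf-weighted baseline symptom frequencies,
    a female-skewed sex mix, and the :class:`AgeModel` age mixture.
    """

    n_reports: int = 5000
    year_range: tuple[int, int] = (1990, 2013)
    n_vaccines: int = 25
    n_symptoms: int = 150
    vaccines_per_report: tuple[int, int] = (1, 3)
    symptoms_per_report: tuple[int, int] = (1, 5)
    baseline_symptom_weights: tuple[float, ...] | None = None  # None -> Zipf(1/rank)
    signals: tuple[SignalSpec, ...] = ()
    sex_probs: tuple[float, float, float] = (0.35, 0.55, 0.10)  # MALE, FEMALE, UNKNOWN
    age_model: AgeModel = AgeModel()
    missing_state_prob: float = 0.05
    seed: int = 0
    vaccine_codes: tuple[str, ...] | None = None  # None -> "V001".."Vnnn"
    symptom_terms: tuple[str, ...] | None = None  # None -> "SYM0001".."SYMnnnn"

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be >= 0")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigError(f"year_range start {self.year_range[0]} > end {self.year_range[1]}")
        if self.n_reports > 0 and (self.codes_count == 0 or self.terms_count == 0):
            raise ConfigError("n_vaccines and n_symptoms must be positive when n_reports > 0")
        for lo, hi, what, limit in (
            (*self.vaccines_per_report, "vaccines_per_report", self.codes_count),
            (*self.symptoms_per_report, "symptoms_per_report", self.terms_count),
        ):
            if lo < 0 or hi < lo:
                raise ConfigError(f"invalid {what} range ({lo}, {hi})")
            if self.n_reports > 0 and hi > limit:
                raise ConfigError(f"{what} max {hi} exceeds vocabulary size {limit}")
        if abs(sum(self.sex_probs) - 1.0) > 1e-9:
            raise ConfigError(f"sex_probs sum to {sum(self.sex_probs)}, not 1")
        if self.baseline_symptom_weights is not None:
            w = np.asarray(self.baseline_symptom_weights, dtype=float)
            if len(w) != self.terms_count:
                raise ConfigError(
                    f"baseline_symptom_weights has {len(w)} entries for {self.terms_count} symptoms"
                )
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigError("baseline_symptom_weights must be a probability vector")
        codes, terms = self.codes, self.terms
        for sig in self.signals:
            if sig.vaccine not in codes:
                raise ConfigError(f"signal vaccine {sig.vaccine!r} not in vaccine vocabulary")
            if sig.symptom not in terms:
                raise ConfigError(f"signal symptom {sig.symptom!r} not in symptom vocabulary")

    @property
    def codes(self) -> tuple[str, ...]:
        if self.vaccine_codes is not None:
            return self.vaccine_codes
        return tuple(f"V{i + 1:03d}" for i in range(self.n_vaccines))

    @property
    def terms(self) -> tuple[str, ...]:
        if self.symptom_terms is not None:
            return self.symptom_terms
        return tuple(f"SYM{i + 1:04d}" for i in range(self.n_symptoms))

    @property
    def codes_count(self) -> int:
        return len(self.vaccine_codes) if self.vaccine_codes is not None else self.n_vaccines

    @property
    def terms_count(self) -> int:
        return len(self.symptom_terms) if self.symptom_terms is not None else self.n_symptoms


def _report_rng(seed: int, index: int) -> np.random.Generator:
    # one deterministic sub-stream per report: insensitive to generation
    # order and stable across platforms
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _sample_date(rng: np.random.Generator, year: int) -> str:
    day = datetime.date(year, 1, 1) + datetime.timedelta(days=int(rng.integers(0, 365)))
    return f"{day.month:02d}/{day.day:02d}/{day.year:04d}"


def _sample_age(rng: np.random.Generator, model: AgeModel) -> str:
    u = rng.random()
    if u < model.missing_prob:
        return ""
    probs = np.array([c.weight for c in model.components])
    comp = model.components[rng.choice(len(probs), p=probs / probs.sum())]
    return f"{rng.uniform(comp.low, comp.high):.1f}"


def simulate_dataset(config: SimConfig) -> RawTables:
    """Generate one dataset; identical config and seed give identical tables.

    Reports are independent. Per report: a year uniform over the range, a
    received date uniform within the year, demographics from the
    configured mixes, 1-3 distinct vaccines uniform over the vocabulary,
    and symptoms drawn without replacement from the baseline weights --
    re-weighted and renormalized by any active signal whose vaccine is on
    the report.
    """
    codes = config.codes
    terms = config.terms
    base = (
        np.asarray(config.baseline_symptom_weights, dtype=float)
        if config.baseline_symptom_weights is not None
        else _zipf_weights(len(terms))
    )
    term_index = {t: i for i, t in enumerate(terms)}
    sex_codes = ("M", "F", "U")

    data_rows: list[list[str]] = []
    vax_rows: list[list[str]] = []
    sym_rows: list[list[str]] = []

    for i in range(config.n_reports):
        rng = _report_rng(config.seed, i)
        rid = f"{i + 1:07d}"
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))

        n_vax = int(rng.integers(config.vaccines_per_report[0], config.vaccines_per_report[1] + 1))
        vax_idx = rng.choice(len(codes), size=n_vax, replace=False)
        report_vaccines = [codes[j] for j in vax_idx]

        weights = base.copy()
        for sig in config.signals:
            if sig.enrichment != 1.0 and sig.vaccine in report_vaccines and sig.active(year):
                weights[term_index[sig.symptom]] *= sig.enrichment
        weights = weights / weights.sum()
        n_sym = int(rng.integers(config.symptoms_per_report[0], config.symptoms_per_report[1] + 1))
        sym_idx = rng.choice(len(terms), size=n_sym, replace=False, p=weights)
        report_symptoms = [terms[j] for j in sym_idx]

        state = "" if rng.random() < config.missing_state_prob else _STATES[rng.choice(len(_STATES))]
        data_rows.append([
            rid,
            _sample_date(rng, year),
            state,
            _sample_age(rng, config.age_model),
            sex_codes[rng.choice(3, p=np.asarray(config.sex_probs))],
            "Y" if rng.random() < 0.01 else "",
            "Y" if rng.random() < 0.02 else "",
            "Y" if rng.random() < 0.10 else "",
            "",
        ])
        for code in report_vaccines:
            vax_rows.append([
                rid,
                code,
                _MANUFACTURERS[rng.choice(len(_MANUFACTURERS))],
                str(int(rng.integers(1, 4))),
                _ROUTES[rng.choice(len(_ROUTES))],
                _SITES[rng.choice(len(_SITES))],
                f"{code} (GENERIC)",
            ])
        for start in range(0, len(report_symptoms), MAX_SYMPTOMS_PER_ROW):
            chunk = report_symptoms[start:start + MAX_SYMPTOMS_PER_ROW]
            sym_rows.append([rid] + chunk + [""] * (MAX_SYMPTOMS_PER_ROW - len(chunk)))

    def _frame(rows: Sequence[Sequence[str]], columns: list[str]) -> pd.DataFrame:
        if not rows:
            return pd.DataFrame(columns=columns, dtype=str)
        return pd.DataFrame(rows, columns=columns, dtype=str)

    return RawTables(
        data=_frame(data_rows, DATA_COLUMNS),
        vaccine=_frame(vax_rows, VAX_COLUMNS),
        symptom=_frame(sym_rows, SYMPTOM_COLUMNS),
    )
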