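"""End-to-end orchestration: raw tables -> summaries -> RDF -> networks.

One :class:`PipelineConfig` drives every stage; :func:`run_pipeline`
writes all artifacts (summary CSV, Turtle document, network exports,
metrics JSON, run manifest) into an output directory. Identical
configuration and seed produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .associations import (
    DEFAULT_AGE_BINS,
    AgeBins,
    occurrence_frame,
    significant_associations,
    summaries_to_frame,
    summarize_associations,
)
from .io import RawTables, read_raw_tables, write_raw_tables, join_reports
from .network import OVERALL, build_network, compare_years, metrics, write_edge_list, write_graphml
from .rdf import VAERS, to_rdf, write_turtle
from .synthetic import SignalSpec, SimConfig, simulate_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for one full run.

    Exactly one of ``input_dir`` (read an existing three-table dataset)
    or ``sim`` (generate one) must be set. ``network_years`` selects the
    per-year networks to build and compare alongside the pooled one.
    """

    output_dir: Path
    input_dir: Path | None = None
    prefix: str | None = None
    sim: SimConfig | None = None
    age_bins: AgeBins = dataclasses.field(default_factory=lambda: DEFAULT_AGE_BINS)
    prr_mode: str = "paper"
    significance_rule: str = "overall"
    prr_threshold: float = 1.0
    min_count: int = 0
    min_prr: float | None = None
    network_years: tuple[int, ...] = ()
    namespace: str = str(VAERS)

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.sim is None):
            raise PipelineError("config", "exactly one of input_dir or sim must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        sim = None
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"])
            signals = tuple(
                SignalSpec(
                    vaccine=s["vaccine"],
                    symptom=s["symptom"],
                    enrichment=float(s["enrichment"]),
                    years=tuple(s["years"]) if s.get("years") else None,
                )
                for s in sim_raw.pop("signals", [])
            )
            for key in ("year_range", "vaccines_per_report", "symptoms_per_report"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = SimConfig(signals=signals, **sim_raw)
        return cls(
            output_dir=Path(raw["output_dir"]),
            input_dir=Path(raw["input_dir"]) if raw.get("input_dir") else None,
            prefix=raw.get("prefix"),
            sim=sim,
            prr_mode=raw.get("prr_mode", "paper"),
            significance_rule=raw.get("significance_rule", "overall"),
            prr_threshold=float(raw.get("prr_threshold", 1.0)),
            min_count=int(raw.get("min_count", 0)),
            min_prr=raw.get("min_prr"),
            network_years=tuple(raw.get("network_years", ())),
            namespace=raw.get("namespace", str(VAERS)),
        )

    def canonical(self) -> str:
        # the hash describes the analysis, not where its artifacts land
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        return json.dumps(payload, sort_keys=True, default=str)


def _jsonable(value: Any) -> Any:
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    return value


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write all artifacts; returns the manifest.

    Artifacts under ``config.output_dir``: ``raw/`` (simulated datasets
    only), ``summaries.csv``, ``associations.ttl``, per-scope network
    edge lists / GraphML / a combined ``metrics.json`` (with the Venn
    overlap when two or more yearly networks were built), and
    ``manifest.json`` recording the configuration hash, seed, stage row
    counts, and package version.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if config.sim is not None:
            tables = simulate_dataset(config.sim)
            write_raw_tables(tables, out / "raw")
            logger.info("simulated %d reports", len(tables.data))
        else:
            tables = read_raw_tables(config.input_dir, prefix=config.prefix)
            logger.info("read %d report rows from %s", len(tables.data), config.input_dir)
    except Exception as exc:  # noqa: BLE001 - re-tag with stage name
        raise PipelineError("ingest", str(exc)) from exc

    try:
        collection = join_reports(tables)
        logger.info(
            "joined %d reports (%d orphan vaccine rows, %d orphan symptom rows)",
            len(collection), collection.orphan_vaccine_rows, collection.orphan_symptom_rows,
        )
        if len(collection) == 0:
            logger.warning("dataset is empty; artifacts will be empty but valid")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("join", str(exc)) from exc

    try:
        occurrences = occurrence_frame(collection)
        summaries = summarize_associations(
            collection,
            age_bins=config.age_bins,
            mode=config.prr_mode,  # type: ignore[arg-type]
            min_count=config.min_count,
            min_prr=config.min_prr,
        )
        summary_frame = summaries_to_frame(summaries)
        summary_frame.to_csv(out / "summaries.csv", index=False, lineterminator="\n")
        significance = significant_associations(summaries, rule=config.significance_rule)  # type: ignore[arg-type]
        logger.info(
            "extracted %d pair occurrences, %d distinct pairs, %d significant (%s), %d significant pair-years",
            len(occurrences), len(summaries), len(significance.pairs),
            config.significance_rule, significance.pair_year_count,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("summarize", str(exc)) from exc

    try:
        graph = to_rdf(summaries.values(), namespace=config.namespace)
        write_turtle(graph, out / "associations.ttl")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("rdf", str(exc)) from exc

    try:
        scopes: list[int | str] = [OVERALL, *config.network_years]
        nets = {}
        all_metrics: dict[str, Any] = {}
        for scope in scopes:
            net = build_network(summaries, scope=scope, threshold=config.prr_threshold)
            nets[scope] = net
            write_edge_list(net, out / f"network_{scope}.tsv")
            write_graphml(net, out / f"network_{scope}.graphml")
            all_metrics[str(scope)] = metrics(net).as_dict()
        yearly_nets = {year: nets[year] for year in config.network_years}
        if len(yearly_nets) >= 2:
            overlap = compare_years(yearly_nets)
            all_metrics["overlap"] = {
                "|".join(map(str, key)): {
                    "vaccines": list(region.vaccines),
                    "symptoms": list(region.symptoms),
                    "count": region.count,
                }
                for key, region in sorted(overlap.regions.items())
            }
        with open(out / "metrics.json", "w") as handle:
            json.dump(_jsonable(all_metrics), handle, indent=2, sort_keys=True)
            handle.write("\n")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("network", str(exc)) from exc

    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "seed": config.sim.seed if config.sim is not None else None,
        "counts": {
            "reports": len(collection),
            "orphan_vaccine_rows": collection.orphan_vaccine_rows,
            "orphan_symptom_rows": collection.orphan_symptom_rows,
            "pair_occurrences": int(len(occurrences)),
            "distinct_pairs": len(summaries),
            "significant_pairs": len(significance.pairs),
            "significance_rule": config.significance_rule,
            "significant_pair_years": significance.pair_year_count,
            "rdf_triples": len(graph),
            "networks": {str(scope): {"n_node": nets[scope].number_of_nodes(),
                                      "n_link": nets[scope].number_of_edges()}
                         for scope in scopes},
        },
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
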