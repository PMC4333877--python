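"""RDF/Turtle serialization of vaccine-symptom association summaries.

Each pair becomes an OWL instance ``vaers:VaccineSymptomMeta_<k>`` linked
to its vaccine and symptom individuals via ``hasVaccine`` / ``hasSymptom``
and carrying its pooled PRR on ``hasOverallPRR``. Yearly PRRs and per-year
age/gender cells hang off the instance as blank detail nodes under
``hasPRRDetail`` / ``hasVAERSAgeDetail`` / ``hasVAERSGenderDetail``::

    vaers:VaccineSymptomMeta_1
        vaers:hasSymptom vaers:intussusception ;
        vaers:hasVaccine vaers:PNC ;
        vaers:hasOverallPRR "4.7518"^^xsd:float ;
        vaers:hasPRRDetail [ vaers:hasPRR "7.1539"^^xsd:float ;
                             vaers:hasYear "2009"^^xsd:long ] ;
        ...

Literal datatypes are xsd:float for PRRs and percentages (rendered to 7
significant digits), xsd:long for years and counts, xsd:string for group
labels. Serialization is deterministic: blank nodes get stable labels and
the statement set depends only on the summaries.
"""

from __future__ import annotations

import logging
import re
import urllib.parse
from typing import Iterable, Mapping

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL, XSD

from .associations import AssociationSummary, GroupCell, YearlyDetail

logger = logging.getLogger(__name__)

#: default namespace for the vocabulary and the instance data
VAERS = Namespace("http://sbmi.uth.edu/ontology/vaers#")

CLASS_ASSOCIATION = "VaccineSymptomAssociation"
#: the originally published spelling of the association class
CLASS_ASSOCIATION_LEGACY = "VaccineSymotomAssociation"
CLASS_VACCINE = "Vaccine"
CLASS_SYMPTOM = "Symptom"

OBJECT_PROPERTIES = ("hasSymptom", "hasVaccine", "hasPRRDetail", "hasVAERSAgeDetail", "hasVAERSGenderDetail")
DATA_PROPERTIES = ("hasOverallPRR", "hasPRR", "hasYear", "hasAgeGroup", "hasGenderGroup", "hasCount", "hasPercentage")


class RdfValidationError(ValueError):
    """Raised when a parsed document violates the vocabulary contract."""


def format_float7(value: float) -> str:
    """Render a float to 7 significant digits, single-precision style.

    31/63 -> ``"0.4920635"``; 1.0 -> ``"1.0"``; 4.7518 -> ``"4.7518"``.
    """
    s = f"{float(value):.7g}"
    if "e" not in s and "E" not in s and "." not in s:
        s += ".0"
    return s


def symptom_iri(namespace: Namespace, term: str) -> URIRef:
    """Symptom individual IRI: lowercased term, whitespace to underscores."""
    local = re.sub(r"\s+", "_", term.strip().lower())
    return namespace[urllib.parse.quote(local, safe="_-.")]


def vaccine_iri(namespace: Namespace, code: str) -> URIRef:
    """Vaccine individual IRI: the raw vaccine code."""
    return namespace[urllib.parse.quote(code.strip(), safe="_-.")]


def _float_literal(value: float) -> Literal:
    return Literal(format_float7(value), datatype=XSD.float)


def _long_literal(value: int) -> Literal:
    return Literal(str(int(value)), datatype=XSD.long)


def _sorted_pairs(summaries: Iterable[AssociationSummary]) -> list[AssociationSummary]:
    return sorted(summaries, key=lambda s: (s.vaccine, s.symptom))


def to_rdf(
    summaries: Iterable[AssociationSummary],
    namespace: str | Namespace = VAERS,
    *,
    declare_individuals: bool = True,
    legacy_class_name: bool = False,
    validate: bool = True,
) -> Graph:
    """Serialize summaries to an rdflib graph in the vaers vocabulary.

    Instances are numbered ``VaccineSymptomMeta_1`` ... in sorted
    (vaccine, symptom) order. With ``declare_individuals`` (default) each
    association, vaccine, and symptom also gets an rdf:type triple and
    vaccine/symptom individuals an rdfs:label preserving the original
    code/term; without it, the graph holds exactly the listing-style
    statements: per pair 3 + 3 per year + 5 per age cell + 5 per gender
    cell. ``legacy_class_name`` reproduces the originally published class
    spelling.
    """
    ns = Namespace(str(namespace))
    graph = Graph()
    graph.bind("vaers", ns)
    graph.bind("xsd", XSD)
    graph.bind("owl", OWL)

    assoc_class = ns[CLASS_ASSOCIATION_LEGACY if legacy_class_name else CLASS_ASSOCIATION]
    blank_counter = 0

    def blank() -> BNode:
        nonlocal blank_counter
        blank_counter += 1
        return BNode(f"d{blank_counter}")

    for k, summary in enumerate(_sorted_pairs(summaries), start=1):
        if validate:
            summary.validate()
        inst = ns[f"VaccineSymptomMeta_{k}"]
        v_iri = vaccine_iri(ns, summary.vaccine)
        s_iri = symptom_iri(ns, summary.symptom)
        graph.add((inst, ns.hasSymptom, s_iri))
        graph.add((inst, ns.hasVaccine, v_iri))
        if summary.overall_prr is not None:
            graph.add((inst, ns.hasOverallPRR, _float_literal(summary.overall_prr)))
        if declare_individuals:
            graph.add((inst, RDF.type, assoc_class))
            graph.add((v_iri, RDF.type, ns[CLASS_VACCINE]))
            graph.add((v_iri, RDFS.label, Literal(summary.vaccine)))
            graph.add((s_iri, RDF.type, ns[CLASS_SYMPTOM]))
            graph.add((s_iri, RDFS.label, Literal(summary.symptom)))
        for year, detail in sorted(summary.yearly.items()):
            if detail.prr is None:
                continue
            node = blank()
            graph.add((inst, ns.hasPRRDetail, node))
            graph.add((node, ns.hasPRR, _float_literal(detail.prr)))
            graph.add((node, ns.hasYear, _long_literal(year)))
        for predicate, label_predicate, cells in (
            (ns.hasVAERSAgeDetail, ns.hasAgeGroup, summary.age_detail),
            (ns.hasVAERSGenderDetail, ns.hasGenderGroup, summary.gender_detail),
        ):
            for (year, label), cell in sorted(cells.items()):
                node = blank()
                graph.add((inst, predicate, node))
                graph.add((node, label_predicate, Literal(label, datatype=XSD.string)))
                graph.add((node, ns.hasCount, _long_literal(cell.count)))
                graph.add((node, ns.hasPercentage, _float_literal(cell.percentage)))
                graph.add((node, ns.hasYear, _long_literal(year)))
    return graph


def _local_name(iri: URIRef, ns: Namespace) -> str:
    prefix = str(ns)
    text = str(iri)
    return urllib.parse.unquote(text[len(prefix):] if text.startswith(prefix) else text.rsplit("#", 1)[-1])


def from_rdf(graph: Graph, namespace: str | Namespace = VAERS) -> dict[tuple[str, str], AssociationSummary]:
    """Reconstruct association summaries from a vaers-vocabulary graph.

    The inverse of :func:`to_rdf` up to the 7-significant-digit float
    rendering: yearly counts are recovered by summing the year's gender
    cells (falling back to age cells), and vaccine/symptom names come
    from rdfs:label where present, else the IRI local name. Unknown vaers
    predicates are logged as warnings; an association missing hasVaccine
    or hasSymptom raises :class:`RdfValidationError`.
    """
    ns = Namespace(str(namespace))
    known = {str(ns[p]) for p in OBJECT_PROPERTIES + DATA_PROPERTIES}
    for _s, p, _o in graph:
        if str(p).startswith(str(ns)) and str(p) not in known:
            logger.warning("unknown predicate in vaers namespace: %s", p)

    instances = set(graph.subjects(ns.hasVaccine, None)) | set(graph.subjects(ns.hasSymptom, None))
    for typed in (CLASS_ASSOCIATION, CLASS_ASSOCIATION_LEGACY):
        instances |= set(graph.subjects(RDF.type, ns[typed]))

    def individual_name(node) -> str:
        label = graph.value(node, RDFS.label)
        return str(label) if label is not None else _local_name(node, ns)

    summaries: dict[tuple[str, str], AssociationSummary] = {}
    for inst in sorted(instances, key=str):
        v_node = graph.value(inst, ns.hasVaccine)
        s_node = graph.value(inst, ns.hasSymptom)
        missing = [name for name, node in (("hasVaccine", v_node), ("hasSymptom", s_node)) if node is None]
        if missing:
            raise RdfValidationError(f"association {inst} lacks required propert{'y' if len(missing) == 1 else 'ies'} {', '.join(missing)}")
        vaccine = individual_name(v_node)
        symptom = individual_name(s_node)

        overall = graph.value(inst, ns.hasOverallPRR)
        yearly_prr: dict[int, float] = {}
        for node in graph.objects(inst, ns.hasPRRDetail):
            year = int(graph.value(node, ns.hasYear))
            yearly_prr[year] = float(graph.value(node, ns.hasPRR))

        age_detail: dict[tuple[int, str], GroupCell] = {}
        gender_detail: dict[tuple[int, str], GroupCell] = {}
        for predicate, label_predicate, target in (
            (ns.hasVAERSAgeDetail, ns.hasAgeGroup, age_detail),
            (ns.hasVAERSGenderDetail, ns.hasGenderGroup, gender_detail),
        ):
            for node in graph.objects(inst, predicate):
                year = int(graph.value(node, ns.hasYear))
                label = str(graph.value(node, label_predicate))
                target[(year, label)] = GroupCell(
                    count=int(graph.value(node, ns.hasCount)),
                    percentage=float(graph.value(node, ns.hasPercentage)),
                )

        # each complete breakdown sums to the yearly count; a partial
        # document may carry only some cells, so take the larger sum
        gender_sums: dict[int, int] = {}
        age_sums: dict[int, int] = {}
        for (year, _label), cell in gender_detail.items():
            gender_sums[year] = gender_sums.get(year, 0) + cell.count
        for (year, _label), cell in age_detail.items():
            age_sums[year] = age_sums.get(year, 0) + cell.count
        year_counts = {
            year: max(gender_sums.get(year, 0), age_sums.get(year, 0))
            for year in set(gender_sums) | set(age_sums)
        }
        yearly = {
            year: YearlyDetail(prr=yearly_prr.get(year), count=year_counts.get(year, 0))
            for year in sorted(set(yearly_prr) | set(year_counts))
        }
        summaries[(vaccine, symptom)] = AssociationSummary(
            vaccine=vaccine,
            symptom=symptom,
            overall_prr=float(overall) if overall is not None else None,
            yearly=yearly,
            age_detail=age_detail,
            gender_detail=gender_detail,
        )
    return summaries


def link_stub(
    summaries: Iterable[AssociationSummary],
    external_map: Mapping[str, str],
    namespace: str | Namespace = VAERS,
    **to_rdf_kwargs,
) -> Graph:
    """Serialize summaries and add owl:sameAs links for mapped vaccines.

    ``external_map`` maps vaccine codes to external IRIs (for example
    Vaccine Ontology identifiers). One linkage triple is added per map
    entry whose code occurs in the data; nothing is fetched. An empty map
    leaves the document identical to :func:`to_rdf`.
    """
    summaries = list(summaries)
    ns = Namespace(str(namespace))
    graph = to_rdf(summaries, ns, **to_rdf_kwargs)
    present = {s.vaccine for s in summaries}
    for code in sorted(set(external_map) & present):
        graph.add((vaccine_iri(ns, code), OWL.sameAs, URIRef(external_map[code])))
    return graph


def serialize_turtle(graph: Graph) -> str:
    """Turtle text; an empty graph still carries its prefix declarations."""
    text = graph.serialize(format="turtle")
    if len(graph) == 0:
        namespaces = dict(graph.namespaces())
        lines = [
            f"@prefix {prefix}: <{uri}> ."
            for prefix, uri in sorted(namespaces.items())
            if prefix in ("vaers", "xsd", "owl")
        ]
        text = "\n".join(lines) + "\n"
    return text


def write_turtle(graph: Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(serialize_turtle(graph))


def write_ntriples(graph: Graph, path) -> None:
    """N-Triples emission for line-oriented diffing."""
    Graph.serialize(graph, destination=str(path), format="nt", encoding="utf-8")
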