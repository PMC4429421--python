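"""Parameterised SPARQL templates for the three canonical query patterns.

The three patterns exercise the cube topology and the enrichment linksets:

threshold_count
    "How many participants have hypertension?" — counts distinct subjects
    whose two vital-sign readings at one timepoint both exceed their
    thresholds (strictly), with the study variables resolved from CDISC
    standard properties through a ``rdfs:subPropertyOf*`` lookup, so the
    query can be phrased in either the study's or the standard's terms.
drug_class_count
    "How many participants take an anti-diabetic drug?" — resolves the
    drugs of a DrugBank category, follows the ``skos:exactMatch`` links
    back to study medication records, and returns (count, product name)
    rows.  Executed as a local join over co-loaded graphs.
transition_count
    "Whose classification moved from healthy to MCI while triglycerides
    stayed normal (< 1.7 mmol/L)?" — spans two specialised cubes and both
    timepoints, grouped by (from-state, to-state).

All templates return aggregate counts only; no result row ever carries a
subject identifier.  Rendering is deterministic (``string.Template`` over
flat parameters) and every rendered query is kept on the returned
:class:`QueryTemplate` for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import Template

from rdflib import Graph, RDFS, URIRef

from .lcdc_model import LCDC

_PREFIXES = """\
PREFIX qb: <http://purl.org/linked-data/cube#>
PREFIX lcdc: <http://example.org/lcdc/ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX skos: <http://www.w3.org/2004/02/skos/core#>
PREFIX dcterms: <http://purl.org/dc/terms/>
"""


class CouplingError(LookupError):
    """A standard property has no coupled study variable in the graphs."""


class UnknownConceptError(LookupError):
    """A class concept or state code is absent from the loaded graphs."""


@dataclass(frozen=True)
class QueryTemplate:
    template_id: str            # threshold_count | drug_class_count | transition_count
    parameters: dict
    sparql: str


_THRESHOLD_SPARQL = Template(_PREFIXES + """
SELECT (COUNT(DISTINCT ?subj) AS ?n) WHERE {
  {
    VALUES ?v1 { $props1 }
    ?obs1 a qb:Observation ;
          lcdc:variable ?v1 ;
          lcdc:timepoint "$timepoint" ;
          lcdc:subject ?subj ;
          lcdc:value ?x1 .
    FILTER(?x1 > $threshold1)
  }
  {
    VALUES ?v2 { $props2 }
    ?obs2 a qb:Observation ;
          lcdc:variable ?v2 ;
          lcdc:timepoint "$timepoint" ;
          lcdc:subject ?subj ;
          lcdc:value ?x2 .
    FILTER(?x2 > $threshold2)
  }
}
""")


def resolve_subproperties(graph: Graph, prop: str) -> set[str]:
    """The sub-property closure of ``prop`` over the graph's
    ``rdfs:subPropertyOf`` triples, including ``prop`` itself — the
    variable-name lookup behind the standard-terminology queries.

    Computed as a reverse fixpoint in Python and injected into the SPARQL
    as a ``VALUES`` block, which keeps the lookup semantics of a
    ``rdfs:subPropertyOf*`` path while staying tractable for the local
    query engine.
    """
    reverse: dict[str, set[str]] = {}
    for s, o in graph.subject_objects(RDFS.subPropertyOf):
        reverse.setdefault(str(o), set()).add(str(s))
    closure = {prop}
    frontier = [prop]
    while frontier:
        node = frontier.pop()
        for sub in reverse.get(node, ()):
            if sub not in closure:
                closure.add(sub)
                frontier.append(sub)
    return closure


def _coupled_with_data(graph: Graph, prop: str) -> list[str]:
    """The sub-property closure restricted to properties actually used as a
    variable dimension by some observation."""
    return sorted(v for v in resolve_subproperties(graph, prop)
                  if next(graph.subjects(LCDC.variable, URIRef(v)), None)
                  is not None)


def render_threshold(standard_props: tuple[str, str],
                     thresholds: tuple[float, float],
                     timepoint: str,
                     resolved: tuple[list[str], list[str]] | None = None
                     ) -> QueryTemplate:
    resolved = resolved or ([standard_props[0]], [standard_props[1]])
    sparql = _THRESHOLD_SPARQL.substitute(
        props1=" ".join(f"<{p}>" for p in resolved[0]),
        props2=" ".join(f"<{p}>" for p in resolved[1]),
        threshold1=thresholds[0], threshold2=thresholds[1],
        timepoint=timepoint)
    return QueryTemplate("threshold_count",
                         {"standard_props": standard_props,
                          "thresholds": thresholds, "timepoint": timepoint},
                         sparql)


def threshold_count(graph: Graph, standard_props: tuple[str, str],
                    thresholds: tuple[float, float],
                    timepoint: str) -> int:
    """Count distinct subjects whose readings for both (coupled) properties
    at ``timepoint`` are strictly greater than their thresholds.  Subjects
    missing either reading are excluded by the join; a property with no
    coupling raises :class:`CouplingError` rather than silently counting
    zero."""
    resolved = []
    for prop in standard_props:
        vs = _coupled_with_data(graph, prop)
        if not vs:
            raise CouplingError(
                f"no study variable is coupled to {prop!r} "
                "(and it is not itself a study variable with data)")
        resolved.append(vs)
    template = render_threshold(standard_props, thresholds, timepoint,
                                (resolved[0], resolved[1]))
    rows = list(graph.query(template.sparql))
    return int(rows[0][0]) if rows and rows[0][0] is not None else 0


_DRUG_CLASS_SPARQL = Template(_PREFIXES + """
SELECT ?name (COUNT(DISTINCT ?subj) AS ?n) WHERE {
  ?drug dcterms:subject <$class_concept> ;
        rdfs:label ?name .
  ?med skos:exactMatch ?drug ;
       a lcdc:MedicationRecord ;
       lcdc:subject ?subj .
}
GROUP BY ?name
ORDER BY ?name
""")


def render_drug_class(class_concept: str) -> QueryTemplate:
    return QueryTemplate(
        "drug_class_count", {"class_concept": class_concept},
        _DRUG_CLASS_SPARQL.substitute(class_concept=class_concept))


def drug_class_count(graph: Graph,
                     class_concept: str) -> list[tuple[int, str]]:
    """Per-drug distinct-subject counts for one drug-classification concept,
    as (count, medicinal product name) rows sorted by name.  Unknown class
    concepts raise :class:`UnknownConceptError`; a known class with no
    matched prescriptions returns zero rows."""
    concept = URIRef(class_concept)
    if (None, None, concept) not in graph and (concept, None, None) not in graph:
        raise UnknownConceptError(
            f"class concept {class_concept!r} absent from the loaded graphs")
    template = render_drug_class(class_concept)
    return [(int(n), str(name)) for name, n in graph.query(template.sparql)]


# the four observation blocks are braced groups so that solutions flow
# block-to-block joined on ?subj; a single flat pattern list would let the
# query engine evaluate all selective patterns first and cross-product the
# four unjoined observation variables
_TRANSITION_SPARQL = Template(_PREFIXES + """
SELECT ?c1 ?c2 (COUNT(DISTINCT ?subj) AS ?n) WHERE {
  {
    ?obs1a a qb:Observation ;
           lcdc:variable <$class_var> ;
           lcdc:timepoint "$tp1" ;
           lcdc:subject ?subj ;
           lcdc:value ?c1 .
    FILTER(?c1 IN ($from_states))
  }
  {
    ?obs1b a qb:Observation ;
           lcdc:variable <$class_var> ;
           lcdc:timepoint "$tp2" ;
           lcdc:subject ?subj ;
           lcdc:value ?c2 .
    FILTER(?c2 IN ($to_states))
  }
  {
    ?obs2a a qb:Observation ;
           lcdc:variable <$quant_var> ;
           lcdc:timepoint "$tp1" ;
           lcdc:subject ?subj ;
           lcdc:value ?x1 .
    FILTER(?x1 < $upper_bound)
  }
  {
    ?obs2b a qb:Observation ;
           lcdc:variable <$quant_var> ;
           lcdc:timepoint "$tp2" ;
           lcdc:subject ?subj ;
           lcdc:value ?x2 .
    FILTER(?x2 < $upper_bound)
  }
}
GROUP BY ?c1 ?c2
ORDER BY ?c1 ?c2
""")


def _literal_list(values: list[str]) -> str:
    return ", ".join('"%s"' % v.replace('"', '\\"') for v in values)


def render_transition(class_var: str, from_states: list[str],
                      to_states: list[str], quant_var: str,
                      upper_bound: float,
                      timepoints: tuple[str, str]) -> QueryTemplate:
    sparql = _TRANSITION_SPARQL.substitute(
        class_var=class_var, quant_var=quant_var,
        from_states=_literal_list(from_states),
        to_states=_literal_list(to_states),
        upper_bound=upper_bound, tp1=timepoints[0], tp2=timepoints[1])
    return QueryTemplate(
        "transition_count",
        {"class_var": class_var, "from_states": from_states,
         "to_states": to_states, "quant_var": quant_var,
         "upper_bound": upper_bound, "timepoints": timepoints},
        sparql)


def transition_count(graph: Graph, class_var: str, from_states: list[str],
                     to_states: list[str], quant_var: str,
                     upper_bound: float, timepoints: tuple[str, str],
                     codelist: set[str] | None = None
                     ) -> dict[tuple[str, str], int]:
    """Count subjects whose classification is in ``from_states`` at the
    first timepoint and in ``to_states`` at the second, with the
    quantitative variable strictly below ``upper_bound`` at BOTH
    timepoints; grouped by (from-state, to-state).

    When the classification codelist is supplied, unknown state codes raise
    :class:`UnknownConceptError` listing the valid codes.
    """
    if codelist is not None:
        unknown = [s for s in [*from_states, *to_states]
                   if s not in codelist]
        if unknown:
            raise UnknownConceptError(
                f"unknown state code(s) {unknown}; codelist: "
                f"{sorted(codelist)}")
    template = render_transition(class_var, from_states, to_states,
                                 quant_var, upper_bound, timepoints)
    return {(str(c1), str(c2)): int(n)
            for c1, c2, n in graph.query(template.sparql)}
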