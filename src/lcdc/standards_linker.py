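"""Couple study variables to CDISC CDASH/SDTM concepts.

Clinical studies that were not designed around CDISC can still be
retrofitted to it: vital-sign items map onto the VS domain, blood work onto
LB (Laboratory Test), patient-reported medications onto CM (Concomitant
Medications), demographics onto DM/SC, questionnaire items onto QS, and the
visit structure onto the trial-design domains.  Two artefacts make that
usable in queries:

* a *linkset* of ``rdfs:subPropertyOf`` pairs from study-variable IRIs to
  standard-property IRIs, so a query phrased in CDISC terms resolves the
  study's own variable names through a sub-property lookup (variable-name
  information hiding);
* a *domain assignment* classifying every variable into one CDISC domain
  (or ``unassigned``), driven by a rules table over sub-themes and
  variable-name patterns — couplings are curated input, not guessed.

Linksets are written as standalone Turtle with a VoID linkset descriptor.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import Graph, Literal, RDF, RDFS, URIRef

from .lcdc_model import LCDC, SKOS, VOID, UriScheme, VariableDef, mint_iri

#: CDISC domains the assigner may produce.
CDISC_DOMAINS = frozenset({
    "VS", "LB", "MH", "CM", "DM", "SC", "QS", "TA", "TS", "TV", "SV",
    "unassigned",
})

SUBPROP = "subPropertyOf"
EXACT = "exactMatch"


class CdiscLookupError(KeyError):
    """A coupling target is absent from the CDISC concept fixture."""


class DomainRuleConflict(ValueError):
    """Two rules assign different domains to one variable."""


@dataclass(frozen=True)
class DomainAssignment:
    variable: str
    cdisc_domain: str
    rationale: str


@dataclass
class Linkset:
    """A single-predicate set of (source IRI, target IRI) pairs with VoID
    dataset descriptors."""

    name: str
    link_predicate: str = SUBPROP  # subPropertyOf | exactMatch
    pairs: set[tuple[str, str]] = field(default_factory=set)
    source_dataset: str = ""
    target_dataset: str = ""

    def __post_init__(self):
        if self.link_predicate not in (SUBPROP, EXACT):
            raise ValueError(
                f"unsupported linkset predicate {self.link_predicate!r}")

    def add(self, source: str, target: str) -> None:
        if source == target:
            raise ValueError(f"self-link rejected: {source}")
        self.pairs.add((source, target))


def couple_variable(study_var: VariableDef, cdisc_property: str,
                    linkset: Linkset,
                    cdisc_fixture: set[str] | Graph,
                    scheme: UriScheme | None = None) -> Linkset:
    """Add a ``subPropertyOf`` pair from the study variable to a CDISC
    standard property.  Idempotent; raises :class:`CdiscLookupError` when
    the property is not in the concept fixture."""
    known: set[str]
    if isinstance(cdisc_fixture, Graph):
        known = {str(s) for s in cdisc_fixture.subjects(RDF.type, None)}
    else:
        known = set(cdisc_fixture)
    if cdisc_property not in known:
        raise CdiscLookupError(
            f"{cdisc_property!r} not present in the CDISC concept fixture")
    scheme = scheme or UriScheme()
    source = mint_iri(scheme, "variable", [study_var.name])
    linkset.add(source, cdisc_property)
    study_var.cdisc_coupling = cdisc_property
    return linkset


@dataclass(frozen=True)
class DomainRule:
    """``match`` is either a sub-theme token (``sub_theme:medications``) or a
    glob over variable names (``name:*bp*``)."""

    match: str
    domain: str
    rationale: str = ""

    def applies(self, var: VariableDef) -> bool:
        kind, _, pattern = self.match.partition(":")
        if kind == "sub_theme":
            return var.universe[1] == pattern
        if kind == "theme":
            return var.universe[0] == pattern
        if kind == "name":
            return fnmatch.fnmatch(var.name, pattern)
        raise ValueError(f"unknown rule kind in {self.match!r}")


def assign_domains(variables: dict[str, VariableDef],
                   rules: list[DomainRule]) -> dict[str, DomainAssignment]:
    """Classify every variable into exactly one CDISC domain.

    Total and single-valued: a variable matching no rule is ``unassigned``;
    one matching rules with different domains raises
    :class:`DomainRuleConflict` listing the offending rules.
    """
    for rule in rules:
        if rule.domain not in CDISC_DOMAINS:
            raise ValueError(f"unknown CDISC domain {rule.domain!r}")
    out: dict[str, DomainAssignment] = {}
    for name, var in variables.items():
        hits = [r for r in rules if r.applies(var)]
        domains = {r.domain for r in hits}
        if len(domains) > 1:
            raise DomainRuleConflict(
                f"variable {name!r} matched conflicting rules: "
                + "; ".join(f"{r.match}->{r.domain}" for r in hits))
        if hits:
            r = hits[0]
            out[name] = DomainAssignment(name, r.domain,
                                         r.rationale or f"rule {r.match}")
        else:
            out[name] = DomainAssignment(name, "unassigned", "no rule matched")
    return out


#: Default rules covering the themes the study taxonomy uses.  Trial-design
#: domains (TA/TS/TV/SV) are assignable but have no default rule.
DEFAULT_DOMAIN_RULES = [
    DomainRule("sub_theme:medications", "CM",
               "patient-reported medications -> Concomitant Medications"),
    DomainRule("sub_theme:vitalsigns", "VS", "vital signs -> VS"),
    DomainRule("sub_theme:blood", "LB",
               "blood work -> Laboratory Test (LB)"),
    DomainRule("sub_theme:demographics", "DM",
               "demographics -> DM / Subject Characteristics"),
    DomainRule("sub_theme:neuropsych", "QS",
               "neuropsychological instruments -> Questionnaires"),
    DomainRule("sub_theme:medicalhistory", "MH", "medical history -> MH"),
]


def expand_standard_property(standard_prop: str,
                             linkset: Linkset) -> set[str]:
    """All study-variable IRIs coupled — directly or through a chain of
    sub-property links — to ``standard_prop``.  Empty set when uncoupled."""
    if linkset.link_predicate != SUBPROP:
        raise ValueError("expansion requires a subPropertyOf linkset")
    reverse: dict[str, set[str]] = {}
    for src, tgt in linkset.pairs:
        reverse.setdefault(tgt, set()).add(src)
    found: set[str] = set()
    frontier = [standard_prop]
    while frontier:
        node = frontier.pop()
        for src in reverse.get(node, ()):
            if src not in found:
                found.add(src)
                frontier.append(src)
    return found


_PREDICATE_IRI = {SUBPROP: RDFS.subPropertyOf, EXACT: SKOS.exactMatch}


def linkset_to_graph(linkset: Linkset) -> Graph:
    """Render the linkset as RDF: the pair triples plus a VoID linkset
    descriptor (source/target dataset, predicate, triple count)."""
    g = Graph()
    g.bind("void", VOID)
    g.bind("skos", SKOS)
    g.bind("rdfs", RDFS)
    g.bind("lcdc", LCDC)
    pred = _PREDICATE_IRI[linkset.link_predicate]
    for src, tgt in sorted(linkset.pairs):
        g.add((URIRef(src), pred, URIRef(tgt)))
    desc = URIRef(f"{LCDC}linkset/{linkset.name}")
    g.add((desc, RDF.type, VOID.Linkset))
    g.add((desc, VOID.linkPredicate, pred))
    g.add((desc, VOID.triples, Literal(len(linkset.pairs))))
    if linkset.source_dataset:
        g.add((desc, VOID.subjectsTarget, URIRef(linkset.source_dataset)))
    if linkset.target_dataset:
        g.add((desc, VOID.objectsTarget, URIRef(linkset.target_dataset)))
    return g


def write_linkset(linkset: Linkset, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(linkset_to_graph(linkset).serialize(format="turtle"))
    return path
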