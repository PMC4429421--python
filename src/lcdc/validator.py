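"""Integrity checks for emitted cube graphs and linksets.

The check set follows the data-cube well-formedness criteria restricted to
what the builder actually emits (fully explicit observations, no
abbreviations), plus the LCDC-specific topology: the three slice paths to
every observation group, subset links for every specialised cube, complete
main/specialised observation pairing, and the sub-property axiom.

The validator is pure: it never mutates a graph, and running it twice
yields identical reports (findings are ordered by check id, then IRI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from rdflib import Graph, RDF, RDFS

from .cube_builder import CubeSet, DIMENSIONS, MAIN
from .lcdc_model import LCDC, QB, VOID
from .standards_linker import Linkset, EXACT, SUBPROP


@dataclass(frozen=True)
class Finding:
    check_id: str
    status: str                      # pass | fail | warn
    offending: tuple[str, ...]
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    def add(self, check_id: str, status: str, offending=(), message=""):
        self.findings.append(
            Finding(check_id, status,
                    tuple(sorted(str(o) for o in offending)), message))

    def finalize(self) -> "ValidationReport":
        self.findings.sort(key=lambda f: (f.check_id, f.offending))
        return self

    @property
    def passed(self) -> bool:
        return all(f.status != "fail" for f in self.findings)

    def failures(self) -> list[Finding]:
        return [f for f in self.findings if f.status == "fail"]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["check_id\tstatus\toffending\tmessage"]
        lines += [f"{f.check_id}\t{f.status}\t{','.join(f.offending)}\t"
                  f"{f.message}" for f in self.findings]
        path.write_text("\n".join(lines) + "\n")
        return path


def _check(report: ValidationReport, check_id: str, offenders: list,
           ok_msg: str, fail_msg: str) -> None:
    if offenders:
        report.add(check_id, "fail", offenders, fail_msg)
    else:
        report.add(check_id, "pass", (), ok_msg)


def check_qb_integrity(graph: Graph) -> ValidationReport:
    """Well-formedness of one cube graph: every observation has exactly one
    dataset link and all DSD dimensions; slice fixed-dimension values agree
    with their members; no two observations share a dimension tuple within
    a dataset."""
    report = ValidationReport()
    observations = sorted(graph.subjects(RDF.type, QB.Observation))
    if not observations:
        report.add("qb-empty", "warn", (),
                   "graph contains no observations; checks are vacuous")

    bad_ds = [o for o in observations
              if len(list(graph.objects(o, QB.dataSet))) != 1]
    _check(report, "qb-dataset-link", bad_ds,
           "every observation has exactly one qb:dataSet link",
           "observation lacks a unique qb:dataSet link")

    bad_dims = [o for o in observations
                if any(graph.value(o, d) is None for d in DIMENSIONS)]
    _check(report, "qb-dimensions-complete", bad_dims,
           "every observation supplies all DSD dimensions",
           "observation missing a dimension value")

    # slice fixed-dimension consistency (timepoint- and subject-fixed slices)
    bad_slices = []
    for s in sorted(graph.subjects(RDF.type, QB.Slice)):
        for dim in (LCDC.timepoint, LCDC.subject):
            fixed = graph.value(s, dim)
            if fixed is None:
                continue
            for member in graph.objects(s, QB.observation):
                if graph.value(member, dim) != fixed:
                    bad_slices.append(s)
    _check(report, "qb-slice-consistent", sorted(set(bad_slices)),
           "slice fixed dimensions agree with member observations",
           "slice member contradicts the slice's fixed dimension")

    seen: dict[tuple, object] = {}
    dupes = []
    for o in observations:
        key = (graph.value(o, QB.dataSet),
               *(graph.value(o, d) for d in DIMENSIONS))
        if key in seen and seen[key] != o:
            dupes.append(o)
        seen[key] = o
    _check(report, "qb-no-duplicate-observation", dupes,
           "no duplicate observation for any dimension tuple",
           "two observations share one dimension tuple")
    return report.finalize()


def check_lcdc_topology(cs: CubeSet) -> ValidationReport:
    """LCDC-specific topology over the full cube set."""
    report = ValidationReport()
    mg = cs.main_graph
    groups = sorted(mg.subjects(RDF.type, QB.ObservationGroup))

    # three slice paths to every observation group
    slice_kinds = {
        "phase series": set(cs.phase_series.values()),
        "subject section": set(cs.subject_sections.values()),
        "sub-theme slice": set(cs.theme_slices.values()),
    }
    for label, slices in slice_kinds.items():
        reachable = set()
        for s in slices:
            reachable.update(mg.objects(s, QB.observationGroup))
        missing = [g for g in groups if g not in reachable]
        _check(report, f"lcdc-path-{label.replace(' ', '-')}", missing,
               f"every observation group is reachable from a {label}",
               f"observation group not reachable from any {label}")

    # subset links for every specialised cube
    if not cs.spec_datasets:
        report.add("lcdc-subset-links", "warn", (),
                   "cube set has no specialised cubes")
    else:
        missing = [ds for theme, ds in sorted(cs.spec_datasets.items())
                   if (cs.main_dataset, VOID.subset, ds)
                   not in cs.link_graph]
        _check(report, "lcdc-subset-links", missing,
               "every specialised dataset is a void:subset of the main one",
               "specialised dataset missing its void:subset link")

    # complete main/specialised pairing
    spec_obs = set()
    for g in cs.specialised_graphs.values():
        spec_obs.update(g.subjects(RDF.type, QB.Observation))
    unpaired = []
    for grp in groups:
        main_o = mg.value(grp, LCDC.mainObservation)
        spec_o = mg.value(grp, LCDC.specialisedObservation)
        if (main_o is None or spec_o is None
                or (main_o, RDF.type, QB.Observation) not in mg
                or spec_o not in spec_obs):
            unpaired.append(grp)
    _check(report, "lcdc-pairing-complete", unpaired,
           "every observation group pairs a main and a specialised "
           "observation",
           "observation group with missing or dangling pairing")

    axiom_count = sum(
        1 for _ in cs.link_graph.triples(
            (LCDC.specialisedObservation, RDFS.subPropertyOf,
             QB.observation)))
    if axiom_count == 1:
        report.add("lcdc-subproperty-axiom", "pass", (),
                   "specialisedObservation sub-property axiom present once")
    else:
        report.add("lcdc-subproperty-axiom", "fail", (),
                   f"expected the sub-property axiom exactly once, "
                   f"found {axiom_count}")
    return report.finalize()


def check_linkset_closure(linkset: Linkset, source_graph: Graph,
                          target_fixture) -> ValidationReport:
    """Every pair endpoint resolves (sources as nodes of the source graph,
    targets against the fixture), no self-links, predicate whitelisted."""
    report = ValidationReport()
    if linkset.link_predicate not in (SUBPROP, EXACT):
        report.add("linkset-predicate", "fail", (),
                   f"predicate {linkset.link_predicate!r} not allowed")
    else:
        report.add("linkset-predicate", "pass", (),
                   "link predicate is whitelisted")

    if isinstance(target_fixture, Graph):
        targets = ({str(s) for s in target_fixture.subjects()}
                   | {str(o) for o in target_fixture.objects()})
    else:
        targets = set(target_fixture)
    source_nodes = ({str(s) for s in source_graph.subjects()}
                    | {str(o) for o in source_graph.objects()})

    self_links = [s for s, t in sorted(linkset.pairs) if s == t]
    _check(report, "linkset-no-self-links", self_links,
           "no pair links an IRI to itself", "self-link found")
    dangling_src = [s for s, _ in sorted(linkset.pairs)
                    if s not in source_nodes]
    _check(report, "linkset-source-resolves", dangling_src,
           "every source IRI resolves in the source graph",
           "source IRI absent from the source graph")
    dangling_tgt = [t for _, t in sorted(linkset.pairs)
                    if t not in targets]
    _check(report, "linkset-target-resolves", dangling_tgt,
           "every target IRI resolves in the target fixture",
           "target IRI absent from the target fixture")
    return report.finalize()


def materialize_subproperties(graph: Graph) -> Graph:
    """Return a copy with the one sub-property entailment applied: every
    ``lcdc:mainObservation`` / ``lcdc:specialisedObservation`` link is also
    visible as a generic ``qb:observation`` link."""
    out = Graph()
    for t in graph:
        out.add(t)
    for prop in (LCDC.mainObservation, LCDC.specialisedObservation):
        for s, o in graph.subject_objects(prop):
            out.add((s, QB.observation, o))
    return out
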