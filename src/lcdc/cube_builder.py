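"""Build the Linked Clinical Data Cube from parsed ODM records.

The LCDC is one *main* cube plus one *specialised* cube per study theme.
Every non-missing ItemData record becomes

* one observation in its theme's specialised cube,
* one observation in the main cube, and
* one observation group in the main cube joining the two via the
  ``lcdc:mainObservation`` / ``lcdc:specialisedObservation`` properties
  (the latter declared a sub-property of ``qb:observation``).

Missing values produce *no* observation — cube integrity is preserved on
patchy observational data by omission, not by null-valued observations.

Three slice families give three direct access paths to every record:

time-series
    one slice per (cube, timepoint) fixing the timepoint dimension, plus a
    *phase series* per timepoint in the main cube grouping observation
    groups (the Study-Event level of ODM);
cross-section
    one slice per (subject property, value) — e.g. gender, genotype,
    neurological classification — plus a *subject section* per subject
    (the Subject level);
theme
    one slice per sub-theme universe (the Item-Group level), linking the
    main and specialised cubes together.

Main-cube slices reference observation groups (``qb:observationGroup``);
specialised-cube slices reference observations (``qb:observation``).
Specialised datasets are declared ``void:subset``\\ s of the main dataset,
and corresponding slices across cubes are linked with
``lcdc:specialisedSeries`` (time) and ``lcdc:specialisedSection`` (subject).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import Graph, Literal, RDF, RDFS, URIRef, XSD

from .lcdc_model import (
    DISCO, LCDC, QB, VOID, UriScheme, Universe, VariableDef, mint_iri,
    variable_for_item,
)
from .odm_io import ODMDocument, ItemDataRecord, iter_records

log = logging.getLogger(__name__)

MAIN = "main"


class CubeConfigError(ValueError):
    """A record's form or variable lacks a theme/universe assignment."""


@dataclass
class ObsEntry:
    """Bookkeeping for one emitted observation trio (spec + main + group)."""

    record: ItemDataRecord
    theme: str
    sub_theme: str
    subject: str
    timepoint: str
    variable: str
    repeat: str
    spec_iri: URIRef
    main_iri: URIRef
    group_iri: URIRef


@dataclass
class CubeSet:
    """The emitted graphs plus the indexes the slicers and validator use."""

    scheme: UriScheme
    main_graph: Graph
    specialised_graphs: dict[str, Graph]
    link_graph: Graph
    main_dataset: URIRef
    spec_datasets: dict[str, URIRef]
    entries: list[ObsEntry] = field(default_factory=list)
    timepoints: list[str] = field(default_factory=list)
    # slice registries, filled by the build_*_slices functions
    time_slices: dict[tuple[str, str], URIRef] = field(default_factory=dict)
    phase_series: dict[str, URIRef] = field(default_factory=dict)
    subject_sections: dict[str, URIRef] = field(default_factory=dict)
    spec_subject_sections: dict[tuple[str, str], URIRef] = field(
        default_factory=dict)
    theme_slices: dict[tuple[str, str], URIRef] = field(default_factory=dict)
    cross_slices: dict[tuple[str, str], URIRef] = field(default_factory=dict)

    def graph_for(self, cube: str) -> Graph:
        return self.main_graph if cube == MAIN else self.specialised_graphs[cube]

    def all_graphs(self) -> Graph:
        """Union of every cube graph and the link graph (for querying)."""
        g = Graph()
        for other in [self.main_graph, self.link_graph,
                      *self.specialised_graphs.values()]:
            for t in other:
                g.add(t)
        return g


def _bind(g: Graph) -> Graph:
    g.bind("qb", QB)
    g.bind("disco", DISCO)
    g.bind("void", VOID)
    g.bind("lcdc", LCDC)
    g.bind("rdfs", RDFS)
    return g


_XSD_FOR = {"integer": XSD.integer, "float": XSD.double, "date": XSD.date}


def _value_literal(record: ItemDataRecord, datatype: str) -> Literal:
    xsd = _XSD_FOR.get(datatype)
    if xsd is not None:
        return Literal(record.typed_value, datatype=xsd)
    return Literal(str(record.typed_value))


def _emit_dsd(g: Graph, dataset: URIRef) -> None:
    """Minimal explicit DSD: four dimensions, one generic measure, a unit
    attribute.  Component nodes are minted IRIs (no blank nodes) so that
    canonical serialisations are byte-stable."""
    dsd = URIRef(str(dataset) + "/structure")
    g.add((dataset, QB.structure, dsd))
    g.add((dsd, RDF.type, QB.DataStructureDefinition))
    comps = [
        (QB.dimension, LCDC.subject, "dim-subject"),
        (QB.dimension, LCDC.timepoint, "dim-timepoint"),
        (QB.dimension, LCDC.variable, "dim-variable"),
        (QB.dimension, LCDC.repeat, "dim-repeat"),
        (QB.measure, LCDC.value, "measure-value"),
        (QB.attribute, LCDC.unit, "attr-unit"),
    ]
    for role, prop, slug in comps:
        node = URIRef(f"{dsd}/{slug}")
        g.add((dsd, QB.component, node))
        g.add((node, RDF.type, QB.ComponentSpecification))
        g.add((node, role, prop))


DIMENSIONS = (LCDC.subject, LCDC.timepoint, LCDC.variable, LCDC.repeat)


def build_cubeset(
    doc: ODMDocument,
    variables: dict[str, VariableDef],
    universes: dict[tuple[str, str], Universe],
    scheme: UriScheme,
    theme_map: dict[str, tuple[str, str]],
) -> CubeSet:
    """Emit the main cube, one specialised cube per theme present in the
    data, and the observation groups joining them.

    Raises :class:`CubeConfigError` if a record's form has no theme
    assignment or its variable no universe.
    """
    meta = doc.meta
    main_ds = URIRef(mint_iri(scheme, "dataset", [MAIN]))
    main_graph = _bind(Graph())
    main_graph.add((main_ds, RDF.type, QB.DataSet))
    # the whole export is additionally a DDI logical dataset
    main_graph.add((main_ds, RDF.type, DISCO.LogicalDataset))
    _emit_dsd(main_graph, main_ds)

    cs = CubeSet(scheme=scheme, main_graph=main_graph,
                 specialised_graphs={}, link_graph=_bind(Graph()),
                 main_dataset=main_ds, spec_datasets={})
    cs.timepoints = [ed.name for ed in meta.event_defs.values()]

    # variable + universe + subject schema triples live in the main graph
    for u in universes.values():
        u_iri = URIRef(mint_iri(scheme, "universe", [u.theme, u.sub_theme]))
        main_graph.add((u_iri, RDF.type, DISCO.Universe))
        main_graph.add((u_iri, RDFS.label,
                        Literal(f"{u.theme} / {u.sub_theme}")))
    for var in variables.values():
        v_iri = URIRef(mint_iri(scheme, "variable", [var.name]))
        main_graph.add((v_iri, RDF.type, DISCO.Variable))
        main_graph.add((v_iri, RDFS.label, Literal(var.label)))
        u_iri = URIRef(mint_iri(scheme, "universe", list(var.universe)))
        main_graph.add((v_iri, DISCO.basedOn, u_iri))

    def spec_graph(theme: str) -> tuple[Graph, URIRef]:
        if theme not in cs.specialised_graphs:
            g = _bind(Graph())
            ds = URIRef(mint_iri(scheme, "dataset", [theme]))
            g.add((ds, RDF.type, QB.DataSet))
            _emit_dsd(g, ds)
            cs.specialised_graphs[theme] = g
            cs.spec_datasets[theme] = ds
        return cs.specialised_graphs[theme], cs.spec_datasets[theme]

    seen_subjects: set[str] = set()
    for record in iter_records(doc):
        if record.typed_value is None:
            log.debug("no observation for %s/%s (missing value)",
                      record.subject_key, record.item_oid)
            continue
        if record.form_oid not in theme_map:
            raise CubeConfigError(
                f"form {record.form_oid!r} has no theme assignment")
        theme, sub_theme = theme_map[record.form_oid]
        var = variable_for_item(variables, meta, record.item_oid)
        if var.universe not in universes:
            raise CubeConfigError(
                f"variable {var.name!r} belongs to unknown universe "
                f"{var.universe!r}")

        timepoint = meta.event_defs[record.event_oid].name
        repeat = (record.itemgroup_repeat if record.event_repeat == "1"
                  else f"{record.event_repeat}-{record.itemgroup_repeat}")
        # a deduplicated variable captured on several forms would collide on
        # the (subject, timepoint, variable, repeat) coordinate when two of
        # its source items are recorded at the same visit; qualify the
        # repeat with the sub-theme to keep the dimension tuple unique
        if len(var.source_item_oids) > 1:
            repeat = f"{sub_theme}-{repeat}"
        coord = [record.subject_key, timepoint, var.name, repeat]

        g, ds = spec_graph(theme)
        spec_iri = URIRef(mint_iri(scheme, "observation", coord))
        main_iri = URIRef(mint_iri(scheme, "main_observation", coord))
        group_iri = URIRef(mint_iri(scheme, "observation_group", coord))
        subj_iri = URIRef(mint_iri(scheme, "subject", [record.subject_key]))
        var_iri = URIRef(mint_iri(scheme, "variable", [var.name]))
        value = _value_literal(record, var.datatype)

        if record.subject_key not in seen_subjects:
            seen_subjects.add(record.subject_key)
            main_graph.add((subj_iri, RDF.type, LCDC.StudySubject))

        for obs_iri, graph, dataset in ((spec_iri, g, ds),
                                        (main_iri, main_graph, main_ds)):
            graph.add((obs_iri, RDF.type, QB.Observation))
            graph.add((obs_iri, QB.dataSet, dataset))
            graph.add((obs_iri, LCDC.subject, subj_iri))
            graph.add((obs_iri, LCDC.timepoint, Literal(timepoint)))
            graph.add((obs_iri, LCDC.variable, var_iri))
            graph.add((obs_iri, LCDC.repeat, Literal(repeat)))
            graph.add((obs_iri, LCDC.value, value))

        main_graph.add((group_iri, RDF.type, QB.ObservationGroup))
        main_graph.add((group_iri, LCDC.mainObservation, main_iri))
        main_graph.add((group_iri, LCDC.specialisedObservation, spec_iri))

        cs.entries.append(ObsEntry(
            record=record, theme=theme, sub_theme=sub_theme,
            subject=record.subject_key, timepoint=timepoint,
            variable=var.name, repeat=repeat, spec_iri=spec_iri,
            main_iri=main_iri, group_iri=group_iri))

    return cs


def _new_slice(cs: CubeSet, cube: str, slice_kind: str, key: str,
               fixed: dict[URIRef, object]) -> URIRef:
    g = cs.graph_for(cube)
    ds = cs.main_dataset if cube == MAIN else cs.spec_datasets[cube]
    iri = URIRef(mint_iri(cs.scheme, "slice", [cube, slice_kind, key]))
    g.add((iri, RDF.type, QB.Slice))
    g.add((ds, QB.slice, iri))
    for prop, value in fixed.items():
        g.add((iri, prop, value if isinstance(value, (URIRef, Literal))
               else Literal(value)))
    return iri


def build_time_series_slices(cs: CubeSet,
                             events: list[str] | None = None) -> list[URIRef]:
    """One slice per (cube, timepoint) fixing the timepoint dimension, plus a
    phase-series slice per timepoint in the main cube referencing the
    observation groups of that timepoint."""
    events = events or cs.timepoints
    made: list[URIRef] = []
    by_tp: dict[str, list[ObsEntry]] = {}
    for e in cs.entries:
        by_tp.setdefault(e.timepoint, []).append(e)

    for tp in events:
        entries = by_tp.get(tp)
        if not entries:
            continue
        # main-cube time-series slice over main observations
        s = _new_slice(cs, MAIN, "time-series", tp, {LCDC.timepoint: tp})
        cs.time_slices[(MAIN, tp)] = s
        made.append(s)
        for e in entries:
            cs.main_graph.add((s, QB.observation, e.main_iri))
        # phase series over observation groups
        ps = _new_slice(cs, MAIN, "phase-series", tp, {LCDC.timepoint: tp})
        cs.phase_series[tp] = ps
        made.append(ps)
        for e in entries:
            cs.main_graph.add((ps, QB.observationGroup, e.group_iri))
        # specialised-cube time-series slices over specialised observations
        themes = sorted({e.theme for e in entries})
        for theme in themes:
            st = _new_slice(cs, theme, "time-series", tp,
                            {LCDC.timepoint: tp})
            cs.time_slices[(theme, tp)] = st
            made.append(st)
            g = cs.specialised_graphs[theme]
            for e in entries:
                if e.theme == theme:
                    g.add((st, QB.observation, e.spec_iri))
    return made


def build_cross_section_slices(cs: CubeSet,
                               subject_props: list[str]) -> list[URIRef]:
    """One slice per (subject property, value) in the main cube, plus one
    subject section per subject in the main cube and per (theme, subject) in
    the specialised cubes.

    A subject property that varies across events draws a warning; the
    latest-event value wins.
    """
    made: list[URIRef] = []
    order = {tp: i for i, tp in enumerate(cs.timepoints)}

    by_subject: dict[str, list[ObsEntry]] = {}
    for e in cs.entries:
        by_subject.setdefault(e.subject, []).append(e)

    for subj in sorted(by_subject):
        s = _new_slice(cs, MAIN, "subject-section", subj, {
            LCDC.subject: URIRef(mint_iri(cs.scheme, "subject", [subj]))})
        cs.subject_sections[subj] = s
        made.append(s)
        for e in by_subject[subj]:
            cs.main_graph.add((s, QB.observationGroup, e.group_iri))
        for theme in sorted({e.theme for e in by_subject[subj]}):
            st = _new_slice(cs, theme, "subject-section", subj, {
                LCDC.subject: URIRef(mint_iri(cs.scheme, "subject", [subj]))})
            cs.spec_subject_sections[(theme, subj)] = st
            made.append(st)
            g = cs.specialised_graphs[theme]
            for e in by_subject[subj]:
                if e.theme == theme:
                    g.add((st, QB.observation, e.spec_iri))

    for prop in subject_props:
        # latest-event value per subject
        values: dict[str, ObsEntry] = {}
        for e in cs.entries:
            if e.variable != prop:
                continue
            prev = values.get(e.subject)
            if prev is None:
                values[e.subject] = e
            else:
                if prev.record.typed_value != e.record.typed_value:
                    log.warning(
                        "subject property %s varies across events for %s; "
                        "using latest-event value", prop, e.subject)
                if order.get(e.timepoint, 0) >= order.get(prev.timepoint, 0):
                    values[e.subject] = e
        by_value: dict[str, list[str]] = {}
        for subj, e in values.items():
            by_value.setdefault(str(e.record.typed_value), []).append(subj)
        var_iri = URIRef(mint_iri(cs.scheme, "variable", [prop]))
        for val in sorted(by_value):
            s = _new_slice(cs, MAIN, "cross-section", f"{prop}={val}", {
                LCDC.subjectProperty: var_iri,
                LCDC.subjectPropertyValue: Literal(val)})
            cs.cross_slices[(prop, val)] = s
            made.append(s)
            for subj in by_value[val]:
                for e in by_subject[subj]:
                    cs.main_graph.add((s, QB.observationGroup, e.group_iri))
    return made


def build_theme_slices(cs: CubeSet,
                       universes: dict[tuple[str, str], Universe]
                       ) -> list[URIRef]:
    """One sub-theme slice per universe with data, in the main cube,
    referencing the observation groups of that universe's variables.
    Universes without records yield no slice."""
    made: list[URIRef] = []
    by_universe: dict[tuple[str, str], list[ObsEntry]] = {}
    for e in cs.entries:
        by_universe.setdefault((e.theme, e.sub_theme), []).append(e)

    for ukey in sorted(by_universe):
        if ukey not in universes:
            continue
        theme, sub = ukey
        u_iri = URIRef(mint_iri(cs.scheme, "universe", [theme, sub]))
        s = _new_slice(cs, MAIN, "sub-theme", f"{theme}.{sub}",
                       {LCDC.universe: u_iri})
        cs.theme_slices[ukey] = s
        made.append(s)
        for e in by_universe[ukey]:
            cs.main_graph.add((s, QB.observationGroup, e.group_iri))
    return made


def link_cubes(cs: CubeSet) -> Graph:
    """Emit the inter-cube link triples into the link graph:

    * ``void:subset`` from the main dataset to every specialised dataset,
    * ``lcdc:specialisedSeries`` from each main-cube phase series to the
      specialised time-series slice of the same timepoint,
    * ``lcdc:specialisedSection`` from each main subject section to the
      specialised subject sections of the same subject,
    * the schema axioms ``lcdc:specialisedObservation ⊑ qb:observation`` and
      ``lcdc:mainObservation ⊑ qb:observation`` (each exactly once).
    """
    lg = cs.link_graph
    for theme, ds in sorted(cs.spec_datasets.items()):
        lg.add((cs.main_dataset, VOID.subset, ds))

    for tp, ps in cs.phase_series.items():
        matched = False
        for (cube, stp), s in cs.time_slices.items():
            if cube != MAIN and stp == tp:
                lg.add((ps, LCDC.specialisedSeries, s))
                matched = True
        if not matched:
            log.warning("phase series %s has no specialised counterpart", tp)

    for subj, sec in cs.subject_sections.items():
        for (theme, ssubj), s in cs.spec_subject_sections.items():
            if ssubj == subj:
                lg.add((sec, LCDC.specialisedSection, s))

    lg.add((LCDC.specialisedObservation, RDFS.subPropertyOf, QB.observation))
    lg.add((LCDC.mainObservation, RDFS.subPropertyOf, QB.observation))
    return lg


def build_all(doc: ODMDocument, variables, universes, scheme: UriScheme,
              theme_map: dict[str, tuple[str, str]],
              subject_props: list[str] | None = None) -> CubeSet:
    """Full pipeline: cubes, all three slice families, inter-cube links."""
    cs = build_cubeset(doc, variables, universes, scheme, theme_map)
    build_time_series_slices(cs)
    build_cross_section_slices(cs, subject_props or [])
    build_theme_slices(cs, universes)
    link_cubes(cs)
    return cs


def canonical_nt(graph: Graph) -> str:
    """Sorted N-Triples serialisation — byte-stable for diffing and
    determinism checks (the emitted graphs contain no blank nodes)."""
    lines = sorted(
        graph.serialize(format="nt").splitlines())
    return "\n".join(line for line in lines if line.strip()) + "\n"


def write_cubeset(cs: CubeSet, outdir: str | Path,
                  fmt: str = "turtle") -> list[Path]:
    """Write one file per cube plus the links file.  ``fmt`` is ``turtle``
    or ``nt`` (canonically sorted, for diffing)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"turtle": "ttl", "nt": "nt"}[fmt]
    written = []
    named = [("main", cs.main_graph), ("links", cs.link_graph)]
    named += [(f"theme_{t}", g) for t, g in sorted(cs.specialised_graphs.items())]
    for name, g in named:
        path = outdir / f"{name}.{ext}"
        if fmt == "nt":
            path.write_text(canonical_nt(g))
        else:
            path.write_text(g.serialize(format="turtle"))
        written.append(path)
    return written
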