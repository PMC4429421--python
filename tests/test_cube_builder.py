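"""Cube construction: observations, groups, slices, inter-cube links."""

import pytest
from rdflib import RDF, RDFS

from lcdc.cube_builder import (
    MAIN, build_all, build_cubeset, build_cross_section_slices,
    build_theme_slices, build_time_series_slices, canonical_nt, link_cubes,
)
from lcdc.lcdc_model import LCDC, QB, UriScheme, VOID, register_variables
from lcdc.odm_io import (
    FormData, ItemData, ItemGroupData, StudyEventData, SubjectData,
    parse_odm, serialize_odm,
)
from lcdc import StudyConfig, generate_study
from lcdc.synth_fixtures import DEFAULT_THEME_MAP


def _tiny_doc():
    """2 subjects x 2 events x 3 variables across 2 themes, no missing."""
    from lcdc.odm_io import (EventDef, FormDef, ItemDef, ItemGroupDef,
                             ODMDocument, StudyMeta)
    meta = StudyMeta(study_oid="S")
    for oid, name, dt in [("I.sys", "systolicBP", "integer"),
                          ("I.dia", "diastolicBP", "integer"),
                          ("I.walk", "walkHours", "float")]:
        meta.item_defs[oid] = ItemDef(oid, name, dt)
    meta.itemgroup_defs["G.vs"] = ItemGroupDef("G.vs", "vs",
                                               ["I.sys", "I.dia"])
    meta.itemgroup_defs["G.ls"] = ItemGroupDef("G.ls", "ls", ["I.walk"])
    meta.form_defs["F.vs"] = FormDef("F.vs", "vs", ["G.vs"])
    meta.form_defs["F.ls"] = FormDef("F.ls", "ls", ["G.ls"])
    meta.event_defs = {
        "E.base": EventDef("E.base", "baseline", ["F.vs", "F.ls"]),
        "E.m18": EventDef("E.m18", "month18", ["F.vs", "F.ls"]),
    }
    doc = ODMDocument(studies=[meta])
    for subj in ("P1", "P2"):
        s = SubjectData(subject_key=subj)
        for ev in ("E.base", "E.m18"):
            e = StudyEventData(event_oid=ev)
            e.forms.append(FormData("F.vs", [ItemGroupData("G.vs", "1", [
                ItemData("I.sys", "120"), ItemData("I.dia", "80")])]))
            e.forms.append(FormData("F.ls", [ItemGroupData("G.ls", "1", [
                ItemData("I.walk", "2.5")])]))
            s.events.append(e)
        doc.subjects.append(s)
    return doc


TINY_THEMES = {"F.vs": ("Clinical", "vitalsigns"),
               "F.ls": ("Lifestyle", "exercise")}


@pytest.fixture()
def tiny_cubeset():
    doc = _tiny_doc()
    variables, universes = register_variables(doc.meta, TINY_THEMES)
    return doc, variables, universes, build_cubeset(
        doc, variables, universes, UriScheme(), TINY_THEMES)


def test_one_specialised_cube_per_theme_present(tiny_cubeset):
    *_, cs = tiny_cubeset
    assert set(cs.specialised_graphs) == {"Clinical", "Lifestyle"}
    assert (cs.main_dataset, RDF.type, QB.DataSet) in cs.main_graph
    # the whole export is additionally a DDI logical dataset
    from lcdc.lcdc_model import DISCO
    assert (cs.main_dataset, RDF.type, DISCO.LogicalDataset) in cs.main_graph


def test_observation_and_group_counts(tiny_cubeset):
    *_, cs = tiny_cubeset
    # 2 subjects x 2 events x 3 variables = 12, no missing
    n_spec = sum(len(set(g.subjects(RDF.type, QB.Observation)))
                 for g in cs.specialised_graphs.values())
    n_groups = len(set(cs.main_graph.subjects(RDF.type,
                                              QB.ObservationGroup)))
    assert n_spec == 12
    assert n_groups == 12


def test_missing_value_produces_no_observation():
    doc = _tiny_doc()
    doc.subjects[0].events[0].forms[0].itemgroups[0].items[0] = ItemData(
        "I.sys", "")
    variables, universes = register_variables(doc.meta, TINY_THEMES)
    cs = build_cubeset(doc, variables, universes, UriScheme(), TINY_THEMES)
    n_spec = sum(len(set(g.subjects(RDF.type, QB.Observation)))
                 for g in cs.specialised_graphs.values())
    assert n_spec == 11


def test_pairing_triples_complete(tiny_cubeset):
    *_, cs = tiny_cubeset
    mains = list(cs.main_graph.subject_objects(LCDC.mainObservation))
    specs = list(cs.main_graph.subject_objects(LCDC.specialisedObservation))
    assert len(mains) == 12 and len(specs) == 12


def test_time_series_slices_partition_observations(cubeset):
    slices_obs = {}
    for (cube, tp), s in cubeset.time_slices.items():
        g = cubeset.graph_for(cube)
        for o in g.objects(s, QB.observation):
            key = (cube, o)
            assert key not in slices_obs, "observation in two time slices"
            slices_obs[key] = tp
    spec_total = sum(len(set(g.subjects(RDF.type, QB.Observation)))
                     for g in cubeset.specialised_graphs.values())
    main_total = len(set(cubeset.main_graph.subjects(RDF.type,
                                                     QB.Observation)))
    assert len(slices_obs) == spec_total + main_total


def test_single_timepoint_gives_one_slice_with_everything():
    xml, _ = generate_study(StudyConfig(n_subjects=4,
                                        timepoints=("baseline",),
                                        transition_fraction=0, seed=2))
    doc = parse_odm(xml)
    variables, universes = register_variables(doc.meta, DEFAULT_THEME_MAP)
    cs = build_cubeset(doc, variables, universes, UriScheme(),
                       DEFAULT_THEME_MAP)
    build_time_series_slices(cs)
    assert len(cs.phase_series) == 1
    members = set(cs.main_graph.objects(cs.phase_series["baseline"],
                                        QB.observationGroup))
    assert members == set(cs.main_graph.subjects(RDF.type,
                                                 QB.ObservationGroup))


def test_phase_series_one_per_timepoint(cubeset, small_config):
    assert set(cubeset.phase_series) == set(small_config.timepoints)


def test_subject_sections_count_equals_subject_count(cubeset, manifest):
    assert len(cubeset.subject_sections) == manifest["counts"]["n_subjects"]


def test_gender_cross_section_slices(cubeset, manifest):
    genders = {t["gender"] for t in manifest["subjects"].values()}
    assert {v for (p, v) in cubeset.cross_slices if p == "gender"} == genders


def test_theme_slices_partition_groups(cubeset):
    seen = {}
    for key, s in cubeset.theme_slices.items():
        for g in cubeset.main_graph.objects(s, QB.observationGroup):
            assert g not in seen, "group reachable from two sub-theme slices"
            seen[g] = key
    all_groups = set(cubeset.main_graph.subjects(RDF.type,
                                                 QB.ObservationGroup))
    assert set(seen) == all_groups


def test_specialised_series_links(tiny_cubeset):
    doc, variables, universes, cs = tiny_cubeset
    build_time_series_slices(cs)
    build_cross_section_slices(cs, [])
    build_theme_slices(cs, universes)
    lg = link_cubes(cs)
    # 2 themes x 2 timepoints
    assert len(list(lg.subject_objects(LCDC.specialisedSeries))) == 4
    assert len(list(lg.triples(
        (LCDC.specialisedObservation, RDFS.subPropertyOf,
         QB.observation)))) == 1
    for ds in cs.spec_datasets.values():
        assert (cs.main_dataset, VOID.subset, ds) in lg


def test_canonical_serialisation_is_deterministic(small_config):
    def run():
        xml, _ = generate_study(small_config)
        doc = parse_odm(xml)
        variables, universes = register_variables(doc.meta,
                                                  DEFAULT_THEME_MAP)
        cs = build_all(doc, variables, universes, UriScheme(),
                       DEFAULT_THEME_MAP, ["gender"])
        return canonical_nt(cs.main_graph), canonical_nt(cs.link_graph)

    assert run() == run()
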