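"""Medication cleaning, four-phase matching, ATC hops, report arithmetic."""

import pytest

from lcdc.med_mapper import (
    MatchResult, MedicationRecord, UnmappableNameError, atc_ancestors,
    build_linked_med_graph, clean_name, load_terminologies, map_medications,
    map_to_atc, mapping_report, match_medicinal_product, match_substance,
    match_trade_product, report_from_counts, validate_terminologies,
    write_terminologies,
)
from lcdc.synth_fixtures import generate_terminologies


@pytest.mark.parametrize("raw, expected", [
    ("METFORMIN  500mg", "metformin"),
    ("Metformin 1 tablet", "metformin"),
    ("Aspirin (morning)", "aspirin"),
    ("  Lipitor   10mg (at night) ", "lipitor"),
    ("amoxicillin + clavulanic acid 2 tablets", "amoxicillin + clavulanic acid"),
])
def test_clean_name_rule_chain(raw, expected):
    assert clean_name(raw) == expected


def test_override_takes_precedence_over_rules():
    overrides = {"panadol osteo": "paracetamol"}
    assert clean_name("Panadol  Osteo", overrides) == "paracetamol"
    assert clean_name("Panadol Osteo") == "panadol osteo"


def test_cleaning_to_empty_flags_unmappable():
    with pytest.raises(UnmappableNameError):
        clean_name("500mg")
    with pytest.raises(UnmappableNameError):
        clean_name("")


def test_trade_product_precedence_and_alias(terms):
    exact = match_trade_product("diabex", terms)
    assert exact and exact.method == "exact"
    alias = match_trade_product("glucophage", terms)
    assert alias and alias.method == "synonym"
    assert alias.code == exact.code  # both brands of the same product
    assert match_trade_product("no such brand", terms) is None


def test_medicinal_product_via_drugbank_synonym(terms):
    direct = match_medicinal_product("metformin", terms)
    assert direct and direct.method == "exact"
    syn = match_medicinal_product("dimethylbiguanide", terms)
    assert syn and syn.method == "synonym" and syn.code == direct.code
    # a trade name does not match at MP level: phases are independent
    assert match_medicinal_product("diabex", terms) is None


def test_substance_split_and_unii_preference(terms):
    m = match_substance("amoxicillin + clavulanic acid", terms)
    assert m is not None and m.scheme == "unii"
    assert m.ingredients == ("amoxicillin", "clavulanic acid")
    schemes = {m.scheme} | {s for s, _ in m.also}
    assert "unii" in schemes
    # UNII hit reports the cross-mapped AMT MS code alongside
    assert any(s == "amt_ms" for s, _ in m.also)


def test_substance_falls_back_to_amt_ms(terms):
    # calcium carbonate is not in the fixture; craft one that is MS-only
    terms2 = generate_terminologies()
    terms2.amt_ms["MS9999"] = "experimentine"
    m = match_substance("experimentine", terms2)
    assert m is not None and m.scheme == "amt_ms"


def test_atc_hop_through_drugbank(terms):
    res = MatchResult(record_id="r1",
                      mp_match=match_medicinal_product("metformin", terms))
    map_to_atc(res, terms)
    assert res.atc_codes == {"A10BA02"}
    assert MatchResult(record_id="r2").atc_codes == set()


def test_atc_ancestors_follow_level_grammar():
    assert atc_ancestors("A10BA02") == ["A", "A10", "A10B", "A10BA"]


def test_phase_independence(terms):
    records = [MedicationRecord("r1", "P1", "baseline", "Metformin"),
               MedicationRecord("r2", "P1", "baseline", "Diabex")]
    _, full = map_medications(records, terms)
    _, no_tp = map_medications(records, terms, phases=("mp", "substance",
                                                       "atc"))
    for a, b in zip(full, no_tp):
        assert (a.mp_match, a.substance_match) == (b.mp_match,
                                                   b.substance_match)
        assert b.tp_match is None


def test_tie_break_is_lexicographically_smallest_code(terms):
    terms2 = generate_terminologies()
    # two TP codes with the same label: the smaller code must win
    terms2.amt_tp["TP0001"] = "Diabex"
    m = match_trade_product("diabex", terms2)
    assert m.code == "TP0001"


@pytest.mark.parametrize("total, count, expected", [
    (7942, 5536, "69.71%"),
    (7942, 5518, "69.48%"),
    (7942, 5266, "66.31%"),
    (7942, 5382, "67.77%"),
    (10, 0, "0.00%"),
    (800, 1, "0.13%"),   # 0.125 rounds half-up
])
def test_percentage_rounding_half_up(total, count, expected):
    df = report_from_counts(total, count, count, count, count)
    assert df.loc[1, "Percentage"] == expected


def test_mapping_report_shape_and_union_bound(manifest, terms):
    records = [MedicationRecord(m["record_id"], m["subject"], m["event"],
                                m["raw_name"])
               for m in manifest["medications"]]
    _, results = map_medications(records, terms)
    df = mapping_report(results)
    assert list(df["Mapped"]) == [
        "Total", "Medicinal product/trade product/substance",
        "Trade product", "Medicinal product", "Substance"]
    total, any_, tp, mp, sub = df["Count"]
    assert any_ >= max(tp, mp, sub)
    assert any_ <= tp + mp + sub
    with pytest.raises(ValueError):
        mapping_report([])


def test_report_is_deterministic(manifest, terms):
    records = [MedicationRecord(m["record_id"], m["subject"], m["event"],
                                m["raw_name"])
               for m in manifest["medications"]]
    _, r1 = map_medications(records, terms)
    _, r2 = map_medications(records, terms)
    assert mapping_report(r1).to_csv() == mapping_report(r2).to_csv()


def test_linked_graph_exact_match_counts(manifest, terms):
    records = [MedicationRecord(m["record_id"], m["subject"], m["event"],
                                m["raw_name"])
               for m in manifest["medications"]]
    cleaned, results = map_medications(records, terms)
    g = build_linked_med_graph(results, cleaned, terms)
    from lcdc.lcdc_model import SKOS, XKOS
    from rdflib import RDF
    n_links = len(list(g.subject_objects(SKOS.exactMatch)))
    # >= one link per phase match (also-codes and DrugBank hops add more)
    n_matches = sum((r.tp_match is not None) + (r.mp_match is not None)
                    + (r.substance_match is not None) + len(r.atc_codes)
                    for r in results)
    assert n_links >= n_matches
    # many-to-many MP<->ARTG pairs are reified as association nodes
    assocs = set(g.subjects(RDF.type, XKOS.ConceptAssociation))
    matched_mp = {r.mp_match.code for r in results if r.mp_match}
    expected_assocs = sum(
        len(terms.crossmap_targets("amt_mp_artg", c)) for c in matched_mp)
    assert len(assocs) == expected_assocs


def test_terminology_round_trip_through_csv(tmp_path, terms):
    write_terminologies(terms, tmp_path)
    loaded = load_terminologies(tmp_path)
    assert loaded.amt_tp == terms.amt_tp
    assert loaded.cross_maps == terms.cross_maps
    assert loaded.drugbank["DB00331"].synonyms == ["dimethylbiguanide"]
    validate_terminologies(loaded)
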