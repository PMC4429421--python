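"""IRI minting and the deduplicated variable dictionary."""

import pytest
from hypothesis import given, settings, strategies as st

from lcdc.lcdc_model import (
    ThemeMapError, UriScheme, UriSchemeError, VariableConflictError,
    mint_iri, register_variables,
)
from lcdc.odm_io import FormDef, ItemDef, ItemGroupDef, StudyMeta


SCHEME = UriScheme(base="http://example.org/lcdc")


def test_observation_iri_template():
    iri = mint_iri(SCHEME, "observation", ["S001", "ev1", "bp_sys", "1"])
    assert iri == "http://example.org/lcdc/observation/S001.ev1.bp_sys.1"


def test_minting_is_deterministic():
    a = mint_iri(SCHEME, "dataset", ["clinical"])
    b = mint_iri(SCHEME, "dataset", ["clinical"])
    assert a == b == "http://example.org/lcdc/dataset/clinical"


def test_keys_are_percent_encoded():
    iri = mint_iri(SCHEME, "subject", ["P 1/α"])
    assert " " not in iri and "/α" not in iri
    assert iri.endswith("P%201%2F%CE%B1")


def test_arity_mismatch_is_a_usage_error():
    with pytest.raises(UriSchemeError, match="key"):
        mint_iri(SCHEME, "observation", ["S001", "ev1"])
    with pytest.raises(UriSchemeError, match="kind"):
        mint_iri(SCHEME, "nonesuch", ["x"])


@settings(max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.text(min_size=1, max_size=8),
                          st.text(min_size=1, max_size=8)),
                min_size=1, max_size=50, unique=True))
def test_minting_injective_on_key_tuples(keys):
    iris = {mint_iri(SCHEME, "universe", list(k)) for k in keys}
    assert len(iris) == len(keys)


def test_thousand_distinct_tuples_give_thousand_iris():
    iris = {mint_iri(SCHEME, "observation", [f"S{i}", "ev", "v", "1"])
            for i in range(1000)}
    assert len(iris) == 1000


# ---------------------------------------------------------------------------

def _meta(items_per_form: dict[str, list[tuple[str, str, str]]]) -> StudyMeta:
    """items_per_form: form oid -> [(item_oid, name, datatype)]"""
    meta = StudyMeta(study_oid="S")
    for form_oid, items in items_per_form.items():
        ig_oid = f"G.{form_oid}"
        meta.form_defs[form_oid] = FormDef(form_oid, form_oid,
                                           itemgroup_oids=[ig_oid])
        meta.itemgroup_defs[ig_oid] = ItemGroupDef(
            ig_oid, ig_oid, item_oids=[i[0] for i in items])
        for oid, name, dt in items:
            meta.item_defs[oid] = ItemDef(oid, name, dt)
    return meta


def test_duplicate_names_collapse_to_one_variable():
    meta = _meta({
        "F1": [("I1", "systolicBP", "integer")],
        "F2": [("I2", "systolicBP", "integer")],
    })
    variables, universes = register_variables(
        meta, {"F1": ("Clinical", "vs"), "F2": ("Clinical", "vs2")})
    assert len(variables) == 1
    assert variables["systolicbp"].source_item_oids == {"I1", "I2"}


def test_distinct_items_map_one_to_one():
    meta = _meta({"F1": [(f"I{i}", f"var{i}", "integer")
                         for i in range(10)]})
    variables, _ = register_variables(meta, {"F1": ("Clinical", "vs")})
    assert len(variables) == 10


def test_conflicting_datatypes_name_both_item_oids():
    meta = _meta({
        "F1": [("I1", "age", "integer")],
        "F2": [("I2", "age", "text")],
    })
    with pytest.raises(VariableConflictError) as err:
        register_variables(meta, {"F1": ("A", "a"), "F2": ("B", "b")})
    assert "I1" in str(err.value) and "I2" in str(err.value)


def test_missing_theme_assignment_is_an_error():
    meta = _meta({"F1": [("I1", "x", "text")]})
    with pytest.raises(ThemeMapError, match="F1"):
        register_variables(meta, {})


def test_universes_partition_the_variable_set(dictionary):
    variables, universes = dictionary
    memberships = [name for u in universes.values()
                   for name in u.member_variables]
    assert sorted(memberships) == sorted(variables)  # no orphan, no double
    for var in variables.values():
        assert var.universe in universes


def test_planted_duplicate_collapses_in_generated_study(doc, dictionary):
    variables, _ = dictionary
    distinct_names = {d.name.strip().lower()
                      for d in doc.meta.item_defs.values()}
    assert len(variables) == len(distinct_names)
    assert len(variables) < len(doc.meta.item_defs)  # duplicates planted
    assert len(variables["notes"].source_item_oids) == 2
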