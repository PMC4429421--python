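"""ODM XML parsing, record streaming, serialisation round-trips."""

import pytest

from lcdc.odm_io import (
    OdmParseError, OdmReferenceError, docs_equal, iter_records, parse_odm,
    serialize_odm,
)
from lcdc import StudyConfig, generate_study

MINIMAL_META = """<?xml version="1.0"?>
<ODM xmlns="http://www.cdisc.org/ns/odm/v1.3" FileType="Snapshot"
     FileOID="t" ODMVersion="1.3">
 <Study OID="S1">
  <GlobalVariables><StudyName>S1</StudyName>
   <StudyDescription>d</StudyDescription><ProtocolName>p</ProtocolName>
  </GlobalVariables>
  <MetaDataVersion OID="M1" Name="M1">
   <StudyEventDef OID="E1" Name="visit" Repeating="No" Type="Scheduled">
    <FormRef FormOID="F1" Mandatory="No"/>
   </StudyEventDef>
   <FormDef OID="F1" Name="form" Repeating="No">
    <ItemGroupRef ItemGroupOID="G1" Mandatory="No"/>
   </FormDef>
   <ItemGroupDef OID="G1" Name="grp" Repeating="No">
    <ItemRef ItemOID="I1" Mandatory="No"/>
    <ItemRef ItemOID="I2" Mandatory="No"/>
   </ItemGroupDef>
   <ItemDef OID="I1" Name="count" DataType="integer"/>
   <ItemDef OID="I2" Name="ratio" DataType="float"/>
  </MetaDataVersion>
 </Study>
 %s
</ODM>
"""

CLINICAL = """<ClinicalData StudyOID="S1" MetaDataVersionOID="M1">
 <SubjectData SubjectKey="P1">
  <StudyEventData StudyEventOID="E1">
   <FormData FormOID="F1">
    <ItemGroupData ItemGroupOID="G1">
     <ItemData ItemOID="I1" Value="142"/>
     <ItemData ItemOID="I2" Value="abc"/>
    </ItemGroupData>
   </FormData>
  </StudyEventData>
 </SubjectData>
</ClinicalData>"""


def test_metadata_only_document_has_no_subjects():
    doc = parse_odm(MINIMAL_META % "")
    assert doc.subjects == []
    assert set(doc.meta.item_defs) == {"I1", "I2"}


def test_malformed_xml_raises_parse_error():
    with pytest.raises(OdmParseError, match="malformed"):
        parse_odm("<ODM><Study>")


def test_dangling_itemgroup_ref_names_the_oid():
    broken = MINIMAL_META % ""
    broken = broken.replace('ItemGroupOID="G1"', 'ItemGroupOID="G9"', 1)
    with pytest.raises(OdmReferenceError, match="G9"):
        parse_odm(broken)


def test_typed_coercion_and_failure_warning():
    doc = parse_odm(MINIMAL_META % CLINICAL)
    records = list(iter_records(doc))
    assert len(records) == 2
    by_item = {r.item_oid: r for r in records}
    assert by_item["I1"].typed_value == 142
    # "abc" under a float ItemDef: value kept raw, typed missing, logged
    assert by_item["I2"].typed_value is None
    assert by_item["I2"].raw_value == "abc"
    assert any(w.code == "W-COERCE" and w.oid == "I2"
               for w in doc.warnings)


def test_repeat_keys_default_to_one():
    doc = parse_odm(MINIMAL_META % CLINICAL)
    rec = next(iter_records(doc))
    assert rec.event_repeat == "1"
    assert rec.itemgroup_repeat == "1"


def test_codelist_violation_yields_missing_value(doc):
    # the generated study carries codelist items; corrupt one value
    from lcdc.odm_io import ItemData
    bad = parse_odm(serialize_odm(doc))
    bad.subjects[0].events[0].forms[0].itemgroups[0].items.append(
        ItemData("I.classification", "NOT-A-CODE"))
    records = [r for r in iter_records(bad)
               if r.item_oid == "I.classification"]
    assert any(r.typed_value is None and r.raw_value == "NOT-A-CODE"
               for r in records)
    assert any(w.code == "W-COERCE" for w in bad.warnings)


def test_generated_subject_count_matches_manifest(doc, manifest):
    assert len(doc.subjects) == manifest["counts"]["n_subjects"]


def test_record_stream_length_equals_item_data_count(doc, manifest, study):
    records = list(iter_records(doc))
    assert len(records) == manifest["counts"]["n_item_data"]
    # independent count straight off the XML text
    assert study[0].count("<ItemData ") == len(records)


@pytest.mark.parametrize("seed", [0, 3])
def test_parse_serialize_round_trip(seed):
    xml, _ = generate_study(StudyConfig(n_subjects=6, seed=seed,
                                        timepoints=("baseline", "month18")))
    d1 = parse_odm(xml)
    d2 = parse_odm(serialize_odm(d1))
    assert docs_equal(d1, d2)


def test_codelist_oids_preserved_verbatim(doc):
    out = serialize_odm(doc)
    assert 'OID="CL.class"' in out and 'OID="CL.gender"' in out
    reparsed = parse_odm(out)
    assert reparsed.meta.codelists == doc.meta.codelists


def test_openclinica_namespace_detected_and_tolerated():
    xml = (MINIMAL_META % CLINICAL).replace(
        'xmlns="http://www.cdisc.org/ns/odm/v1.3"',
        'xmlns="http://www.cdisc.org/ns/odm/v1.3" '
        'xmlns:oc="http://www.openclinica.org/ns/odm_ext_v130/v3.1"')
    doc = parse_odm(xml)
    assert doc.source_dialect == "openclinica"
    assert len(list(iter_records(doc))) == 2
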