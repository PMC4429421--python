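"""Reading and writing the supported subset of CDISC ODM 1.3 XML.

The ODM format carries both a study's data dictionary (StudyEventDef /
FormDef / ItemGroupDef / ItemDef / CodeList in the MetaDataVersion) and its
clinical data (SubjectData / StudyEventData / FormData / ItemGroupData /
ItemData).  This module parses that subset into typed records, flattens the
clinical-data tree into :class:`ItemDataRecord` streams, and serialises
documents back to XML such that ``parse_odm(serialize_odm(d)) == d`` on all
modelled fields.

Both plain ODM and the OpenClinica dialect are accepted: elements are matched
on local name, so vendor namespaces and extension attributes are tolerated
(and noted in the warning log) rather than fatal.  Observational study data
is patchy by nature, so type-coercion failures downgrade values to missing
instead of aborting the parse.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterator, Optional

from lxml import etree

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"

#: ODM datatypes supported by the pipeline, normalised to lowercase tokens.
DATATYPES = frozenset({"text", "integer", "float", "date", "codelist"})


class OdmError(Exception):
    """Base class for ODM parsing problems."""


class OdmParseError(OdmError):
    """Malformed XML or structurally unusable document."""


class OdmReferenceError(OdmError):
    """An OID referenced by a *Ref / *Data element has no matching *Def."""

    def __init__(self, oid: str, referencing: str):
        self.oid = oid
        self.referencing = referencing
        super().__init__(f"dangling OID reference {oid!r} from <{referencing}>")


@dataclass
class Warning_:
    """One structured log line: a machine code, the OID involved, a message."""

    code: str
    oid: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.code}\t{self.oid}\t{self.message}"


@dataclass
class EventDef:
    oid: str
    name: str
    form_oids: list[str] = field(default_factory=list)


@dataclass
class FormDef:
    oid: str
    name: str
    itemgroup_oids: list[str] = field(default_factory=list)


@dataclass
class ItemGroupDef:
    oid: str
    name: str
    item_oids: list[str] = field(default_factory=list)


@dataclass
class ItemDef:
    oid: str
    name: str
    datatype: str  # one of DATATYPES
    codelist_oid: Optional[str] = None


@dataclass
class StudyMeta:
    study_oid: str
    event_defs: dict[str, EventDef] = field(default_factory=dict)
    form_defs: dict[str, FormDef] = field(default_factory=dict)
    itemgroup_defs: dict[str, ItemGroupDef] = field(default_factory=dict)
    item_defs: dict[str, ItemDef] = field(default_factory=dict)
    codelists: dict[str, dict[str, str]] = field(default_factory=dict)


@dataclass
class ItemData:
    item_oid: str
    value: str


@dataclass
class ItemGroupData:
    itemgroup_oid: str
    repeat_key: str = "1"
    items: list[ItemData] = field(default_factory=list)


@dataclass
class FormData:
    form_oid: str
    itemgroups: list[ItemGroupData] = field(default_factory=list)


@dataclass
class StudyEventData:
    event_oid: str
    repeat_key: str = "1"
    forms: list[FormData] = field(default_factory=list)


@dataclass
class SubjectData:
    subject_key: str
    events: list[StudyEventData] = field(default_factory=list)


@dataclass
class ODMDocument:
    studies: list[StudyMeta] = field(default_factory=list)
    subjects: list[SubjectData] = field(default_factory=list)
    source_dialect: str = "generic"  # or "openclinica"
    warnings: list[Warning_] = field(default_factory=list)

    @property
    def meta(self) -> StudyMeta:
        """The first (usually only) study's metadata."""
        return self.studies[0]


@dataclass(frozen=True)
class ItemDataRecord:
    """One ItemData element with its full five-OID coordinate.

    ``typed_value`` is None iff ``raw_value`` is empty or failed coercion to
    the ItemDef's datatype (the failure is logged on the document).
    """

    subject_key: str
    event_oid: str
    event_repeat: str
    form_oid: str
    itemgroup_oid: str
    itemgroup_repeat: str
    item_oid: str
    raw_value: str
    typed_value: object = None


def _local(el) -> str:
    tag = el.tag
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _children(el, name: str):
    return [c for c in el if _local(c) == name]


def _find(el, name: str):
    for c in el:
        if _local(c) == name:
            return c
    return None


_ODM_TYPE_MAP = {
    "text": "text",
    "string": "text",
    "integer": "integer",
    "float": "float",
    "double": "float",
    "date": "date",
    "datetime": "date",
    "partialdate": "date",
}


def _parse_metadata(study_el, warnings: list[Warning_]) -> StudyMeta:
    meta = StudyMeta(study_oid=study_el.get("OID", "Study.1"))
    mdv = None
    for mdv_candidate in study_el.iter():
        if _local(mdv_candidate) == "MetaDataVersion":
            mdv = mdv_candidate
            break
    if mdv is None:
        raise OdmParseError(
            f"study {meta.study_oid!r} has no MetaDataVersion element"
        )

    for el in _children(mdv, "CodeList"):
        codes: dict[str, str] = {}
        for item in _children(el, "CodeListItem"):
            code = item.get("CodedValue", "")
            decode = _find(item, "Decode")
            label = code
            if decode is not None:
                tt = _find(decode, "TranslatedText")
                if tt is not None and tt.text:
                    label = tt.text
            codes[code] = label
        meta.codelists[el.get("OID", "")] = codes

    for el in _children(mdv, "ItemDef"):
        raw_type = (el.get("DataType") or "text").lower()
        datatype = _ODM_TYPE_MAP.get(raw_type)
        if datatype is None:
            warnings.append(
                Warning_("W-DATATYPE", el.get("OID", ""),
                         f"unsupported DataType {raw_type!r}; treated as text")
            )
            datatype = "text"
        clref = _find(el, "CodeListRef")
        codelist_oid = None
        if clref is not None:
            codelist_oid = clref.get("CodeListOID")
            if codelist_oid not in meta.codelists:
                raise OdmReferenceError(codelist_oid or "?", "CodeListRef")
            datatype = "codelist"
        meta.item_defs[el.get("OID", "")] = ItemDef(
            oid=el.get("OID", ""),
            name=el.get("Name", el.get("OID", "")),
            datatype=datatype,
            codelist_oid=codelist_oid,
        )

    for el in _children(mdv, "ItemGroupDef"):
        igd = ItemGroupDef(oid=el.get("OID", ""), name=el.get("Name", ""))
        for ref in _children(el, "ItemRef"):
            oid = ref.get("ItemOID", "")
            if oid not in meta.item_defs:
                raise OdmReferenceError(oid, "ItemRef")
            igd.item_oids.append(oid)
        meta.itemgroup_defs[igd.oid] = igd

    for el in _children(mdv, "FormDef"):
        fd = FormDef(oid=el.get("OID", ""), name=el.get("Name", ""))
        for ref in _children(el, "ItemGroupRef"):
            oid = ref.get("ItemGroupOID", "")
            if oid not in meta.itemgroup_defs:
                raise OdmReferenceError(oid, "ItemGroupRef")
            fd.itemgroup_oids.append(oid)
        meta.form_defs[fd.oid] = fd

    for el in _children(mdv, "StudyEventDef"):
        ed = EventDef(oid=el.get("OID", ""), name=el.get("Name", ""))
        for ref in _children(el, "FormRef"):
            oid = ref.get("FormOID", "")
            if oid not in meta.form_defs:
                raise OdmReferenceError(oid, "FormRef")
            ed.form_oids.append(oid)
        meta.event_defs[ed.oid] = ed

    return meta


def _parse_clinical(cd_el, meta: StudyMeta) -> list[SubjectData]:
    subjects = []
    seen_keys: set[str] = set()
    for subj_el in _children(cd_el, "SubjectData"):
        key = subj_el.get("SubjectKey", "")
        if key in seen_keys:
            raise OdmParseError(f"duplicate SubjectKey {key!r}")
        seen_keys.add(key)
        subject = SubjectData(subject_key=key)
        for ev_el in _children(subj_el, "StudyEventData"):
            ev_oid = ev_el.get("StudyEventOID", "")
            if ev_oid not in meta.event_defs:
                raise OdmReferenceError(ev_oid, "StudyEventData")
            event = StudyEventData(
                event_oid=ev_oid,
                repeat_key=ev_el.get("StudyEventRepeatKey") or "1",
            )
            for form_el in _children(ev_el, "FormData"):
                form_oid = form_el.get("FormOID", "")
                if form_oid not in meta.form_defs:
                    raise OdmReferenceError(form_oid, "FormData")
                form = FormData(form_oid=form_oid)
                for ig_el in _children(form_el, "ItemGroupData"):
                    ig_oid = ig_el.get("ItemGroupOID", "")
                    if ig_oid not in meta.itemgroup_defs:
                        raise OdmReferenceError(ig_oid, "ItemGroupData")
                    ig = ItemGroupData(
                        itemgroup_oid=ig_oid,
                        repeat_key=ig_el.get("ItemGroupRepeatKey") or "1",
                    )
                    for it_el in _children(ig_el, "ItemData"):
                        it_oid = it_el.get("ItemOID", "")
                        if it_oid not in meta.item_defs:
                            raise OdmReferenceError(it_oid, "ItemData")
                        ig.items.append(
                            ItemData(item_oid=it_oid,
                                     value=it_el.get("Value", ""))
                        )
                    form.itemgroups.append(ig)
                event.forms.append(form)
            subject.events.append(event)
        subjects.append(subject)
    return subjects


def parse_odm(xml_text: str | bytes) -> ODMDocument:
    """Parse an ODM XML document into an :class:`ODMDocument`.

    Raises :class:`OdmParseError` for malformed XML (the lxml message carries
    the line number) and :class:`OdmReferenceError` for dangling OIDs.
    Unknown elements and vendor extension attributes are skipped with a
    warning on ``doc.warnings``.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise OdmParseError(f"malformed XML: {exc}") from exc
    if _local(root) != "ODM":
        raise OdmParseError(f"root element is <{_local(root)}>, expected <ODM>")

    dialect = "generic"
    for ns in (root.nsmap or {}).values():
        if ns and "openclinica" in ns.lower():
            dialect = "openclinica"

    doc = ODMDocument(source_dialect=dialect)
    study_els = _children(root, "Study")
    if not study_els:
        raise OdmParseError("document contains no Study element")
    for study_el in study_els:
        doc.studies.append(_parse_metadata(study_el, doc.warnings))

    meta = doc.studies[0]
    for cd_el in _children(root, "ClinicalData"):
        doc.subjects.extend(_parse_clinical(cd_el, meta))

    if dialect == "openclinica":
        doc.warnings.append(
            Warning_("I-DIALECT", "", "OpenClinica namespace detected; "
                     "extension attributes ignored")
        )
    return doc


def _coerce(raw: str, item_def: ItemDef, meta: StudyMeta):
    """Coerce a raw string per the ItemDef's datatype; None on failure."""
    if raw == "":
        return None
    dt = item_def.datatype
    try:
        if dt == "integer":
            return int(raw)
        if dt == "float":
            return float(raw)
        if dt == "date":
            return _dt.date.fromisoformat(raw)
        if dt == "codelist":
            codelist = meta.codelists.get(item_def.codelist_oid or "", {})
            if raw not in codelist:
                return None
            return raw
        return raw  # text
    except ValueError:
        return None


def iter_records(doc: ODMDocument) -> Iterator[ItemDataRecord]:
    """Yield one :class:`ItemDataRecord` per ItemData element, in document
    order, with values coerced per the ItemDef datatype.

    Coercion failures (including codelist violations) yield the record with
    ``typed_value=None`` and append a warning to ``doc.warnings``.
    """
    meta = doc.meta
    for subject in doc.subjects:
        for event in subject.events:
            for form in event.forms:
                for ig in form.itemgroups:
                    for item in ig.items:
                        item_def = meta.item_defs[item.item_oid]
                        typed = _coerce(item.value, item_def, meta)
                        if typed is None and item.value != "":
                            doc.warnings.append(Warning_(
                                "W-COERCE", item.item_oid,
                                f"value {item.value!r} failed coercion to "
                                f"{item_def.datatype}",
                            ))
                        yield ItemDataRecord(
                            subject_key=subject.subject_key,
                            event_oid=event.event_oid,
                            event_repeat=event.repeat_key,
                            form_oid=form.form_oid,
                            itemgroup_oid=ig.itemgroup_oid,
                            itemgroup_repeat=ig.repeat_key,
                            item_oid=item.item_oid,
                            raw_value=item.value,
                            typed_value=typed,
                        )


def serialize_odm(doc: ODMDocument) -> str:
    """Serialise an :class:`ODMDocument` back to ODM XML (plain dialect).

    Total on valid documents; round-trips through :func:`parse_odm` on all
    modelled fields.
    """
    nsmap = {None: ODM_NS}
    root = etree.Element(f"{{{ODM_NS}}}ODM", nsmap=nsmap,
                         FileType="Snapshot", FileOID="lcdc-export",
                         ODMVersion="1.3")

    for meta in doc.studies:
        study = etree.SubElement(root, f"{{{ODM_NS}}}Study", OID=meta.study_oid)
        gv = etree.SubElement(study, f"{{{ODM_NS}}}GlobalVariables")
        etree.SubElement(gv, f"{{{ODM_NS}}}StudyName").text = meta.study_oid
        etree.SubElement(gv, f"{{{ODM_NS}}}StudyDescription").text = meta.study_oid
        etree.SubElement(gv, f"{{{ODM_NS}}}ProtocolName").text = meta.study_oid
        mdv = etree.SubElement(study, f"{{{ODM_NS}}}MetaDataVersion",
                               OID="MDV.1", Name="MDV.1")
        for ed in meta.event_defs.values():
            el = etree.SubElement(mdv, f"{{{ODM_NS}}}StudyEventDef",
                                  OID=ed.oid, Name=ed.name, Repeating="No",
                                  Type="Scheduled")
            for oid in ed.form_oids:
                etree.SubElement(el, f"{{{ODM_NS}}}FormRef", FormOID=oid,
                                 Mandatory="No")
        for fd in meta.form_defs.values():
            el = etree.SubElement(mdv, f"{{{ODM_NS}}}FormDef", OID=fd.oid,
                                  Name=fd.name, Repeating="No")
            for oid in fd.itemgroup_oids:
                etree.SubElement(el, f"{{{ODM_NS}}}ItemGroupRef",
                                 ItemGroupOID=oid, Mandatory="No")
        for igd in meta.itemgroup_defs.values():
            el = etree.SubElement(mdv, f"{{{ODM_NS}}}ItemGroupDef",
                                  OID=igd.oid, Name=igd.name, Repeating="Yes")
            for oid in igd.item_oids:
                etree.SubElement(el, f"{{{ODM_NS}}}ItemRef", ItemOID=oid,
                                 Mandatory="No")
        for idf in meta.item_defs.values():
            dt = {"codelist": "text"}.get(idf.datatype, idf.datatype)
            el = etree.SubElement(mdv, f"{{{ODM_NS}}}ItemDef", OID=idf.oid,
                                  Name=idf.name, DataType=dt)
            if idf.codelist_oid:
                etree.SubElement(el, f"{{{ODM_NS}}}CodeListRef",
                                 CodeListOID=idf.codelist_oid)
        for cl_oid, codes in meta.codelists.items():
            el = etree.SubElement(mdv, f"{{{ODM_NS}}}CodeList", OID=cl_oid,
                                  Name=cl_oid, DataType="text")
            for code, label in codes.items():
                item = etree.SubElement(el, f"{{{ODM_NS}}}CodeListItem",
                                        CodedValue=code)
                dec = etree.SubElement(item, f"{{{ODM_NS}}}Decode")
                tt = etree.SubElement(dec, f"{{{ODM_NS}}}TranslatedText")
                tt.text = label

    if doc.subjects:
        meta = doc.meta
        cd = etree.SubElement(root, f"{{{ODM_NS}}}ClinicalData",
                              StudyOID=meta.study_oid, MetaDataVersionOID="MDV.1")
        for subject in doc.subjects:
            s_el = etree.SubElement(cd, f"{{{ODM_NS}}}SubjectData",
                                    SubjectKey=subject.subject_key)
            for event in subject.events:
                e_el = etree.SubElement(
                    s_el, f"{{{ODM_NS}}}StudyEventData",
                    StudyEventOID=event.event_oid,
                    StudyEventRepeatKey=event.repeat_key)
                for form in event.forms:
                    f_el = etree.SubElement(e_el, f"{{{ODM_NS}}}FormData",
                                            FormOID=form.form_oid)
                    for ig in form.itemgroups:
                        g_el = etree.SubElement(
                            f_el, f"{{{ODM_NS}}}ItemGroupData",
                            ItemGroupOID=ig.itemgroup_oid,
                            ItemGroupRepeatKey=ig.repeat_key)
                        for item in ig.items:
                            etree.SubElement(g_el, f"{{{ODM_NS}}}ItemData",
                                             ItemOID=item.item_oid,
                                             Value=item.value)

    return etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


def docs_equal(a: ODMDocument, b: ODMDocument) -> bool:
    """Field-by-field equality on modelled content (dialect and warnings
    excluded: they describe provenance of the parse, not the study)."""
    return a.studies == b.studies and a.subjects == b.subjects
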