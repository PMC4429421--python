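"""LCDC vocabulary, URI scheme and the deduplicated variable dictionary.

Every resource emitted by the pipeline — datasets, slices, observations,
observation groups, variables, universes, subjects — is minted through one
:class:`UriScheme` so IRIs are deterministic and injective.  The scheme
follows the Linked Data API convention: an IRI ending in an identifier
addresses a single instance (item endpoint), one ending in a keyword
addresses a list.

Study variables are modelled DDI-style: ItemDefs sharing a (normalised name,
datatype) pair collapse into a single :class:`VariableDef` that records all
source ItemDef OIDs, and variables are grouped into :class:`Universe`
instances (one per form-level theme / sub-theme pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from urllib.parse import quote

from rdflib import Namespace

from .odm_io import StudyMeta

QB = Namespace("http://purl.org/linked-data/cube#")
DISCO = Namespace("http://rdf-vocabulary.ddialliance.org/discovery#")
VOID = Namespace("http://rdfs.org/ns/void#")
XKOS = Namespace("http://rdf-vocabulary.ddialliance.org/xkos#")
SKOS = Namespace("http://www.w3.org/2004/02/skos/core#")
#: LCDC-specific terms: mainObservation, specialisedObservation,
#: specialisedSeries, specialisedSection, the dimension/measure properties.
LCDC = Namespace("http://example.org/lcdc/ns#")

DEFAULT_TEMPLATES: dict[str, str] = {
    "dataset": "{base}/dataset/{theme}",
    "slice": "{base}/dataset/{theme}/slice/{slice_kind}/{key}",
    "observation": "{base}/observation/{subject}.{event}.{variable}.{repeat}",
    "main_observation":
        "{base}/observation/main/{subject}.{event}.{variable}.{repeat}",
    "observation_group":
        "{base}/observation-group/{subject}.{event}.{variable}.{repeat}",
    "variable": "{base}/variable/{name}",
    "universe": "{base}/universe/{theme}/{sub_theme}",
    "subject": "{base}/subject/{subject_key}",
    "medication": "{base}/medication/{record_id}",
}


class UriSchemeError(ValueError):
    """Template arity mismatch or unknown resource kind."""


@dataclass(frozen=True)
class UriScheme:
    base: str = "http://example.org/lcdc"
    templates: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES))


def _placeholders(template: str) -> list[str]:
    import string

    return [f for _, f, _, _ in string.Formatter().parse(template)
            if f is not None and f != "base"]


def mint_iri(scheme: UriScheme, kind: str, keys: tuple | list) -> str:
    """Mint the IRI for a resource.

    Deterministic and injective on (kind, keys); key components are
    percent-encoded so arbitrary study identifiers stay URL-safe.
    """
    template = scheme.templates.get(kind)
    if template is None:
        raise UriSchemeError(f"unknown resource kind {kind!r}")
    names = _placeholders(template)
    if len(names) != len(keys):
        raise UriSchemeError(
            f"kind {kind!r} takes {len(names)} key(s) {names}, got "
            f"{len(keys)}: {list(keys)!r}")
    encoded = {n: quote(str(k), safe="") for n, k in zip(names, keys)}
    return template.format(base=scheme.base.rstrip("/"), **encoded)


@dataclass
class VariableDef:
    """A deduplicated study variable (DDI disco:Variable analogue)."""

    name: str
    label: str
    datatype: str
    universe: tuple[str, str]  # (theme, sub_theme)
    source_item_oids: set[str] = field(default_factory=set)
    cdisc_coupling: str | None = None


@dataclass
class Universe:
    theme: str
    sub_theme: str
    member_variables: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, str]:
        return (self.theme, self.sub_theme)


class VariableConflictError(ValueError):
    """Same variable name declared with two different datatypes."""


class ThemeMapError(KeyError):
    """A FormDef OID is missing from the theme configuration."""


def register_variables(
    meta: StudyMeta, theme_map: dict[str, tuple[str, str]]
) -> tuple[dict[str, VariableDef], dict[tuple[str, str], Universe]]:
    """Build the deduplicated variable dictionary and its universes.

    ItemDefs with the same (case-normalised name, datatype) collapse into one
    :class:`VariableDef` listing every source OID; the label and universe come
    from the first occurrence in definition order.  A name reused with a
    conflicting datatype raises :class:`VariableConflictError` naming both
    ItemDef OIDs.
    """
    for form_oid in meta.form_defs:
        if form_oid not in theme_map:
            raise ThemeMapError(
                f"form {form_oid!r} has no theme/sub-theme assignment")

    variables: dict[str, VariableDef] = {}
    universes: dict[tuple[str, str], Universe] = {}
    seen_name_oid: dict[str, str] = {}

    for form_oid, form in meta.form_defs.items():
        theme, sub_theme = theme_map[form_oid]
        ukey = (theme, sub_theme)
        if ukey not in universes:
            universes[ukey] = Universe(theme=theme, sub_theme=sub_theme)
        for ig_oid in form.itemgroup_oids:
            for item_oid in meta.itemgroup_defs[ig_oid].item_oids:
                item = meta.item_defs[item_oid]
                name = item.name.strip().lower()
                existing = variables.get(name)
                if existing is None:
                    variables[name] = VariableDef(
                        name=name, label=item.name, datatype=item.datatype,
                        universe=ukey, source_item_oids={item_oid})
                    universes[ukey].member_variables.add(name)
                    seen_name_oid[name] = item_oid
                elif existing.datatype != item.datatype:
                    raise VariableConflictError(
                        f"variable {name!r} declared as {existing.datatype} "
                        f"(ItemDef {seen_name_oid[name]}) and "
                        f"{item.datatype} (ItemDef {item_oid})")
                else:
                    existing.source_item_oids.add(item_oid)

    # drop universes that gathered no variables (forms with empty groups)
    universes = {k: u for k, u in universes.items() if u.member_variables}
    return variables, universes


def variable_for_item(
    variables: dict[str, VariableDef], meta: StudyMeta, item_oid: str
) -> VariableDef:
    """Resolve an ItemDef OID to its (possibly shared) VariableDef."""
    name = meta.item_defs[item_oid].name.strip().lower()
    return variables[name]
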