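"""Map patient-reported medication names to drug terminologies.

Free-text medication entries mix trade names, active ingredients and
informal names, with inconsistent casing, embedded dosages ("50mg",
"1 tablet") and parenthetical asides.  The pipeline cleans each name with a
reproducible rule chain plus a curated override table (so one-off manual
fixes are data, not code), then attempts four mapping phases:

1. **Trade Product** (AMT TP), assisted by the ARTG brand registry;
2. **Medicinal Product** (AMT MP), boosted by DrugBank names and synonyms
   routed through the DrugBank↔AMT-MP cross-map;
3. **Substance** (active ingredients), against the UNII list with AMT
   Medicinal Substance as fallback — multi-ingredient names are split on
   "+" and "/" and matched per ingredient;
4. **ATC DDD** classification codes, collected over the cross-maps
   (DrugBank↔ATC for product matches; substance↔ATC where the fixture
   provides it).

Phases are independent: disabling one never changes another's matches.
Within a phase, match precedence is exact > normalized > synonym/alias, and
ties within a method are broken by the lexicographically smallest code.

The output is a linked-medications RDF graph (``skos:exactMatch`` links,
plus xkos-style concept-association nodes for the many-to-many AMT-MP ↔
ARTG relationships) and a mapping-statistics report with percentages
rounded half-up to two decimals.
"""

from __future__ import annotations

import csv
import difflib
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional

import pandas as pd
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef

from .lcdc_model import LCDC, SKOS, UriScheme, XKOS, mint_iri

AMT = Namespace("http://example.org/terms/amt/")
ARTG = Namespace("http://example.org/terms/artg/")
DRUGBANK = Namespace("http://example.org/terms/drugbank/")
DBCAT = Namespace("http://example.org/terms/drugbank/category/")
UNII_NS = Namespace("http://example.org/terms/unii/")
ATC_NS = Namespace("http://example.org/terms/atc/")
DCT = Namespace("http://purl.org/dc/terms/")

#: valid ATC code lengths per level of the 5-level hierarchy
ATC_LEVEL_LENGTHS = (1, 3, 4, 5, 7)


class UnmappableNameError(ValueError):
    """Cleaning reduced a medication name to the empty string."""


class TerminologyIntegrityError(ValueError):
    """A cross-map endpoint does not resolve, or a code is malformed."""


@dataclass(frozen=True)
class MedicationRecord:
    record_id: str
    subject_key: str
    event: str
    raw_name: str
    cleaned_name: str = ""


@dataclass
class DrugBankEntry:
    id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)
    interacts_with: list[str] = field(default_factory=list)


@dataclass
class TerminologySet:
    """Indexed mini-terminologies plus the cross-maps that interlink them.

    Cross-maps are sets of (source_code, target_code) pairs keyed by
    ``"<source>_<target>"``: ``amt_tp_artg``, ``amt_mp_drugbank``,
    ``amt_ms_unii``, ``drugbank_atc`` and optionally ``amt_mp_artg`` (brand
    registrations of a medicinal product) and ``unii_atc``.
    """

    amt_tp: dict[str, str] = field(default_factory=dict)
    amt_mp: dict[str, str] = field(default_factory=dict)
    amt_ms: dict[str, str] = field(default_factory=dict)
    artg_brands: dict[str, str] = field(default_factory=dict)  # code -> brand
    drugbank: dict[str, DrugBankEntry] = field(default_factory=dict)
    unii: dict[str, str] = field(default_factory=dict)
    atc: dict[str, str] = field(default_factory=dict)
    cross_maps: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    # ---- lazily built lookup indexes -------------------------------------
    def _index(self, labels: dict[str, str], normalize: bool) -> dict[str, str]:
        idx: dict[str, str] = {}
        for code in sorted(labels):  # sorted => smallest code wins a tie
            key = _normalize(labels[code]) if normalize else labels[code].casefold()
            idx.setdefault(key, code)
        return idx

    def indexes(self, scheme: str) -> tuple[dict[str, str], dict[str, str]]:
        """(exact, normalized) label indexes for an AMT/UNII scheme."""
        cache = self.__dict__.setdefault("_idx_cache", {})
        if scheme not in cache:
            labels = getattr(self, scheme)
            cache[scheme] = (self._index(labels, False),
                             self._index(labels, True))
        return cache[scheme]

    def crossmap_targets(self, name: str, code: str) -> list[str]:
        return sorted(t for s, t in self.cross_maps.get(name, ()) if s == code)

    def crossmap_sources(self, name: str, code: str) -> list[str]:
        return sorted(s for s, t in self.cross_maps.get(name, ()) if t == code)


def validate_terminologies(terms: TerminologySet) -> None:
    """Enforce the TerminologySet invariants: every cross-map endpoint
    resolves and ATC codes respect the 5-level code grammar."""
    pools = {
        "amt_tp": terms.amt_tp, "amt_mp": terms.amt_mp,
        "amt_ms": terms.amt_ms, "artg": terms.artg_brands,
        "drugbank": terms.drugbank, "unii": terms.unii, "atc": terms.atc,
    }
    for code in terms.atc:
        if len(code) not in ATC_LEVEL_LENGTHS:
            raise TerminologyIntegrityError(
                f"ATC code {code!r} violates the 5-level grammar")
    for name, pairs in terms.cross_maps.items():
        src_scheme, _, tgt_scheme = name.rpartition("_")
        src_pool = pools.get(src_scheme)
        tgt_pool = pools.get(tgt_scheme)
        if src_pool is None or tgt_pool is None:
            raise TerminologyIntegrityError(f"unknown cross-map {name!r}")
        for s, t in pairs:
            if s not in src_pool:
                raise TerminologyIntegrityError(
                    f"cross-map {name}: dangling source {s!r}")
            if t not in tgt_pool:
                raise TerminologyIntegrityError(
                    f"cross-map {name}: dangling target {t!r}")


# --------------------------------------------------------------------------
# name cleaning

_PAREN_RE = re.compile(r"\([^)]*\)")
_DOSE_RE = re.compile(
    r"\b\d+(?:\.\d+)?\s*(?:mg|mcg|µg|g|kg|ml|l|iu|u|%)\b"
    r"|\b\d+\s*(?:x\s*)?(?:tablets?|tabs?|capsules?|caps?|drops?|puffs?)\b"
    r"|\b(?:tablets?|tabs?|capsules?|caps?)\b",
    re.IGNORECASE)
_PUNCT_RE = re.compile(r"[^\w+/\s-]")
_WS_RE = re.compile(r"\s+")


def _squash(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


def _normalize(text: str) -> str:
    """Aggressive form for the 'normalized' match method: alphanumerics only."""
    return re.sub(r"[^0-9a-z]", "", text.casefold())


def clean_name(raw: str, overrides: Optional[dict[str, str]] = None) -> str:
    """Clean one patient-reported medication name.

    Rule chain: curated override lookup (on the case-folded,
    whitespace-collapsed raw name) takes precedence; then case folding,
    parenthetical removal, dosage/strength token stripping, and
    punctuation/whitespace collapse.  ``+`` and ``/`` survive so
    multi-ingredient names can still be split downstream.

    Raises :class:`UnmappableNameError` when cleaning empties the name.
    """
    if not raw:
        raise UnmappableNameError("empty medication name")
    key = _squash(raw.casefold())
    if overrides:
        normalized_overrides = {
            _squash(k.casefold()): v for k, v in overrides.items()}
        if key in normalized_overrides:
            return normalized_overrides[key]
    text = raw.casefold()
    text = _PAREN_RE.sub(" ", text)
    text = _DOSE_RE.sub(" ", text)
    text = _PUNCT_RE.sub(" ", text)
    text = _squash(text)
    if not text:
        raise UnmappableNameError(f"name {raw!r} cleaned to empty string")
    return text


# --------------------------------------------------------------------------
# match phases

@dataclass(frozen=True)
class Match:
    code: str
    scheme: str                 # amt_tp | amt_mp | unii | amt_ms
    method: str                 # exact | normalized | synonym | fuzzy
    ingredients: tuple[str, ...] = ()
    #: cross-mapped companion codes reported alongside the primary code
    also: tuple[tuple[str, str], ...] = ()


@dataclass
class MatchResult:
    record_id: str
    tp_match: Optional[Match] = None
    mp_match: Optional[Match] = None
    substance_match: Optional[Match] = None
    atc_codes: set[str] = field(default_factory=set)
    #: ATC codes that arrived via a substance↔ATC hop only (flagged)
    atc_substance_codes: set[str] = field(default_factory=set)
    unmappable: bool = False

    @property
    def mapped_any(self) -> bool:
        return any((self.tp_match, self.mp_match, self.substance_match))


def _dict_lookup(name: str, terms: TerminologySet,
                 scheme: str) -> Optional[Match]:
    exact, normalized = terms.indexes(scheme)
    code = exact.get(name.casefold())
    if code is not None:
        return Match(code, scheme, "exact")
    code = normalized.get(_normalize(name))
    if code is not None:
        return Match(code, scheme, "normalized")
    return None


def _fuzzy_lookup(name: str, labels: dict[str, str], scheme: str,
                  threshold: float) -> Optional[Match]:
    best: tuple[float, str] | None = None
    target = name.casefold()
    for code in sorted(labels):
        score = difflib.SequenceMatcher(None, target,
                                        labels[code].casefold()).ratio()
        if score >= threshold and (best is None or score > best[0]):
            best = (score, code)
    return Match(best[1], scheme, "fuzzy") if best else None


def match_trade_product(name: str, terms: TerminologySet,
                        fuzzy_threshold: float | None = None
                        ) -> Optional[Match]:
    """Phase 1: AMT Trade Product.  Precedence: exact label > normalized
    label > ARTG brand alias routed through the ARTG↔AMT-TP cross-map."""
    hit = _dict_lookup(name, terms, "amt_tp")
    if hit:
        return hit
    # ARTG brand alias
    brand_exact, brand_norm = terms.indexes("artg_brands")
    artg_code = brand_exact.get(name.casefold()) or brand_norm.get(
        _normalize(name))
    if artg_code is not None:
        tp_codes = terms.crossmap_sources("amt_tp_artg", artg_code)
        if tp_codes:
            return Match(tp_codes[0], "amt_tp", "synonym")
    if fuzzy_threshold is not None:
        return _fuzzy_lookup(name, terms.amt_tp, "amt_tp", fuzzy_threshold)
    return None


def match_medicinal_product(name: str, terms: TerminologySet,
                            fuzzy_threshold: float | None = None
                            ) -> Optional[Match]:
    """Phase 2: AMT Medicinal Product, boosted by DrugBank names/synonyms
    routed through the DrugBank↔AMT-MP cross-map."""
    hit = _dict_lookup(name, terms, "amt_mp")
    if hit:
        return hit
    wanted = {name.casefold(), _normalize(name)}
    candidates: list[str] = []
    for db_id in sorted(terms.drugbank):
        entry = terms.drugbank[db_id]
        aliases = [entry.name, *entry.synonyms]
        if any(a.casefold() in wanted or _normalize(a) in wanted
               for a in aliases):
            candidates.extend(terms.crossmap_sources("amt_mp_drugbank", db_id))
    if candidates:
        return Match(sorted(candidates)[0], "amt_mp", "synonym")
    if fuzzy_threshold is not None:
        return _fuzzy_lookup(name, terms.amt_mp, "amt_mp", fuzzy_threshold)
    return None


_SPLIT_RE = re.compile(r"\s*[+/]\s*")


def match_substance(name: str, terms: TerminologySet,
                    fuzzy_threshold: float | None = None) -> Optional[Match]:
    """Phase 3: active-ingredient match against UNII, falling back to AMT
    Medicinal Substance; UNII preferred on a double hit with the
    cross-mapped AMT-MS code reported alongside.  Multi-ingredient names are
    split on "+" / "/" — a match on any ingredient counts and every matched
    ingredient is recorded."""
    parts = [p for p in _SPLIT_RE.split(name) if p]
    matched: list[tuple[str, Match]] = []
    for part in parts:
        unii_hit = _dict_lookup(part, terms, "unii")
        ms_hit = _dict_lookup(part, terms, "amt_ms")
        hit = None
        if unii_hit:
            also = []
            for ms_code in terms.crossmap_sources("amt_ms_unii",
                                                  unii_hit.code):
                also.append(("amt_ms", ms_code))
            hit = Match(unii_hit.code, "unii", unii_hit.method,
                        also=tuple(also))
        elif ms_hit:
            hit = ms_hit
        elif fuzzy_threshold is not None:
            hit = _fuzzy_lookup(part, terms.unii, "unii", fuzzy_threshold)
        if hit:
            matched.append((part, hit))
    if not matched:
        return None
    first = matched[0][1]
    extra = tuple((m.scheme, m.code) for _, m in matched[1:])
    return Match(first.code, first.scheme, first.method,
                 ingredients=tuple(p for p, _ in matched),
                 also=first.also + extra)


def map_to_atc(result: MatchResult, terms: TerminologySet) -> MatchResult:
    """Phase 4: collect ATC DDD codes over the cross-maps.

    Product matches hop AMT-MP → DrugBank → ATC; substance matches hop
    UNII → ATC only where the fixture provides that map, and such codes are
    additionally flagged in ``atc_substance_codes``."""
    if result.mp_match and result.mp_match.scheme == "amt_mp":
        for db_id in terms.crossmap_targets("amt_mp_drugbank",
                                            result.mp_match.code):
            result.atc_codes.update(
                terms.crossmap_targets("drugbank_atc", db_id))
    if result.substance_match:
        codes = [result.substance_match.code] + [
            c for s, c in result.substance_match.also if s == "unii"]
        for code in codes:
            hops = terms.crossmap_targets("unii_atc", code)
            result.atc_codes.update(hops)
            result.atc_substance_codes.update(hops)
    return result


def atc_ancestors(code: str) -> list[str]:
    """The proper ancestors of an ATC code, derived from the level grammar
    (1/3/4/5/7 characters)."""
    return [code[:n] for n in ATC_LEVEL_LENGTHS if n < len(code)]


def map_medications(records: list[MedicationRecord], terms: TerminologySet,
                    overrides: Optional[dict[str, str]] = None,
                    fuzzy_threshold: float | None = None,
                    phases: tuple[str, ...] = ("tp", "mp", "substance", "atc"),
                    ) -> tuple[list[MedicationRecord], list[MatchResult]]:
    """Run the full cleaning + four-phase mapping pipeline.

    Returns the records with ``cleaned_name`` filled and one
    :class:`MatchResult` per record, in input order.
    """
    cleaned_records: list[MedicationRecord] = []
    results: list[MatchResult] = []
    for rec in records:
        try:
            cleaned = clean_name(rec.raw_name, overrides)
        except UnmappableNameError:
            cleaned_records.append(rec)
            results.append(MatchResult(record_id=rec.record_id,
                                       unmappable=True))
            continue
        rec = MedicationRecord(rec.record_id, rec.subject_key, rec.event,
                               rec.raw_name, cleaned)
        cleaned_records.append(rec)
        res = MatchResult(record_id=rec.record_id)
        if "tp" in phases:
            res.tp_match = match_trade_product(cleaned, terms, fuzzy_threshold)
        if "mp" in phases:
            res.mp_match = match_medicinal_product(cleaned, terms,
                                                   fuzzy_threshold)
        if "substance" in phases:
            res.substance_match = match_substance(cleaned, terms,
                                                  fuzzy_threshold)
        if "atc" in phases:
            map_to_atc(res, terms)
        results.append(res)
    return cleaned_records, results


# --------------------------------------------------------------------------
# report

def _pct(count: int, total: int) -> str:
    pct = Decimal(count) * 100 / Decimal(total)
    return str(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)) + "%"


def report_from_counts(total: int, any_count: int, tp: int, mp: int,
                       substance: int) -> pd.DataFrame:
    """Format the mapping-statistics table from raw counts (percentages
    rounded half-up to two decimals)."""
    if total <= 0:
        raise ValueError("report requires a positive record total")
    if not max(tp, mp, substance) <= any_count <= tp + mp + substance:
        raise ValueError("union count inconsistent with per-phase counts")
    rows = [
        ("Total", total),
        ("Medicinal product/trade product/substance", any_count),
        ("Trade product", tp),
        ("Medicinal product", mp),
        ("Substance", substance),
    ]
    return pd.DataFrame(
        [(name, count, _pct(count, total)) for name, count in rows],
        columns=["Mapped", "Count", "Percentage"])


def mapping_report(results: list[MatchResult]) -> pd.DataFrame:
    """The mapping-statistics report: total records, records mapped to any
    of MP/TP/Substance, and each phase individually, with percentages."""
    if not results:
        raise ValueError("cannot report on an empty result set")
    total = len(results)
    return report_from_counts(
        total,
        sum(r.mapped_any for r in results),
        sum(r.tp_match is not None for r in results),
        sum(r.mp_match is not None for r in results),
        sum(r.substance_match is not None for r in results),
    )


# --------------------------------------------------------------------------
# linked-medications graph

_SCHEME_NS = {"amt_tp": AMT, "amt_mp": AMT, "amt_ms": AMT,
              "unii": UNII_NS, "atc": ATC_NS}
_SCHEME_TYPE = {"amt_tp": AMT.TradeProduct, "amt_mp": AMT.MedicinalProduct,
                "amt_ms": AMT.MedicinalSubstance, "unii": UNII_NS.Substance,
                "atc": ATC_NS.Classification}


def concept_iri(scheme: str, code: str) -> URIRef:
    if scheme == "drugbank":
        return DRUGBANK[code]
    if scheme == "artg":
        return ARTG[code]
    return _SCHEME_NS[scheme][code]


def _emit_concept(g: Graph, scheme: str, code: str, label: str) -> URIRef:
    iri = concept_iri(scheme, code)
    g.add((iri, RDF.type, _SCHEME_TYPE[scheme]))
    g.add((iri, RDFS.label, Literal(label)))
    return iri


def build_linked_med_graph(results: list[MatchResult],
                           records: list[MedicationRecord],
                           terms: TerminologySet,
                           scheme: UriScheme | None = None) -> Graph:
    """Emit the linked-medications graph: one node per study medication
    record with ``skos:exactMatch`` links to every matched terminology
    concept (including the DrugBank entity behind a cross-mapped MP match),
    plus xkos concept-association nodes reifying the many-to-many AMT-MP ↔
    ARTG relationships of the matched products."""
    scheme = scheme or UriScheme()
    by_id = {r.record_id: r for r in records}
    g = Graph()
    g.bind("skos", SKOS)
    g.bind("xkos", XKOS)
    g.bind("lcdc", LCDC)
    g.bind("amt", AMT)
    g.bind("drugbank", DRUGBANK)

    pools = {"amt_tp": terms.amt_tp, "amt_mp": terms.amt_mp,
             "amt_ms": terms.amt_ms, "unii": terms.unii, "atc": terms.atc}

    def label_for(scheme_name: str, code: str) -> str:
        pool = pools[scheme_name]
        if code not in pool:
            raise TerminologyIntegrityError(
                f"dangling code {code!r} in scheme {scheme_name!r}")
        return pool[code]

    mp_codes_seen: set[str] = set()
    for res in results:
        rec = by_id[res.record_id]
        med = URIRef(mint_iri(scheme, "medication", [rec.record_id]))
        g.add((med, RDF.type, LCDC.MedicationRecord))
        g.add((med, RDFS.label, Literal(rec.raw_name)))
        g.add((med, LCDC.cleanedName, Literal(rec.cleaned_name)))
        g.add((med, LCDC.subject,
               URIRef(mint_iri(scheme, "subject", [rec.subject_key]))))
        g.add((med, LCDC.timepoint, Literal(rec.event)))

        for match in (res.tp_match, res.mp_match, res.substance_match):
            if match is None:
                continue
            iri = _emit_concept(g, match.scheme, match.code,
                                label_for(match.scheme, match.code))
            g.add((med, SKOS.exactMatch, iri))
            for also_scheme, also_code in match.also:
                also_iri = _emit_concept(g, also_scheme, also_code,
                                         label_for(also_scheme, also_code))
                g.add((med, SKOS.exactMatch, also_iri))
        if res.mp_match and res.mp_match.scheme == "amt_mp":
            mp_codes_seen.add(res.mp_match.code)
            for db_id in terms.crossmap_targets("amt_mp_drugbank",
                                                res.mp_match.code):
                if db_id not in terms.drugbank:
                    raise TerminologyIntegrityError(
                        f"dangling DrugBank id {db_id!r}")
                db_iri = DRUGBANK[db_id]
                g.add((db_iri, RDF.type, DRUGBANK.Drug))
                g.add((db_iri, RDFS.label,
                       Literal(terms.drugbank[db_id].name)))
                g.add((med, SKOS.exactMatch, db_iri))
        for atc_code in sorted(res.atc_codes):
            iri = _emit_concept(g, "atc", atc_code,
                                label_for("atc", atc_code))
            g.add((med, SKOS.exactMatch, iri))

    # xkos concept associations: MP <-> registered ARTG brands (many-to-many)
    for mp_code in sorted(mp_codes_seen):
        for artg_code in terms.crossmap_targets("amt_mp_artg", mp_code):
            assoc = URIRef(f"{str(LCDC)}association/{mp_code}.{artg_code}")
            g.add((assoc, RDF.type, XKOS.ConceptAssociation))
            g.add((assoc, LCDC.associationSource, AMT[mp_code]))
            g.add((assoc, LCDC.associationTarget, ARTG[artg_code]))
    return g


def terminology_graph(terms: TerminologySet) -> Graph:
    """Render the terminology set itself as RDF: typed concepts with labels,
    DrugBank categories and interaction links, the ATC broader-code tree,
    and every cross-map as ``skos:exactMatch``."""
    g = Graph()
    g.bind("skos", SKOS)
    g.bind("amt", AMT)
    g.bind("drugbank", DRUGBANK)
    g.bind("dcterms", DCT)
    for scheme_name in ("amt_tp", "amt_mp", "amt_ms", "unii", "atc"):
        for code, label in getattr(terms, scheme_name).items():
            _emit_concept(g, scheme_name, code, label)
    for code in sorted(terms.atc):
        for anc in atc_ancestors(code):
            if anc in terms.atc:
                g.add((ATC_NS[code], SKOS.broader, ATC_NS[anc]))
    for artg_code, brand in terms.artg_brands.items():
        g.add((ARTG[artg_code], RDF.type, ARTG.RegisteredMedicine))
        g.add((ARTG[artg_code], RDFS.label, Literal(brand)))
    for db_id, entry in terms.drugbank.items():
        iri = DRUGBANK[db_id]
        g.add((iri, RDF.type, DRUGBANK.Drug))
        g.add((iri, RDFS.label, Literal(entry.name)))
        for syn in entry.synonyms:
            g.add((iri, SKOS.altLabel, Literal(syn)))
        for cat in entry.categories:
            cat_iri = DBCAT[cat.replace(" ", "-")]
            g.add((cat_iri, RDF.type, DBCAT.Category))
            g.add((cat_iri, RDFS.label, Literal(cat)))
            g.add((iri, DCT.subject, cat_iri))
        for other in entry.interacts_with:
            g.add((iri, DRUGBANK.interactsWith, DRUGBANK[other]))
    _XM_SCHEME = {"amt_tp": "amt_tp", "amt_mp": "amt_mp", "amt_ms": "amt_ms",
                  "drugbank": "drugbank", "artg": "artg", "unii": "unii",
                  "atc": "atc"}
    for name, pairs in terms.cross_maps.items():
        src_scheme, _, tgt_scheme = name.rpartition("_")
        for s, t in sorted(pairs):
            g.add((concept_iri(_XM_SCHEME[src_scheme], s), SKOS.exactMatch,
                   concept_iri(_XM_SCHEME[tgt_scheme], t)))
    return g


# --------------------------------------------------------------------------
# delimited-table persistence for terminology fixtures and records

def write_terminologies(terms: TerminologySet, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _write(name: str, header: list[str], rows) -> None:
        with open(outdir / name, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)

    for scheme_name in ("amt_tp", "amt_mp", "amt_ms", "unii", "atc"):
        pool = getattr(terms, scheme_name)
        _write(f"{scheme_name}.csv", ["code", "label"],
               sorted(pool.items()))
    _write("artg.csv", ["code", "brand"], sorted(terms.artg_brands.items()))
    _write("drugbank.csv",
           ["id", "name", "synonyms", "categories", "interacts_with"],
           [(e.id, e.name, "|".join(e.synonyms), "|".join(e.categories),
             "|".join(e.interacts_with))
            for e in (terms.drugbank[k] for k in sorted(terms.drugbank))])
    _write("crossmaps.csv",
           ["source_scheme", "source_code", "target_scheme", "target_code"],
           [(name.rpartition("_")[0], s, name.rpartition("_")[2], t)
            for name in sorted(terms.cross_maps)
            for s, t in sorted(terms.cross_maps[name])])
    return outdir


def load_terminologies(indir: str | Path) -> TerminologySet:
    indir = Path(indir)

    def _read(name: str) -> list[dict[str, str]]:
        with open(indir / name, newline="") as fh:
            return list(csv.DictReader(fh))

    terms = TerminologySet()
    for scheme_name in ("amt_tp", "amt_mp", "amt_ms", "unii", "atc"):
        getattr(terms, scheme_name).update(
            (r["code"], r["label"]) for r in _read(f"{scheme_name}.csv"))
    terms.artg_brands.update(
        (r["code"], r["brand"]) for r in _read("artg.csv"))
    for r in _read("drugbank.csv"):
        terms.drugbank[r["id"]] = DrugBankEntry(
            id=r["id"], name=r["name"],
            synonyms=[s for s in r["synonyms"].split("|") if s],
            categories=[s for s in r["categories"].split("|") if s],
            interacts_with=[s for s in r["interacts_with"].split("|") if s])
    for r in _read("crossmaps.csv"):
        key = f"{r['source_scheme']}_{r['target_scheme']}"
        terms.cross_maps.setdefault(key, set()).add(
            (r["source_code"], r["target_code"]))
    validate_terminologies(terms)
    return terms


def load_medication_records(path: str | Path) -> list[MedicationRecord]:
    with open(path, newline="") as fh:
        return [MedicationRecord(r["record_id"], r["subject_key"],
                                 r["event"], r["raw_name"])
                for r in csv.DictReader(fh)]


def write_report(report: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    report.to_csv(path, sep="\t", index=False)
    return path
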