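"""Synthetic longitudinal-study and terminology fixtures with ground truth.

The generator emulates, at desk scale, a prospective ageing cohort: subjects
reassessed at scheduled visits (baseline, month18, ...), with themed case
report forms across five domains (Study, Clinical, Cognitive, Imaging,
Lifestyle) covering vital signs, blood triglycerides, neurological
classifications, demographics and free-text patient-reported medications.

Everything is planted: the fraction of subjects hypertensive at baseline
(both readings strictly above 140/90), the fraction whose triglycerides stay
below the 1.7 mmol/L bound, the fraction transitioning from a healthy
classification to mild cognitive impairment between the first two visits,
and — per medication string — the terminology entry it corrupts and the
mapping phase expected to recover it.  The accompanying
:class:`GroundTruthManifest` records all of it, so every downstream module
can be checked against an oracle that never touches the RDF pipeline.

Determinism contract: the same config and seed produce byte-identical ODM
XML and an identical manifest.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

from .med_mapper import DrugBankEntry, TerminologySet, validate_terminologies
from .odm_io import (
    EventDef, FormDef, ItemData, ItemDef, ItemGroupData, ItemGroupDef,
    ODMDocument, FormData, StudyEventData, StudyMeta, SubjectData,
    serialize_odm,
)

# --------------------------------------------------------------------------
# curated drug catalogue (constant: closure invariants hold by construction)

ANTI_DIABETIC = "anti-diabetic"


@dataclass(frozen=True)
class _Drug:
    ingredient: str
    db_id: str
    atc: str | None
    categories: tuple[str, ...]
    brands: tuple[str, ...] = ()          # first brand is the TP label
    alias_brands: tuple[str, ...] = ()    # in ARTG only, not a TP label
    synonyms: tuple[str, ...] = ()
    in_unii: bool = True
    in_amt: bool = True                   # has MP/MS/TP entries


_CATALOGUE: tuple[_Drug, ...] = (
    _Drug("metformin", "DB00331", "A10BA02", (ANTI_DIABETIC,),
          ("Diabex",), ("Glucophage", "Diaformin"), ("dimethylbiguanide",)),
    _Drug("gliclazide", "DB01120", "A10BB09", (ANTI_DIABETIC,),
          ("Diamicron",)),
    _Drug("glimepiride", "DB00222", "A10BB12", (ANTI_DIABETIC,), ("Amaryl",)),
    _Drug("glipizide", "DB01067", "A10BB07", (ANTI_DIABETIC,), ("Minidiab",)),
    _Drug("pioglitazone", "DB01132", "A10BG03", (ANTI_DIABETIC,), ("Actos",)),
    _Drug("rosiglitazone", "DB00412", "A10BG02", (ANTI_DIABETIC,),
          ("Avandia",)),
    _Drug("sitagliptin", "DB01261", "A10BH01", (ANTI_DIABETIC,), ("Januvia",)),
    _Drug("insulin glargine", "DB00047", "A10AE04", (ANTI_DIABETIC,),
          ("Lantus",)),
    _Drug("paracetamol", "DB00316", "N02BE01", ("analgesic",),
          ("Panadol",), ("Panadol Osteo",), ("acetaminophen",)),
    _Drug("atorvastatin", "DB01076", "C10AA05", ("statin",), ("Lipitor",)),
    _Drug("simvastatin", "DB00641", "C10AA01", ("statin",), ("Zocor",)),
    _Drug("omeprazole", "DB00338", "A02BC01", ("proton-pump-inhibitor",),
          ("Losec",)),
    _Drug("ramipril", "DB00178", "C09AA05", ("ace-inhibitor",), ("Tritace",)),
    _Drug("amlodipine", "DB00381", "C08CA01", ("calcium-channel-blocker",),
          ("Norvasc",)),
    _Drug("sertraline", "DB01104", "N06AB06", ("antidepressant",),
          ("Zoloft",)),
    _Drug("donepezil", "DB00843", "N06DA02", ("anti-dementia",),
          ("Aricept",)),
    _Drug("ibuprofen", "DB01050", "M01AE01", ("nsaid",), ("Nurofen",)),
    _Drug("aspirin", "DB00945", "B01AC06", ("antiplatelet",), ("Cartia",),
          (), ("acetylsalicylic acid",)),
    _Drug("amoxicillin", "DB01060", "J01CA04", ("antibiotic",), ("Amoxil",)),
    # substance-level-only entries: no AMT product, no DrugBank product link
    _Drug("clavulanic acid", "DB00766", None, (), (), (), (), True, False),
    _Drug("folic acid", "DB00158", None, (), (), (), (), True, False),
)

_INTERACTIONS = (("DB00945", "DB01050"), ("DB01104", "DB00843"))

_ATC_LEVEL_LABELS = {1: "anatomical main group", 3: "therapeutic subgroup",
                     4: "pharmacological subgroup", 5: "chemical subgroup"}


def generate_terminologies(seed: int = 0) -> TerminologySet:
    """Build the internally consistent mini-terminology set: AMT TP/MP/MS,
    ARTG brands, DrugBank entries (with an anti-diabetic category), the
    UNII list, a grammar-respecting ATC tree, and all cross-maps closed.

    The catalogue is curated and constant; ``seed`` is accepted for
    interface uniformity and the output does not depend on it.
    """
    del seed
    terms = TerminologySet()
    tp_counter = 3000
    artg_counter = 4000
    for i, drug in enumerate(_CATALOGUE):
        title = drug.ingredient.capitalize()
        if drug.in_unii:
            unii_code = f"U{i:09d}"
            terms.unii[unii_code] = drug.ingredient
        # AMT medicinal substance exists for every catalogue entry except
        # folic acid (UNII-only, exercises the UNII-without-MS branch)
        if drug.ingredient != "folic acid":
            ms_code = f"MS{1000 + i}"
            terms.amt_ms[ms_code] = drug.ingredient
            if drug.in_unii:
                terms.cross_maps.setdefault("amt_ms_unii", set()).add(
                    (ms_code, f"U{i:09d}"))
        if drug.in_amt:
            mp_code = f"MP{2000 + i}"
            terms.amt_mp[mp_code] = drug.ingredient
            terms.cross_maps.setdefault("amt_mp_drugbank", set()).add(
                (mp_code, drug.db_id))
            for j, brand in enumerate(drug.brands):
                tp_code = f"TP{tp_counter}"
                tp_counter += 1
                terms.amt_tp[tp_code] = brand
                artg_code = f"ARTG{artg_counter}"
                artg_counter += 1
                terms.artg_brands[artg_code] = brand
                terms.cross_maps.setdefault("amt_tp_artg", set()).add(
                    (tp_code, artg_code))
                terms.cross_maps.setdefault("amt_mp_artg", set()).add(
                    (mp_code, artg_code))
            for brand in drug.alias_brands:
                # registered brand without its own TP label: resolvable only
                # through the ARTG alias path, against the drug's first TP
                first_tp = next(c for c, b in terms.amt_tp.items()
                                if b == drug.brands[0])
                artg_code = f"ARTG{artg_counter}"
                artg_counter += 1
                terms.artg_brands[artg_code] = brand
                terms.cross_maps.setdefault("amt_tp_artg", set()).add(
                    (first_tp, artg_code))
                terms.cross_maps.setdefault("amt_mp_artg", set()).add(
                    (mp_code, artg_code))
        entry = DrugBankEntry(
            id=drug.db_id, name=title, synonyms=list(drug.synonyms),
            categories=list(drug.categories))
        terms.drugbank[drug.db_id] = entry
        if drug.atc:
            terms.atc[drug.atc] = f"{title} (ATC)"
            for n in (1, 3, 4, 5):
                terms.atc.setdefault(drug.atc[:n],
                                     f"{drug.atc[:n]} {_ATC_LEVEL_LABELS[n]}")
            terms.cross_maps.setdefault("drugbank_atc", set()).add(
                (drug.db_id, drug.atc))
    for a, b in _INTERACTIONS:
        terms.drugbank[a].interacts_with.append(b)
        terms.drugbank[b].interacts_with.append(a)
    validate_terminologies(terms)
    return terms


# --------------------------------------------------------------------------
# CDISC concept fixture (SKOS-like: IRI -> label)

CDISC_VS = "http://example.org/cdisc/vs#"
CDISC_LB = "http://example.org/cdisc/lb#"
CDISC_CM = "http://example.org/cdisc/cm#"
CDISC_DM = "http://example.org/cdisc/dm#"


def generate_cdisc_fixture() -> dict[str, str]:
    """Exemplar standard properties for the VS/LB/CM/DM domains."""
    return {
        CDISC_VS + "systolicBloodPressure": "Systolic Blood Pressure",
        CDISC_VS + "diastolicBloodPressure": "Diastolic Blood Pressure",
        CDISC_VS + "heartRate": "Heart Rate",
        CDISC_LB + "triglycerides": "Triglycerides",
        CDISC_CM + "medicationName": "Concomitant Medication Name",
        CDISC_DM + "sex": "Sex",
    }


#: default couplings from study variable names to CDISC standard properties
DEFAULT_COUPLINGS = {
    "systolicbp": CDISC_VS + "systolicBloodPressure",
    "diastolicbp": CDISC_VS + "diastolicBloodPressure",
    "heartrate": CDISC_VS + "heartRate",
    "triglycerides": CDISC_LB + "triglycerides",
    "medicationname": CDISC_CM + "medicationName",
    "gender": CDISC_DM + "sex",
}


# --------------------------------------------------------------------------
# study generator

#: classification codelist: healthy (memory complainer / non memory
#: complainer), mild cognitive impairment, Alzheimer's disease
CLASS_CODES = {
    "HC-MC": "memoryComplainerHealthyControl",
    "HC-NMC": "nonMemoryComplainerHealthyControl",
    "MCI": "mciPatient",
    "AD": "adPatient",
}
HEALTHY_CODES = ("HC-MC", "HC-NMC")

#: form OID -> (theme, sub-theme); the study taxonomy at reduced scale
DEFAULT_THEME_MAP = {
    "F.vitalsigns": ("Clinical", "vitalsigns"),
    "F.blood": ("Clinical", "blood"),
    "F.medications": ("Clinical", "medications"),
    "F.neuropsych": ("Cognitive", "neuropsych"),
    "F.demographics": ("Lifestyle", "demographics"),
    "F.lifestyle": ("Lifestyle", "lifestyle"),
    "F.imaging": ("Imaging", "imaging"),
    "F.admin": ("Study", "admin"),
}

DEFAULT_SUBJECT_PROPS = ["gender"]

#: medication record kinds and their default mix
MED_KINDS = ("tp_exact", "artg_alias", "mp_exact", "db_synonym",
             "substance_only", "unmappable")
DEFAULT_MED_MIX = {"tp_exact": 0.30, "artg_alias": 0.15, "mp_exact": 0.25,
                   "db_synonym": 0.10, "substance_only": 0.10,
                   "unmappable": 0.10}


@dataclass
class StudyConfig:
    n_subjects: int = 200
    timepoints: tuple[str, ...] = ("baseline", "month18", "month36",
                                   "month54")
    missingness: float = 0.05
    hypertensive_fraction: float = 0.25
    transition_fraction: float = 0.20
    normal_trig_fraction: float = 0.60
    meds_per_subject: tuple[int, int] = (0, 3)
    med_mix: dict = field(default_factory=lambda: dict(DEFAULT_MED_MIX))
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.missingness, self.hypertensive_fraction,
                 self.transition_fraction, self.normal_trig_fraction)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.transition_fraction > 0 and len(self.timepoints) < 2:
            raise ValueError("transitions require at least two timepoints")
        if abs(sum(self.med_mix.values()) - 1) > 1e-9:
            raise ValueError("medication kind mix must sum to 1")
        if set(self.med_mix) - set(MED_KINDS):
            raise ValueError(f"unknown medication kinds: "
                             f"{set(self.med_mix) - set(MED_KINDS)}")


def _build_metadata() -> StudyMeta:
    meta = StudyMeta(study_oid="S.SYNTH")
    items = {
        "I.systolicBP": ("systolicBP", "integer", None),
        "I.diastolicBP": ("diastolicBP", "integer", None),
        "I.heartRate": ("heartRate", "integer", None),
        "I.triglycerides": ("triglycerides", "float", None),
        "I.cholesterol": ("cholesterol", "float", None),
        "I.medicationName": ("medicationName", "text", None),
        "I.classification": ("classification", "codelist", "CL.class"),
        "I.mmseScore": ("mmseScore", "integer", None),
        "I.gender": ("gender", "codelist", "CL.gender"),
        "I.yearOfBirth": ("yearOfBirth", "integer", None),
        "I.exerciseHours": ("exerciseHours", "float", None),
        "I.notesLifestyle": ("notes", "text", None),
        "I.hippocampalVolume": ("hippocampalVolume", "float", None),
        "I.notesImaging": ("notes", "text", None),  # planted duplicate name
        "I.siteId": ("siteId", "text", None),
    }
    meta.codelists["CL.class"] = dict(CLASS_CODES)
    meta.codelists["CL.gender"] = {"M": "Male", "F": "Female"}
    for oid, (name, datatype, cl) in items.items():
        meta.item_defs[oid] = ItemDef(oid=oid, name=name, datatype=datatype,
                                      codelist_oid=cl)
    groups = {
        "IG.vitalsigns": ["I.systolicBP", "I.diastolicBP", "I.heartRate"],
        "IG.blood": ["I.triglycerides", "I.cholesterol"],
        "IG.medications": ["I.medicationName"],
        "IG.neuropsych": ["I.classification", "I.mmseScore"],
        "IG.demographics": ["I.gender", "I.yearOfBirth"],
        "IG.lifestyle": ["I.exerciseHours", "I.notesLifestyle"],
        "IG.imaging": ["I.hippocampalVolume", "I.notesImaging"],
        "IG.admin": ["I.siteId"],
    }
    for oid, item_oids in groups.items():
        meta.itemgroup_defs[oid] = ItemGroupDef(
            oid=oid, name=oid.split(".", 1)[1], item_oids=list(item_oids))
    for form_oid in DEFAULT_THEME_MAP:
        name = form_oid.split(".", 1)[1]
        meta.form_defs[form_oid] = FormDef(
            oid=form_oid, name=name, itemgroup_oids=[f"IG.{name}"])
    return meta


#: forms administered at every visit vs baseline only
_EVERY_VISIT_FORMS = ("F.vitalsigns", "F.blood", "F.neuropsych",
                      "F.lifestyle", "F.imaging")
_BASELINE_FORMS = ("F.demographics", "F.medications", "F.admin")

#: variables eligible for missingness (the planted-signal variables —
#: blood pressure, triglycerides, classification, gender, medications —
#: are always present so ground-truth answers stay exact)
_MISSABLE_ITEMS = ("I.heartRate", "I.cholesterol", "I.mmseScore",
                   "I.exerciseHours", "I.notesLifestyle",
                   "I.hippocampalVolume", "I.notesImaging")


def _corrupt(rng: random.Random, name: str) -> str:
    """Apply the reversible corruption model: token case shuffling, dosage
    suffixes, extra whitespace, parenthetical asides."""
    text = name
    style = rng.choice(("upper", "title", "lower", "asis"))
    if style == "upper":
        text = text.upper()
    elif style == "title":
        text = text.title()
    elif style == "lower":
        text = text.lower()
    if rng.random() < 0.5:
        text += rng.choice((" 500mg", " 50 mg", " 10mg", " 1 tablet",
                            " 2 tablets", " 5 ml"))
    if rng.random() < 0.3:
        text += rng.choice((" (morning)", " (at night)", " (prn)"))
    if rng.random() < 0.3:
        text = text.replace(" ", "  ", 1)
    return text


@dataclass
class _MedPlan:
    record_id: str
    subject: str
    event: str
    raw_name: str
    canonical: str
    kind: str
    expected: dict


def _plan_medication(rng: random.Random, terms: TerminologySet,
                     record_id: str, subject: str, event: str,
                     mix: dict[str, float]) -> _MedPlan:
    kinds = sorted(mix)
    kind = rng.choices(kinds, weights=[mix[k] for k in kinds])[0]
    tp_by_label = {v: k for k, v in terms.amt_tp.items()}
    mp_by_label = {v: k for k, v in terms.amt_mp.items()}
    expected: dict = {"tp": None, "tp_method": None, "mp": None,
                      "mp_method": None, "substance": None,
                      "substance_scheme": None, "drugbank": None,
                      "atc": []}

    def product_drugs():
        return [d for d in _CATALOGUE if d.in_amt]

    if kind == "tp_exact":
        drug = rng.choice(product_drugs())
        canonical = drug.brands[0].casefold()
        expected.update(tp=tp_by_label[drug.brands[0]], tp_method="exact")
    elif kind == "artg_alias":
        candidates = [d for d in _CATALOGUE if d.alias_brands]
        drug = rng.choice(candidates)
        brand = rng.choice(drug.alias_brands)
        canonical = brand.casefold()
        first_tp = tp_by_label[drug.brands[0]]
        expected.update(tp=first_tp, tp_method="synonym")
    elif kind == "mp_exact":
        drug = rng.choice(product_drugs())
        canonical = drug.ingredient
        mp_code = mp_by_label[drug.ingredient]
        unii = {v: k for k, v in terms.unii.items()}.get(drug.ingredient)
        expected.update(
            mp=mp_code, mp_method="exact",
            substance=unii, substance_scheme="unii" if unii else None,
            drugbank=drug.db_id, atc=[drug.atc] if drug.atc else [])
    elif kind == "db_synonym":
        candidates = [d for d in _CATALOGUE if d.synonyms and d.in_amt]
        drug = rng.choice(candidates)
        canonical = rng.choice(drug.synonyms).casefold()
        expected.update(
            mp=mp_by_label[drug.ingredient], mp_method="synonym",
            drugbank=drug.db_id, atc=[drug.atc] if drug.atc else [])
    elif kind == "substance_only":
        choice = rng.choice(("combo", "folic acid"))
        if choice == "combo":
            # multi-ingredient free text: neither product phase matches the
            # full string, but both ingredients resolve in UNII
            canonical = "amoxicillin + clavulanic acid"
            unii = {v: k for k, v in terms.unii.items()}["amoxicillin"]
            expected.update(substance=unii, substance_scheme="unii")
        else:
            canonical = "folic acid"
            unii = {v: k for k, v in terms.unii.items()}["folic acid"]
            expected.update(substance=unii, substance_scheme="unii")
    else:  # unmappable
        canonical = rng.choice(("multivitamin supplement", "herbal tonic",
                                "unknown white pill"))

    raw = _corrupt(rng, canonical)
    return _MedPlan(record_id, subject, event, raw, canonical, kind, expected)


def generate_study(config: StudyConfig) -> tuple[str, dict]:
    """Generate one synthetic ODM study export and its ground-truth
    manifest.

    The manifest contains per-subject planted states (blood pressure,
    triglycerides, classification per timepoint, gender), per-medication
    planted terminology resolutions, element counts, and the record list —
    everything :func:`expected_answers` needs without touching the RDF
    pipeline.
    """
    config.validate()
    rng = random.Random(config.seed)
    meta = _build_metadata()
    doc = ODMDocument(studies=[meta])

    n = config.n_subjects
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    n_hyp = round(config.hypertensive_fraction * n)
    n_trans = round(config.transition_fraction * n)
    n_normal_trig = round(config.normal_trig_fraction * n)

    hypertensive = set(subject_ids[:n_hyp])
    shuffled = list(subject_ids)
    rng.shuffle(shuffled)
    transition = set(shuffled[:n_trans])
    trig_order = list(subject_ids)
    rng.shuffle(trig_order)
    normal_trig = set(trig_order[:n_normal_trig])

    subjects_truth: dict[str, dict] = {}
    med_plans: list[_MedPlan] = []
    n_item_data = 0
    n_non_missing = 0
    theme_counts: dict[str, int] = {}

    meta.event_defs = {
        f"SE.{tp}": EventDef(oid=f"SE.{tp}", name=tp,
                             form_oids=list(DEFAULT_THEME_MAP))
        for tp in config.timepoints
    }

    for subj_id in subject_ids:
        truth: dict = {"gender": rng.choice(("M", "F")),
                       "hypertensive": subj_id in hypertensive,
                       "normal_trig": subj_id in normal_trig,
                       "bp": {}, "trig": {}, "classification": {}}
        if subj_id in transition:
            base_class = rng.choice(HEALTHY_CODES)
            classes = {tp: ("MCI" if i >= 1 else base_class)
                       for i, tp in enumerate(config.timepoints)}
        else:
            stable = rng.choices(("healthy", "MCI", "AD"),
                                 weights=(0.6, 0.25, 0.15))[0]
            code = (rng.choice(HEALTHY_CODES) if stable == "healthy"
                    else stable)
            classes = {tp: code for tp in config.timepoints}
        truth["classification"] = classes

        subject = SubjectData(subject_key=subj_id)
        for tp in config.timepoints:
            if truth["hypertensive"]:
                sys_bp = rng.randint(142, 180)
                dia_bp = rng.randint(92, 110)
            else:
                sys_bp = rng.randint(100, 138)
                dia_bp = rng.randint(70, 88)
            trig = (round(rng.uniform(0.9, 1.6), 2) if truth["normal_trig"]
                    else round(rng.uniform(1.8, 3.2), 2))
            truth["bp"][tp] = [sys_bp, dia_bp]
            truth["trig"][tp] = trig

            event = StudyEventData(event_oid=f"SE.{tp}")
            forms = _EVERY_VISIT_FORMS + (
                _BASELINE_FORMS if tp == config.timepoints[0] else ())
            values = {
                "I.systolicBP": str(sys_bp),
                "I.diastolicBP": str(dia_bp),
                "I.heartRate": str(rng.randint(55, 95)),
                "I.triglycerides": str(trig),
                "I.cholesterol": str(round(rng.uniform(3.5, 7.5), 2)),
                "I.classification": classes[tp],
                "I.mmseScore": str(rng.randint(18, 30)),
                "I.gender": truth["gender"],
                "I.yearOfBirth": str(rng.randint(1925, 1955)),
                "I.exerciseHours": str(round(rng.uniform(0, 14), 1)),
                "I.notesLifestyle": rng.choice(("walks daily", "sedentary",
                                                "swims", "gardens")),
                "I.hippocampalVolume": str(round(rng.uniform(2.4, 4.4), 2)),
                "I.notesImaging": rng.choice(("scan ok", "minor artefact",
                                              "repeat scan")),
                "I.siteId": rng.choice(("Melbourne", "Perth")),
            }
            for form_oid in forms:
                form = FormData(form_oid=form_oid)
                ig_oid = f"IG.{form_oid.split('.', 1)[1]}"
                if form_oid == "F.medications":
                    n_meds = rng.randint(*config.meds_per_subject)
                    for k in range(1, n_meds + 1):
                        record_id = f"{subj_id}.{tp}.med{k}"
                        plan = _plan_medication(rng, _TERMS_SINGLETON,
                                                record_id, subj_id, tp,
                                                config.med_mix)
                        med_plans.append(plan)
                        ig = ItemGroupData(itemgroup_oid=ig_oid,
                                           repeat_key=str(k))
                        ig.items.append(ItemData("I.medicationName",
                                                 plan.raw_name))
                        form.itemgroups.append(ig)
                        n_item_data += 1
                        n_non_missing += 1
                        theme = DEFAULT_THEME_MAP[form_oid][0]
                        theme_counts[theme] = theme_counts.get(theme, 0) + 1
                    if n_meds:
                        event.forms.append(form)
                    continue
                ig = ItemGroupData(itemgroup_oid=ig_oid)
                for item_oid in meta.itemgroup_defs[ig_oid].item_oids:
                    value = values[item_oid]
                    if (item_oid in _MISSABLE_ITEMS
                            and rng.random() < config.missingness):
                        value = ""
                    ig.items.append(ItemData(item_oid, value))
                    n_item_data += 1
                    if value != "":
                        n_non_missing += 1
                        theme = DEFAULT_THEME_MAP[form_oid][0]
                        theme_counts[theme] = theme_counts.get(theme, 0) + 1
                form.itemgroups.append(ig)
                event.forms.append(form)
            subject.events.append(event)
        doc.subjects.append(subject)
        subjects_truth[subj_id] = truth

    manifest = {
        "config": {**asdict(config),
                   "timepoints": list(config.timepoints),
                   "meds_per_subject": list(config.meds_per_subject)},
        "counts": {
            "n_subjects": n,
            "n_item_data": n_item_data,
            "n_non_missing": n_non_missing,
            "per_theme": dict(sorted(theme_counts.items())),
        },
        "subjects": subjects_truth,
        "medications": [
            {"record_id": p.record_id, "subject": p.subject,
             "event": p.event, "raw_name": p.raw_name,
             "canonical": p.canonical, "kind": p.kind,
             "expected": p.expected}
            for p in med_plans
        ],
    }
    return serialize_odm(doc), manifest


# one shared terminology set for medication planning (constant catalogue)
_TERMS_SINGLETON = generate_terminologies()


# --------------------------------------------------------------------------
# reference answers, by direct record scans independent of RDF

def expected_hypertension_count(manifest: dict,
                                thresholds: tuple[float, float] = (140, 90),
                                timepoint: str = "baseline") -> int:
    t1, t2 = thresholds
    return sum(
        1 for truth in manifest["subjects"].values()
        if timepoint in truth["bp"]
        and truth["bp"][timepoint][0] > t1 and truth["bp"][timepoint][1] > t2)


def expected_drug_class_counts(manifest: dict,
                               category: str = ANTI_DIABETIC,
                               terms: TerminologySet | None = None
                               ) -> list[tuple[int, str]]:
    """(count, product name) rows: distinct subjects whose medication record
    resolves (through an AMT-MP match) to a DrugBank drug in the category."""
    terms = terms or _TERMS_SINGLETON
    members = {db_id: e.name for db_id, e in terms.drugbank.items()
               if category in e.categories}
    per_drug: dict[str, set[str]] = {}
    for med in manifest["medications"]:
        db_id = med["expected"]["drugbank"]
        # only product-level matches carry the study-record -> DrugBank link
        if db_id in members and med["expected"]["mp"] is not None:
            per_drug.setdefault(db_id, set()).add(med["subject"])
    return sorted(((len(subjects), members[db_id])
                   for db_id, subjects in per_drug.items()),
                  key=lambda row: row[1])


def expected_transition_counts(manifest: dict,
                               from_states=HEALTHY_CODES,
                               to_states=("MCI",),
                               upper_bound: float = 1.7,
                               timepoints: tuple[str, str] = ("baseline",
                                                              "month18"),
                               ) -> dict[tuple[str, str], int]:
    tp1, tp2 = timepoints
    out: dict[tuple[str, str], int] = {}
    for truth in manifest["subjects"].values():
        c1 = truth["classification"].get(tp1)
        c2 = truth["classification"].get(tp2)
        if (c1 in from_states and c2 in to_states
                and truth["trig"].get(tp1, upper_bound) < upper_bound
                and truth["trig"].get(tp2, upper_bound) < upper_bound):
            out[(c1, c2)] = out.get((c1, c2), 0) + 1
    return out


def expected_mapping_counts(manifest: dict) -> dict[str, int]:
    meds = manifest["medications"]
    tp = sum(m["expected"]["tp"] is not None for m in meds)
    mp = sum(m["expected"]["mp"] is not None for m in meds)
    sub = sum(m["expected"]["substance"] is not None for m in meds)
    any_ = sum(any((m["expected"]["tp"], m["expected"]["mp"],
                    m["expected"]["substance"])) for m in meds)
    return {"total": len(meds), "any": any_, "tp": tp, "mp": mp,
            "substance": sub}


def expected_answers(manifest: dict,
                     terms: TerminologySet | None = None) -> dict:
    """Reference outputs for the three query templates and the mapping
    report, computed by direct scans of the manifest."""
    return {
        "hypertension_count": expected_hypertension_count(manifest),
        "drug_class_counts": expected_drug_class_counts(manifest,
                                                        terms=terms),
        "transition_counts": expected_transition_counts(manifest),
        "mapping_counts": expected_mapping_counts(manifest),
    }
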