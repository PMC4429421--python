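"""Hand-built micro-graphs for direct rule-application query tests."""

from rdflib import Graph, Literal, RDF, URIRef, XSD

from lcdc.lcdc_model import LCDC, QB, UriScheme, mint_iri

_SCHEME = UriScheme()


def _obs(g: Graph, subj: str, tp: str, var_iri: str, value, key: str):
    obs = URIRef(f"urn:obs:{key}")
    g.add((obs, RDF.type, QB.Observation))
    g.add((obs, LCDC.variable, URIRef(var_iri)))
    g.add((obs, LCDC.subject, URIRef(f"urn:subj:{subj}")))
    g.add((obs, LCDC.timepoint, Literal(tp)))
    if isinstance(value, float):
        g.add((obs, LCDC.value, Literal(value, datatype=XSD.double)))
    elif isinstance(value, int):
        g.add((obs, LCDC.value, Literal(value, datatype=XSD.integer)))
    else:
        g.add((obs, LCDC.value, Literal(str(value))))


def tiny_bp_graph(readings):
    """One baseline systolic/diastolic pair per subject."""
    g = Graph()
    sysvar = mint_iri(_SCHEME, "variable", ["systolicbp"])
    diavar = mint_iri(_SCHEME, "variable", ["diastolicbp"])
    for i, (sys_bp, dia_bp) in enumerate(readings):
        _obs(g, f"P{i}", "baseline", sysvar, sys_bp, f"sys{i}")
        _obs(g, f"P{i}", "baseline", diavar, dia_bp, f"dia{i}")
    return g, sysvar, diavar


def tiny_transition_graph(rows):
    """rows: (subject, class at tp1, class at tp2, trig at tp1, trig at
    tp2)."""
    g = Graph()
    classvar = mint_iri(_SCHEME, "variable", ["classification"])
    quantvar = mint_iri(_SCHEME, "variable", ["triglycerides"])
    for subj, c1, c2, x1, x2 in rows:
        _obs(g, subj, "baseline", classvar, c1, f"c1{subj}")
        _obs(g, subj, "month18", classvar, c2, f"c2{subj}")
        _obs(g, subj, "baseline", quantvar, float(x1), f"x1{subj}")
        _obs(g, subj, "month18", quantvar, float(x2), f"x2{subj}")
    return g, classvar, quantvar
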