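"""Noun normalization: lowercasing plus rule-cascade singularization.

A deterministic, auditable alternative to a full lemmatizer: an irregular /
invariant form table (biased toward biomedical vocabulary, notably the Greek
and Latin plurals) followed by ordered suffix rules with guards so that
singular forms like "virus", "analysis", "class" or "gas" pass through
unchanged.  The cascade is idempotent.
"""

from __future__ import annotations

__all__ = ["normalize_noun", "IRREGULAR_FORMS"]

# plural -> singular, plus invariant forms mapped to themselves so the
# suffix rules never touch them
IRREGULAR_FORMS: dict[str, str] = {
    # Greek/Latin -ses -> -sis
    "analyses": "analysis",
    "diagnoses": "diagnosis",
    "prognoses": "prognosis",
    "hypotheses": "hypothesis",
    "syntheses": "synthesis",
    "metastases": "metastasis",
    "prostheses": "prosthesis",
    "anastomoses": "anastomosis",
    "stenoses": "stenosis",
    "thromboses": "thrombosis",
    "fibroses": "fibrosis",
    "scleroses": "sclerosis",
    "neuroses": "neurosis",
    "psychoses": "psychosis",
    "apoptoses": "apoptosis",
    "mitoses": "mitosis",
    "meioses": "meiosis",
    "bases": "basis",
    "crises": "crisis",
    "axes": "axis",
    "testes": "testis",
    # Latin -a / -i / -ae
    "bacteria": "bacterium",
    "mitochondria": "mitochondrion",
    "criteria": "criterion",
    "phenomena": "phenomenon",
    "genera": "genus",
    "corpora": "corpus",
    "ova": "ovum",
    "sera": "serum",
    "media": "medium",
    "data": "datum",
    "fungi": "fungus",
    "nuclei": "nucleus",
    "stimuli": "stimulus",
    "foci": "focus",
    "loci": "locus",
    "bacilli": "bacillus",
    "radii": "radius",
    "vertebrae": "vertebra",
    "larvae": "larva",
    "algae": "alga",
    "sequelae": "sequela",
    "aortae": "aorta",
    # Latin -us plurals in -uses (the bare -uses suffix rule would clip
    # house/abuse/excuse-type nouns, so these are table entries)
    "viruses": "virus",
    "fetuses": "fetus",
    "statuses": "status",
    "sinuses": "sinus",
    "uteruses": "uterus",
    "boluses": "bolus",
    "thymuses": "thymus",
    "calluses": "callus",
    "censuses": "census",
    # -che/-she nouns the -es rule would clip
    "aches": "ache",
    "headaches": "headache",
    "niches": "niche",
    "caches": "cache",
    # Germanic irregulars
    "men": "man",
    "women": "woman",
    "children": "child",
    "teeth": "tooth",
    "feet": "foot",
    "mice": "mouse",
    "lice": "louse",
    # invariant singulars that end in s
    "species": "species",
    "series": "series",
    "feces": "feces",
    "diabetes": "diabetes",
    "herpes": "herpes",
    "rabies": "rabies",
    "scabies": "scabies",
    "measles": "measles",
    "caries": "caries",
    "aids": "aids",
    "gas": "gas",
    "lens": "lens",
    "bias": "bias",
    "atlas": "atlas",
    "pancreas": "pancreas",
}

_ES_STRIP_SUFFIXES = ("xes", "ches", "shes", "sses", "zzes")


def normalize_noun(surface: str) -> str:
    """Lowercase and singularize a noun token.

    Unknown forms pass through lowercased; the function is idempotent.
    """
    word = surface.lower()
    if word in IRREGULAR_FORMS:
        return IRREGULAR_FORMS[word]
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(_ES_STRIP_SUFFIXES) and len(word) > 4:
        return word[:-2]
    if (
        word.endswith("s")
        and len(word) > 3
        and not word.endswith(("ss", "us", "is"))
    ):
        return word[:-1]
    return word
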