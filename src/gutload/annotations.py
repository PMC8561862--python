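"""Curated oxygen-requirement and body-site annotations for duodenal genera.

The built-in table covers the genera that recur in quantitative
small-intestine surveys: the prevalent oral-derived community (streptococci,
Prevotella spp., Veillonella, fusobacteria, HACEK organisms, ...), the
gut-resident strict anaerobes, and the facultative "disruptor" group
(Enterobacteriaceae and relatives) that blooms in overgrowth.

``oxygen_class`` uses a closed vocabulary {strict_anaerobe,
facultative_anaerobe, aerobe, unknown}; genera outside the table default to
"unknown" and are excluded from anaerobe partitions.  ``site_flags`` mark
where a genus is commonly found (oral cavity and/or stool).
"""

from __future__ import annotations

from .datamodel import TaxonAnnotation

# genus, phylum, family, oxygen_class, site flags (O = oral, S = stool)
_BUILTIN = [
    # -- prevalent oral-derived genera -------------------------------------
    ("Streptococcus", "Firmicutes", "Streptococcaceae", "facultative_anaerobe", "OS"),
    ("Prevotella", "Bacteroidetes", "Prevotellaceae", "strict_anaerobe", "OS"),
    ("Prevotella 7", "Bacteroidetes", "Prevotellaceae", "strict_anaerobe", "OS"),
    ("Veillonella", "Firmicutes", "Veillonellaceae", "strict_anaerobe", "OS"),
    ("Haemophilus", "Proteobacteria", "Pasteurellaceae", "facultative_anaerobe", "OS"),
    ("Fusobacterium", "Fusobacteria", "Fusobacteriaceae", "strict_anaerobe", "O"),
    ("Neisseria", "Proteobacteria", "Neisseriaceae", "aerobe", "O"),
    ("Porphyromonas", "Bacteroidetes", "Porphyromonadaceae", "strict_anaerobe", "O"),
    ("Leptotrichia", "Fusobacteria", "Leptotrichiaceae", "strict_anaerobe", "O"),
    ("Campylobacter", "Proteobacteria", "Campylobacteraceae", "facultative_anaerobe", "O"),
    ("Actinomyces", "Actinobacteria", "Actinomycetaceae", "facultative_anaerobe", "O"),
    ("Rothia", "Actinobacteria", "Micrococcaceae", "facultative_anaerobe", "O"),
    ("Granulicatella", "Firmicutes", "Carnobacteriaceae", "facultative_anaerobe", "O"),
    ("Gemella", "Firmicutes", "Bacillales Family XI", "facultative_anaerobe", "O"),
    ("Alloprevotella", "Bacteroidetes", "Prevotellaceae", "strict_anaerobe", "O"),
    ("Oribacterium", "Firmicutes", "Lachnospiraceae", "strict_anaerobe", "O"),
    ("Stomatobaculum", "Firmicutes", "Lachnospiraceae", "strict_anaerobe", "O"),
    ("Solobacterium", "Firmicutes", "Erysipelotrichaceae", "strict_anaerobe", "O"),
    ("Atopobium", "Actinobacteria", "Atopobiaceae", "strict_anaerobe", "O"),
    ("Megasphaera", "Firmicutes", "Veillonellaceae", "strict_anaerobe", "O"),
    ("Selenomonas", "Firmicutes", "Selenomonadaceae", "strict_anaerobe", "O"),
    ("Capnocytophaga", "Bacteroidetes", "Flavobacteriaceae", "facultative_anaerobe", "O"),
    ("Lachnoanaerobaculum", "Firmicutes", "Lachnospiraceae", "strict_anaerobe", "O"),
    ("Butyrivibrio", "Firmicutes", "Lachnospiraceae", "strict_anaerobe", "O"),
    ("Catonella", "Firmicutes", "Lachnospiraceae", "strict_anaerobe", "O"),
    ("Peptostreptococcus", "Firmicutes", "Peptostreptococcaceae", "strict_anaerobe", "O"),
    ("Parvimonas", "Firmicutes", "Peptoniphilaceae", "strict_anaerobe", "O"),
    ("Mogibacterium", "Firmicutes", "Anaerovoracaceae", "strict_anaerobe", "O"),
    ("Eubacterium nodatum group", "Firmicutes", "Eubacteriaceae", "strict_anaerobe", "O"),
    ("Dialister", "Firmicutes", "Veillonellaceae", "strict_anaerobe", "O"),
    ("Tannerella", "Bacteroidetes", "Tannerellaceae", "strict_anaerobe", "O"),
    ("Treponema 2", "Spirochaetes", "Spirochaetaceae", "strict_anaerobe", "O"),
    ("Bergeyella", "Bacteroidetes", "Weeksellaceae", "aerobe", "O"),
    ("Lautropia", "Proteobacteria", "Burkholderiaceae", "aerobe", "O"),
    # HACEK organisms (with Haemophilus above)
    ("Cardiobacterium", "Proteobacteria", "Cardiobacteriaceae", "facultative_anaerobe", "O"),
    ("Aggregatibacter", "Proteobacteria", "Pasteurellaceae", "facultative_anaerobe", "O"),
    ("Eikenella", "Proteobacteria", "Neisseriaceae", "facultative_anaerobe", "O"),
    ("Kingella", "Proteobacteria", "Neisseriaceae", "facultative_anaerobe", "O"),
    ("Corynebacterium", "Actinobacteria", "Corynebacteriaceae", "aerobe", "O"),
    ("Abiotrophia", "Firmicutes", "Aerococcaceae", "facultative_anaerobe", "O"),
    ("Moraxella", "Proteobacteria", "Moraxellaceae", "aerobe", "O"),
    ("Candidatus Saccharimonas", "Patescibacteria", "Saccharimonadaceae", "unknown", "O"),
    ("Pseudomonas", "Proteobacteria", "Pseudomonadaceae", "aerobe", "O"),
    ("Mycoplasma", "Tenericutes", "Mycoplasmataceae", "facultative_anaerobe", "O"),
    # -- gut-resident genera (absent from saliva) --------------------------
    ("Enterobacteriaceae", "Proteobacteria", "Enterobacteriaceae", "facultative_anaerobe", "S"),
    ("Escherichia-Shigella", "Proteobacteria", "Enterobacteriaceae", "facultative_anaerobe", "S"),
    ("Clostridium sensu stricto 1", "Firmicutes", "Clostridiaceae", "strict_anaerobe", "S"),
    ("Lactobacillus", "Firmicutes", "Lactobacillaceae", "facultative_anaerobe", "S"),
    ("Enterococcus", "Firmicutes", "Enterococcaceae", "facultative_anaerobe", "S"),
    ("Romboutsia", "Firmicutes", "Peptostreptococcaceae", "strict_anaerobe", "S"),
    ("Aeromonas", "Proteobacteria", "Aeromonadaceae", "facultative_anaerobe", "S"),
    ("Bacteroides", "Bacteroidetes", "Bacteroidaceae", "strict_anaerobe", "S"),
    ("Faecalibacterium", "Firmicutes", "Ruminococcaceae", "strict_anaerobe", "S"),
    ("Blautia", "Firmicutes", "Lachnospiraceae", "strict_anaerobe", "S"),
    ("Bifidobacterium", "Actinobacteria", "Bifidobacteriaceae", "strict_anaerobe", "S"),
    ("Ruminococcus", "Firmicutes", "Ruminococcaceae", "strict_anaerobe", "S"),
    ("Akkermansia", "Verrucomicrobia", "Akkermansiaceae", "strict_anaerobe", "S"),
    ("Roseburia", "Firmicutes", "Lachnospiraceae", "strict_anaerobe", "S"),
    ("Dorea", "Firmicutes", "Lachnospiraceae", "strict_anaerobe", "S"),
    ("Coprococcus", "Firmicutes", "Lachnospiraceae", "strict_anaerobe", "S"),
]

#: The eight mutually-exclusive bloom ("disruptor") genera of the first
#: taxonomic signature; Lactobacillus is excluded from the final disruptor
#: set by downstream analyses.
DISRUPTOR_SIGNATURE = (
    "Enterobacteriaceae",
    "Escherichia-Shigella",
    "Clostridium sensu stricto 1",
    "Lactobacillus",
    "Enterococcus",
    "Romboutsia",
    "Aeromonas",
    "Bacteroides",
)

DEFAULT_DISRUPTOR_EXCLUSIONS = ("Lactobacillus",)

#: Genera expected to grow on aerobic MacConkey plates / anaerobic blood agar,
#: used for culture-vs-sequencing concordance.
MACCONKEY_SUBSET = ("Escherichia-Shigella", "Enterobacteriaceae", "Enterococcus", "Aeromonas")
BLOOD_AGAR_SUBSET = ("Prevotella", "Streptococcus", "Fusobacterium", "Escherichia-Shigella")


def builtin_annotations() -> dict[str, TaxonAnnotation]:
    """Return the built-in genus -> TaxonAnnotation table."""
    table = {}
    for genus, phylum, family, oxygen, flags in _BUILTIN:
        table[genus] = TaxonAnnotation(
            taxon_id=genus,
            phylum=phylum,
            family=family,
            genus=genus,
            oxygen_class=oxygen,
            site_flags={{"O": "oral", "S": "stool"}[f] for f in flags},
        )
    return table


def annotate(taxon_ids, table: dict[str, TaxonAnnotation] | None = None) -> dict[str, TaxonAnnotation]:
    """Annotation for every requested taxon; unknowns get an 'unknown' row."""
    table = table if table is not None else builtin_annotations()
    out = {}
    for t in taxon_ids:
        out[t] = table.get(t, TaxonAnnotation(taxon_id=t, genus=t))
    return out


def oral_pool() -> list[str]:
    return [g for g, *_rest, flags in _BUILTIN if "O" in flags]


def gut_pool() -> list[str]:
    return [g for g, *_rest, flags in _BUILTIN if "O" not in flags]
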