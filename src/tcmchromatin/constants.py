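"""Controlled vocabularies shared across the pipeline.

The seven-grade cold-hot nature scale, the eleven-token flavor scale with
yin/yang polarity, and the fixed 18-attribute histone/DNA-modification
catalog (attribute code -> chromatin conformation) that every potency
vector is indexed by.
"""

from __future__ import annotations

# Seven-grade cold-hot scale: cold medicinals are yin (negative), hot are
# yang (positive).
NATURE_SCORES: dict[str, int] = {
    "cold": -3,
    "mild cold": -2,
    "cool": -1,
    "neutral": 0,
    "mild warm": 1,
    "warm": 2,
    "hot": 3,
}

# Flavor polarity: sweet/pungent/plain are yang (+), sour/bitter/salty are
# yin (-); a "mild" grade is exactly half the full grade.
FLAVOR_SCORES: dict[str, float] = {
    "sweet": 1.0,
    "mild sweet": 0.5,
    "pungent": 1.0,
    "mild pungent": 0.5,
    "plain": 1.0,
    "sour": -1.0,
    "mild sour": -0.5,
    "bitter": -1.0,
    "mild bitter": -0.5,
    "salty": -1.0,
    "mild salty": -0.5,
}

EUCHROMATIC = "euchromatic"
HETEROCHROMATIC = "heterochromatic"
AMBIVALENT = "ambivalent"

# Fixed attribute order used for every 18-column potency matrix.
# i-suffixed codes denote the reverse reaction (e.g. H3K4i = H3K4
# demethylation, H3S10i = H3S10 dephosphorylation).
ATTRIBUTE_CONFORMATION: dict[str, str] = {
    "DNMT": HETEROCHROMATIC,   # cytosine methylation
    "HAT": EUCHROMATIC,        # histone acetylation
    "HDAC": HETEROCHROMATIC,   # histone deacetylation
    "H3K4": EUCHROMATIC,
    "H3K36": EUCHROMATIC,
    "H3K79": EUCHROMATIC,
    "H3R17": EUCHROMATIC,
    "H3K9": HETEROCHROMATIC,
    "H3K27": HETEROCHROMATIC,
    "H4K20": HETEROCHROMATIC,
    "H3K4i": HETEROCHROMATIC,
    "H3K36i": HETEROCHROMATIC,
    "H3R2i": HETEROCHROMATIC,
    "H4R3i": HETEROCHROMATIC,
    "H3K27i": EUCHROMATIC,
    "H3S10": EUCHROMATIC,      # phosphorylation
    "H3S10i": HETEROCHROMATIC, # dephosphorylation
    "ATP": AMBIVALENT,         # ATP-dependent remodeling: hetero- or euchromatic
}

ATTRIBUTE_ORDER: tuple[str, ...] = tuple(ATTRIBUTE_CONFORMATION)

CONFORMATIONS = frozenset({EUCHROMATIC, HETEROCHROMATIC, AMBIVALENT})

# Chemistry classes used for per-class heterochromatinization tallies:
# me = DNA/histone (de)methylation, ph = (de)phosphorylation,
# ac = (de)acetylation.  The ambivalent ATP attribute belongs to none.
CHEMISTRY_CLASSES: dict[str, tuple[str, ...]] = {
    "me": (
        "DNMT", "H3K4", "H3K36", "H3K79", "H3R17", "H3K9", "H3K27",
        "H4K20", "H3K4i", "H3K36i", "H3R2i", "H4R3i", "H3K27i",
    ),
    "ph": ("H3S10", "H3S10i"),
    "ac": ("HAT", "HDAC"),
    "all": tuple(c for c, conf in ATTRIBUTE_CONFORMATION.items() if conf != AMBIVALENT),
}

ACTIONS = ("activation", "inhibition", "unspecified")

CHROMATIN_LABELS = ("condensing", "unpacking", "poising", "non_modifying")
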