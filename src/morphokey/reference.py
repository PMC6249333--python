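"""Published reference data for the *Pteromalus* key.

The printed taxon list (47 Central European species, 29 of them in the
*P. albipennis* species group), the published best-ratio thresholds
separating *P. capito* from its closest relatives, and the type-series
ratio ranges printed in the *P. capito* description.  These are the
self-contained fixtures the package can be exercised against without
the deposited raw measurement files.
"""

from __future__ import annotations

from morphokey.key_engine import (
    UNKNOWN,
    Descriptor,
    KeyMatrix,
    TaxonDescription,
)

ALBIPENNIS_GROUP_TAG = "albipennis-group"

#: The 29 species of the *P. albipennis* species group included in the key.
ALBIPENNIS_GROUP_SPECIES: tuple[str, ...] = (
    "Pteromalus aartseni",
    "Pteromalus achillei",
    "Pteromalus albipennis",
    "Pteromalus ametrus",
    "Pteromalus berylli",
    "Pteromalus brachygaster",
    "Pteromalus capito",
    "Pteromalus cardui",
    "Pteromalus caudiger",
    "Pteromalus conformis",
    "Pteromalus costulata",
    "Pteromalus cingulipes",
    "Pteromalus elevatus",
    "Pteromalus eudecipiens",
    "Pteromalus inclytus",
    "Pteromalus integer",
    "Pteromalus intermedius",
    "Pteromalus lactucae",
    "Pteromalus musaeus",
    "Pteromalus myopitae",
    "Pteromalus parietinae",
    "Pteromalus patro",
    "Pteromalus pilosellae",
    "Pteromalus scandiae",
    "Pteromalus solidaginis",
    "Pteromalus speculifer",
    "Pteromalus temporalis",
    "Pteromalus tibiellus",
    "Pteromalus tripolii",
)

#: The 18 other *Pteromalus* species included for comparison.
OTHER_PTEROMALUS_SPECIES: tuple[str, ...] = (
    "Pteromalus altus",
    "Pteromalus bedeguaris",
    "Pteromalus bifoveolatus",
    "Pteromalus briani",
    "Pteromalus chlorospilus",
    "Pteromalus chrysos",
    "Pteromalus crassinervis",
    "Pteromalus cyniphidis",
    "Pteromalus elatus",
    "Pteromalus hieracii",
    "Pteromalus janstai",
    "Pteromalus ochrocerus",
    "Pteromalus platyphilus",
    "Pteromalus puparum",
    "Pteromalus semotus",
    "Pteromalus sequester",
    "Pteromalus vibulenus",
    "Pteromalus vopiscus",
)

#: Published best-ratio separations of *P. capito*: the discriminating
#: ratio, the bound, and which side *P. capito* lies on.
BEST_RATIO_FACTS = (
    {
        "comparison": ("capito", "albipennis+cingulipes"),
        "numerator": "eye.d",
        "denominator": "pol.l",
        "bound": 2.73,
        "capito_side": "high",
    },
    {
        "comparison": ("capito", "albipennis"),
        "numerator": "ant.l",
        "denominator": "ool.l",
        "bound": 5.85,
        "capito_side": "low",
    },
)

#: Ratio (and two size) ranges from the *P. capito* type-series description.
CAPITO_DESCRIPTION_RANGES: dict[str, tuple[float, float]] = {
    "body.l_mm": (2.8, 4.0),
    "msc.b_um": (635.0, 1002.0),
    "hea.b/hea.h": (1.30, 1.45),
    "hea.b/hea.l": (1.89, 2.25),
    "hea.b/msc.b": (1.02, 1.15),
    "upf.l/hea.h": (0.56, 0.61),
    "pol.l/ool.l": (1.26, 1.52),
    "eye.h/eye.b": (1.34, 1.52),
    "eye.d/eye.h": (1.38, 1.52),
    "tmp.l/eye.h": (0.21, 0.42),
    "msp.l/eye.h": (0.46, 0.54),
    "ant.l/hea.b": (0.86, 0.94),
    "scp.l/eye.h": (0.72, 0.80),
    "pdl.l/pdl.b": (1.33, 1.94),
    "mss.l/msc.b": (1.28, 1.50),
    "msc.b/msc.l": (1.43, 1.87),
    "msc.l/sct.l": (1.05, 1.28),
    "ppd.l/sct.l": (0.29, 0.42),
    "plc.d/ppd.l": (1.90, 3.05),
    "fwi.l/fwi.b": (2.15, 2.36),
    "mav.l/stv.l": (1.44, 1.80),
    "fm3.l/fm3.b": (3.46, 3.76),
    "gst.l/gst.b": (1.93, 2.39),
    "gst.l/mss.l": (1.43, 1.66),
}

# Qualitative states from the diagnoses of P. capito and the species it is
# most easily confused with.  Polymorphic taxa carry several states.
_QUALITATIVE = {
    "Pteromalus capito": {
        "paraspiracular inclination": {"blunt"},
        "metasternum pit": {"absent"},
        "metasternum fissure": {"present"},
    },
    "Pteromalus achillei": {
        "paraspiracular inclination": {"sharp", "blunt"},
        "metasternum pit": {"present", "absent"},
        "metasternum fissure": {"absent"},
    },
    "Pteromalus albipennis": {
        "paraspiracular inclination": {"sharp"},
        "metasternum pit": {"present"},
        "metasternum fissure": {"present", "absent"},
    },
    "Pteromalus caudiger": {
        "paraspiracular inclination": {"sharp"},
        "metasternum pit": {"present"},
        "metasternum fissure": {"absent"},
    },
    "Pteromalus cingulipes": {
        "paraspiracular inclination": {"sharp"},
        "metasternum pit": {"present", "absent"},
        "metasternum fissure": {"absent"},
    },
    "Pteromalus eudecipiens": {
        "paraspiracular inclination": {"sharp"},
        "metasternum pit": {"present"},
        "metasternum fissure": {"present", "absent"},
    },
    "Pteromalus intermedius": {
        "paraspiracular inclination": {"blunt"},
        "metasternum pit": {"absent"},
        "metasternum fissure": {"present"},
    },
    "Pteromalus patro": {
        "paraspiracular inclination": {"sharp"},
        "metasternum pit": {"present"},
        "metasternum fissure": {"absent"},
    },
    "Pteromalus temporalis": {
        "paraspiracular inclination": {"blunt"},
        "metasternum pit": {"absent"},
        "metasternum fissure": {"absent"},
    },
}

# Published quantitative cells: the two discriminating ratios.  Only
# one-sided bounds (2.73 / 5.85) are published; the opposite interval
# ends are synthetic plausible extremes.
_QUANTITATIVE = {
    "Pteromalus capito": {
        "eye.d/pol.l": (2.73, 3.50),
        "ant.l/ool.l": (4.50, 5.85),
    },
    "Pteromalus albipennis": {
        "eye.d/pol.l": (2.00, 2.73),
        "ant.l/ool.l": (5.85, 7.00),
    },
    "Pteromalus cingulipes": {
        "eye.d/pol.l": (2.00, 2.73),
    },
}


def pteromalus_key_matrix() -> KeyMatrix:
    """Key matrix over the 47 published taxa with a representative descriptor subset.

    Carries the qualitative characters (paraspiracular inclination and
    the two metasternum characters) and the two discriminating ratios
    for the taxa whose diagnoses state them; all other cells are
    unknown, exactly as a partly-described working database would look.
    The full published key (45+ descriptors, 585 images) is not
    transcribed.
    """
    descriptors = (
        Descriptor(
            name="paraspiracular inclination",
            kind="categorical",
            states=("sharp", "blunt"),
            weight=2,
        ),
        Descriptor(
            name="metasternum pit",
            kind="categorical",
            states=("present", "absent"),
            weight=3,
        ),
        Descriptor(
            name="metasternum fissure",
            kind="categorical",
            states=("present", "absent"),
            weight=3,
        ),
        Descriptor(
            name="eye.d/pol.l", kind="quantitative", unit="ratio", weight=5
        ),
        Descriptor(
            name="ant.l/ool.l", kind="quantitative", unit="ratio", weight=5
        ),
    )
    taxa = []
    for name in ALBIPENNIS_GROUP_SPECIES + OTHER_PTEROMALUS_SPECIES:
        desc: dict = {}
        for dname, states in _QUALITATIVE.get(name, {}).items():
            desc[dname] = frozenset(states)
        for dname, rng in _QUANTITATIVE.get(name, {}).items():
            desc[dname] = rng
        for d in descriptors:
            desc.setdefault(d.name, UNKNOWN)
        tags = (
            (ALBIPENNIS_GROUP_TAG,)
            if name in ALBIPENNIS_GROUP_SPECIES
            else ()
        )
        taxa.append(TaxonDescription(name=name, description=desc, tags=tags))
    return KeyMatrix(descriptors=descriptors, taxa=tuple(taxa))
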