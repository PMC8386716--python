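"""Gene-name classification and product strings for animal mitogenomes.

Names follow the compact nomenclature of Boore and Brown used by most
recent GenBank mitogenome annotations: thirteen protein-coding genes
(atp6 ... nad6), rrnL/16S and rrnS/12S for the ribosomal RNAs, single
amino-acid letters for tRNAs with L1/L2 and S1/S2 distinguishing the two
leucine and serine isoacceptors by codon family, and control_region/CR
(CR1, CR2) for the control region.  Anything else is annotated as a
miscellaneous feature.

Matching is case-sensitive exactly as listed, so near-misses such as
``Nad4l`` are not silently accepted; a "did you mean" hint is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger("mitotbl")

CDS_NAMES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

CDS_PRODUCTS: dict[str, str] = {
    "atp6": "ATP synthase F0 subunit 6",
    "atp8": "ATP synthase F0 subunit 8",
    "cob": "cytochrome b",
    "cox1": "cytochrome c oxidase subunit I",
    "cox2": "cytochrome c oxidase subunit II",
    "cox3": "cytochrome c oxidase subunit III",
    "nad1": "NADH dehydrogenase subunit 1",
    "nad2": "NADH dehydrogenase subunit 2",
    "nad3": "NADH dehydrogenase subunit 3",
    "nad4": "NADH dehydrogenase subunit 4",
    "nad4L": "NADH dehydrogenase subunit 4L",
    "nad5": "NADH dehydrogenase subunit 5",
    "nad6": "NADH dehydrogenase subunit 6",
}

RRNA_PRODUCTS: dict[str, str] = {
    "rrnL": "16S ribosomal RNA",
    "16S": "16S ribosomal RNA",
    "rrnS": "12S ribosomal RNA",
    "12S": "12S ribosomal RNA",
}

CONTROL_REGION_NAMES = ("control_region", "CR", "CR1", "CR2")

AA3: dict[str, str] = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}

# Leucine/serine isoacceptors, distinguished by the codon family they read.
TRNA_FAMILIES: dict[str, tuple[str, str]] = {
    "L1": ("L", "CUN"),
    "L2": ("L", "UUR"),
    "S1": ("S", "AGN"),
    "S2": ("S", "UCN"),
}

_KNOWN = set(CDS_NAMES) | set(RRNA_PRODUCTS) | set(AA3) | set(TRNA_FAMILIES) | set(
    CONTROL_REGION_NAMES
)


@dataclass(frozen=True)
class GeneIdentity:
    raw_name: str
    category: str  # CDS | tRNA | rRNA | control_region | misc
    product: str | None = None
    trna_letter: str | None = None
    trna_codon_family: str | None = None


def _suggest(name: str) -> str | None:
    folded = name.casefold()
    for known in sorted(_KNOWN):
        if known.casefold() == folded:
            return known
    return None


def classify(raw_name: str, products: dict[str, str] | None = None) -> GeneIdentity:
    """Map a curated gene name to its feature category and product string.

    *products* optionally overrides any default product string (keyed by raw
    name).  Unknown names degrade to the ``misc`` category with a logged
    warning; classification never fails.
    """
    if not raw_name or any(ch.isspace() for ch in raw_name):
        raise ValueError(f"invalid gene name {raw_name!r}")
    overrides = products or {}

    if raw_name in CDS_NAMES:
        product = overrides.get(raw_name, CDS_PRODUCTS[raw_name])
        return GeneIdentity(raw_name, "CDS", product)
    if raw_name in RRNA_PRODUCTS:
        product = overrides.get(raw_name, RRNA_PRODUCTS[raw_name])
        return GeneIdentity(raw_name, "rRNA", product)
    if raw_name in TRNA_FAMILIES:
        letter, family = TRNA_FAMILIES[raw_name]
        product = overrides.get(raw_name, f"tRNA-{AA3[letter]}")
        return GeneIdentity(raw_name, "tRNA", product, letter, family)
    if raw_name in AA3:
        product = overrides.get(raw_name, f"tRNA-{AA3[raw_name]}")
        return GeneIdentity(raw_name, "tRNA", product, raw_name)
    if raw_name in CONTROL_REGION_NAMES:
        return GeneIdentity(raw_name, "control_region")

    hint = _suggest(raw_name)
    if hint is not None:
        log.warning(
            "unknown gene name '%s' (did you mean '%s'?); annotating as "
            "miscellaneous feature", raw_name, hint,
        )
    else:
        log.warning(
            "unknown gene name '%s'; annotating as miscellaneous feature",
            raw_name,
        )
    return GeneIdentity(raw_name, "misc")


def product_string(identity: GeneIdentity) -> str | None:
    """Full product name for CDS/tRNA/rRNA identities; None otherwise."""
    if identity.category in ("CDS", "tRNA", "rRNA"):
        return identity.product
    return None


def load_product_config(text: str) -> dict[str, str]:
    """Parse a simple ``name=Product String`` per-line override file.

    Blank lines and ``#`` comments are ignored.
    """
    overrides: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'name=product'")
        key, value = line.split("=", 1)
        overrides[key.strip()] = value.strip()
    return overrides
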