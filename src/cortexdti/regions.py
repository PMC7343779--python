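"""Canonical cortical parcellation names and integer label codes.

The regional vocabulary is the 34 bilateral cortical areas of the
Desikan-Killiany atlas (68 regions over both hemispheres).  Label volumes
use integer codes: ``LABEL_WHITE`` for voxels inside the white surface,
``LABEL_PIAL`` for voxels outside the pial surface, 0 for everything else,
and per-region grey-matter codes from :func:`region_code`.
"""

from __future__ import annotations

LABEL_OTHER = 0
LABEL_WHITE = 1
LABEL_PIAL = 2

#: offset of the first left-hemisphere grey-matter code
_LEFT_BASE = 100
#: offset of the first right-hemisphere grey-matter code
_RIGHT_BASE = 200

#: the 34 bilateral Desikan-Killiany cortical areas
DK_AREAS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

HEMISPHERES = ("left", "right")


def canonical_region_names() -> list[str]:
    """All 68 region names, left hemisphere first, atlas order within."""
    return [f"{hemi}_{area}" for hemi in HEMISPHERES for area in DK_AREAS]


def region_code(name: str) -> int:
    """Integer grey-matter label code for a canonical region name."""
    hemi, _, area = name.partition("_")
    idx = DK_AREAS.index(area)
    base = _LEFT_BASE if hemi == "left" else _RIGHT_BASE
    if hemi not in HEMISPHERES:
        raise KeyError(name)
    return base + idx


def default_region_map() -> dict[int, str]:
    """Code -> name map covering all 68 canonical regions."""
    return {region_code(name): name for name in canonical_region_names()}
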