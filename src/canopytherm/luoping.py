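"""Published summary measurements of the Luoping County (Yunnan) urban
built-up area, 2020-2021 — the case study this pipeline reproduces.

These are inputs to the analysis (the original Landsat scene and the
object-based land-cover delineation are not redistributable); the 63-patch
metric table ships as the packaged CSV fixture loaded by
:func:`canopytherm.cli_io.load_patch_table`.
"""

from __future__ import annotations

from .raster import LandCover

#: total study area, hm^2
TOTAL_AREA_HM2 = 2897.7

#: planimetric area by land-cover class, hm^2 (sums to the total)
CLASS_AREAS_HM2 = {
    LandCover.IMPERVIOUS: 1615.71,
    LandCover.TREE_CANOPY: 731.37,
    LandCover.BARE_LAND: 480.79,
    LandCover.GRASSLAND: 57.48,
    LandCover.WATER: 12.35,
}

#: class-mean LST, deg C (impervious > bare > grass > canopy > water)
CLASS_MEAN_LST_C = {
    LandCover.IMPERVIOUS: 31.44,
    LandCover.BARE_LAND: 30.21,
    LandCover.GRASSLAND: 30.09,
    LandCover.TREE_CANOPY: 29.98,
    LandCover.WATER: 28.43,
}

#: scene LST range and mean, deg C
LST_MIN_C, LST_MAX_C, LST_MEAN_C = 24.73, 37.63, 30.83

#: natural-breaks temperature-level boundaries, deg C (5 levels)
LST_LEVEL_BREAKS_C = (28.32, 30.15, 31.56, 33.23)

#: canopy patch composition by size class: (count, total area hm^2)
PATCH_LEVELS = {
    "small": (492, 14.27),
    "medium": (579, 63.89),
    "large": (298, 122.68),
    "super_large": (48, 92.34),
    "extra_large": (15, 438.19),
}

#: total canopy patches and their summed area, hm^2
PATCH_TOTAL_COUNT, PATCH_TOTAL_AREA_HM2 = 1432, 731.37
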