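"""Zonal LST statistics, cooling rates and canopy-coverage arithmetic.

The cooling rate of a canopy patch is its mean-LST deficit relative to the
scene-wide bare-land mean, on the percent scale:

    cooling_rate = 100 * (LST_bare - LST_patch) / LST_bare

with temperatures in degrees Celsius. A single global bare-land baseline is
used (not a per-patch local one); negative rates mean the patch is warmer
than bare land. The ratio in Celsius is physically arbitrary but is the
convention of the source analyses this pipeline reproduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import LandCover, LandCoverMap, RasterGrid, congruent
from .patch_analysis import Patch

logger = logging.getLogger(__name__)

__all__ = [
    "zonal_mean_lst",
    "cooling_rate",
    "attach_patch_lst",
    "CoverageReport",
    "coverage_metrics",
]


def zonal_mean_lst(lst: RasterGrid, landcover: LandCoverMap) -> pd.DataFrame:
    """Per-class LST statistics: mean (deg C), cell count, area (hm^2) and
    share of total valid area (%). Classes with no cells are absent."""
    if lst.shape != landcover.shape:
        raise ValueError(
            f"grid shapes differ: {lst.shape} vs {landcover.shape}")
    valid = lst.valid & landcover.valid
    if not valid.any():
        raise ValueError("no overlap between valid LST and land-cover cells")
    labels = np.where(valid, landcover.grid, 0)
    total = int(valid.sum())
    rows = []
    for cls in LandCover:
        n = int(np.sum(labels == int(cls)))
        if n == 0:
            continue
        mean = float(ndimage.mean(lst.data, labels=labels, index=int(cls)))
        rows.append({"landcover": cls.name.lower(), "mean_lst_c": mean,
                     "cell_count": n,
                     "area_hm2": n * landcover.cell_area_m2 / 1e4,
                     "share_pct": 100.0 * n / total})
    return pd.DataFrame(rows).set_index("landcover")


def cooling_rate(patch_mean_lst, bare_mean_lst: float):
    """Cooling rate (%) of a patch mean LST against the bare-land baseline.

    Accepts a scalar or array of patch means; antitone in the patch mean.
    """
    if bare_mean_lst == 0:
        raise ValueError("bare-land mean LST baseline must be non-zero")
    patch = np.asarray(patch_mean_lst, dtype=float)
    out = 100.0 * (bare_mean_lst - patch) / bare_mean_lst
    return float(out) if out.ndim == 0 else out


def attach_patch_lst(patches: Sequence[Patch], lst: RasterGrid,
                     bare_mean_lst: float) -> None:
    """Fill each patch's mean LST (over its cell mask) and cooling rate.

    LST is sampled at the patch cells of the (congruent) LST grid; patches
    whose cells are all nodata keep ``mean_lst_c = None``.
    """
    for p in patches:
        r0, c0 = p.bbox
        h, w = p.mask.shape
        vals = lst.data[r0:r0 + h, c0:c0 + w][p.mask]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            logger.warning("patch %d has no valid LST cells", p.id)
            continue
        p.mean_lst_c = float(vals.mean())
        p.cooling_rate_pct = cooling_rate(p.mean_lst_c, bare_mean_lst)


@dataclass(frozen=True)
class CoverageReport:
    """Current and attainable canopy coverage of a study area.

    PUTC (possible urban tree canopy) is the bare land plus grassland area
    convertible to canopy; ``max_coverage_pct`` is current coverage plus the
    potential increase, an exact identity before any rounding.
    """

    total_area_hm2: float
    canopy_area_hm2: float
    canopy_coverage_pct: float
    putc_area_hm2: float
    potential_increase_pct: float
    max_coverage_pct: float


def coverage_metrics(class_areas_hm2: Mapping, total_area_hm2: float
                     ) -> CoverageReport:
    """Coverage arithmetic from per-class areas (hm^2) and the total area.

    ``class_areas_hm2`` maps :class:`LandCover` members (or their lower-case
    names) to areas. Percentages are unrounded; round at presentation.
    """
    if not total_area_hm2 > 0:
        raise ValueError("total area must be > 0")
    areas = {}
    for key, val in class_areas_hm2.items():
        cls = key if isinstance(key, LandCover) else LandCover[str(key).upper()]
        if val < 0:
            raise ValueError(f"negative area for {cls.name}")
        areas[cls] = float(val)
    if sum(areas.values()) > total_area_hm2 * (1 + 1e-9):
        raise ValueError("class areas exceed the total study area")
    canopy = areas.get(LandCover.TREE_CANOPY, 0.0)
    putc = areas.get(LandCover.BARE_LAND, 0.0) + \
        areas.get(LandCover.GRASSLAND, 0.0)
    coverage = 100.0 * canopy / total_area_hm2
    potential = 100.0 * putc / total_area_hm2
    return CoverageReport(
        total_area_hm2=float(total_area_hm2), canopy_area_hm2=canopy,
        canopy_coverage_pct=coverage, putc_area_hm2=putc,
        potential_increase_pct=potential,
        max_coverage_pct=coverage + potential)
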