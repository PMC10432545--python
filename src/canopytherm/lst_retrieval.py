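"""Single-channel LST retrieval with atmospheric correction, and
natural-breaks temperature classification.

The retrieval removes path radiance and transmittance from one thermal band,
corrects for surface emissivity, and inverts Planck's law:

    B(T_s) = (L_lambda - L_up - tau (1 - eps) L_down) / (tau eps)
    T_s    = K2 / ln(K1 / B(T_s) + 1)

with emissivity modelled linearly in the vegetation fraction P_V scaled from
NDVI between bare-soil and full-vegetation endpoints:

    eps = 0.004 P_V + 0.986,   P_V = (NDVI - NDVI_soil) / (NDVI_veg - NDVI_soil)

Default parameters are the Landsat 8 TIRS band-10 calibration constants and
the atmospheric profile of the Luoping County scene (2021-03-18).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid, congruent

logger = logging.getLogger(__name__)

KELVIN_OFFSET = 273.15

__all__ = [
    "AtmosphericProfile",
    "PlanckConstants",
    "EmissivityParams",
    "TemperatureLevels",
    "LEVEL_NAMES",
    "ndvi",
    "vegetation_fraction",
    "emissivity",
    "blackbody_radiance",
    "planck_radiance",
    "planck_invert",
    "retrieve_lst",
    "jenks_breaks",
    "jenks_breaks_sampled",
    "classify_lst",
]


@dataclass(frozen=True)
class AtmosphericProfile:
    """Single-channel atmospheric correction terms.

    tau: transmittance (unitless, 0 < tau <= 1); L_up / L_down: up- and
    downwelling path radiance in W/m^2/sr/um. Defaults are the NASA
    atmospheric-correction values for the Luoping scene.
    """

    tau: float = 0.91
    L_up: float = 0.75
    L_down: float = 1.29

    def __post_init__(self):
        if not 0 < self.tau <= 1:
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        if self.L_up < 0 or self.L_down < 0:
            raise ValueError("path radiances must be >= 0")


@dataclass(frozen=True)
class PlanckConstants:
    """Thermal-band calibration constants (defaults: Landsat 8 TIRS band 10)."""

    K1: float = 774.89   # W/m^2/sr/um
    K2: float = 1321.08  # kelvin

    def __post_init__(self):
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("K1 and K2 must be > 0")


@dataclass(frozen=True)
class EmissivityParams:
    """Linear emissivity model eps = slope * P_V + intercept, with NDVI
    endpoints for the vegetation-fraction scaling.

    The NDVI endpoints are not fixed by the retrieval method itself;
    defaults (0.05 / 0.70) follow common Landsat practice.
    """

    slope: float = 0.004
    intercept: float = 0.986
    ndvi_soil: float = 0.05
    ndvi_veg: float = 0.70

    def __post_init__(self):
        if not self.ndvi_soil < self.ndvi_veg:
            raise ValueError("ndvi_soil must be < ndvi_veg")
        for pv in (0.0, 1.0):
            eps = self.slope * pv + self.intercept
            if not 0 < eps <= 1:
                raise ValueError(f"emissivity {eps} out of (0, 1] at P_V={pv}")


def ndvi(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """Normalized difference vegetation index (nir - red)/(nir + red).

    Cells where nir + red == 0 become nodata; the count is logged.
    """
    congruent(red, nir)
    denom = nir.data + red.data
    zero = denom == 0
    if zero.any():
        logger.warning("ndvi: %d zero-sum cells set to nodata", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (nir.data - red.data) / denom
    out[zero] = np.nan
    return red.like(out)


def vegetation_fraction(ndvi_grid: RasterGrid,
                        params: EmissivityParams = EmissivityParams()) -> RasterGrid:
    """Vegetation fraction P_V scaled from NDVI, clipped to [0, 1]."""
    pv = (ndvi_grid.data - params.ndvi_soil) / (params.ndvi_veg - params.ndvi_soil)
    return ndvi_grid.like(np.clip(pv, 0.0, 1.0))


def emissivity(pv: RasterGrid,
               params: EmissivityParams = EmissivityParams()) -> RasterGrid:
    """Surface emissivity eps = slope * P_V + intercept."""
    return pv.like(params.slope * pv.data + params.intercept)


def blackbody_radiance(radiance: RasterGrid, epsilon: RasterGrid,
                       atmos: AtmosphericProfile = AtmosphericProfile()) -> RasterGrid:
    """Surface-leaving blackbody radiance B(T_s) after atmospheric correction.

    Cells where the corrected radiance is non-positive (observed radiance at
    or below the path radiance) become nodata; the count is logged.
    """
    congruent(radiance, epsilon)
    eps = epsilon.data
    if np.any(eps[~np.isnan(eps)] == 0):
        raise ValueError("emissivity must be non-zero everywhere")
    b = (radiance.data - atmos.L_up - atmos.tau * (1.0 - eps) * atmos.L_down) / (
        atmos.tau * eps)
    bad = b <= 0
    n_bad = int(np.nansum(bad))
    if n_bad:
        logger.warning("blackbody_radiance: %d non-physical cells (B <= 0) "
                       "set to nodata", n_bad)
        b = np.where(bad, np.nan, b)
    return radiance.like(b)


def planck_radiance(t_kelvin, planck: PlanckConstants = PlanckConstants()):
    """Band-effective Planck radiance B(T) = K1 / (exp(K2/T) - 1)."""
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t[~np.isnan(t)] <= 0):
        raise ValueError("temperature must be > 0 kelvin")
    return planck.K1 / np.expm1(planck.K2 / t)


def planck_invert(b: RasterGrid,
                  planck: PlanckConstants = PlanckConstants()) -> RasterGrid:
    """Invert Planck's law: T_s = K2 / ln(K1/B + 1), in kelvin.

    Non-positive B becomes nodata. Strictly increasing in B.
    """
    data = np.where(b.data > 0, b.data, np.nan)
    t = planck.K2 / np.log1p(planck.K1 / data)
    return b.like(t)


def retrieve_lst(radiance: RasterGrid, red: RasterGrid, nir: RasterGrid,
                 atmos: AtmosphericProfile = AtmosphericProfile(),
                 planck: PlanckConstants = PlanckConstants(),
                 emis_params: EmissivityParams = EmissivityParams()) -> RasterGrid:
    """Full retrieval chain: NDVI -> P_V -> emissivity -> atmospheric
    correction -> Planck inversion. Returns LST in degrees Celsius; nodata
    propagates through every stage."""
    congruent(radiance, red, nir)
    nd = ndvi(red, nir)
    pv = vegetation_fraction(nd, emis_params)
    eps = emissivity(pv, emis_params)
    b = blackbody_radiance(radiance, eps, atmos)
    t = planck_invert(b, planck)
    return t.like(t.data - KELVIN_OFFSET)


# ---------------------------------------------------------------------------
# natural-breaks (Fisher-Jenks) classification
# ---------------------------------------------------------------------------

LEVEL_NAMES = ("low", "mild_low", "medium", "sub_high", "high")


@dataclass(frozen=True)
class TemperatureLevels:
    """Interior breakpoints (ascending, degrees C) partitioning LST into
    k = len(breaks) + 1 ordered levels."""

    breaks: tuple

    def __post_init__(self):
        b = tuple(float(x) for x in self.breaks)
        object.__setattr__(self, "breaks", b)
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"breaks must be strictly ascending: {b}")

    @property
    def n_classes(self) -> int:
        return len(self.breaks) + 1


def jenks_breaks(values, k: int) -> TemperatureLevels:
    """Optimal 1-D classification by the exact Fisher-Jenks dynamic program.

    Finds the partition of the sorted values into ``k`` contiguous classes
    minimising the total within-class sum of squared deviations. Each interior
    break is the smallest member of the upper class, so classification with
    lower-closed intervals reproduces the optimal partition. Ties between
    equally good partitions are broken toward the smallest upper bound of the
    lower class.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if np.isnan(x).any():
        x = x[~np.isnan(x)]
    n = x.size
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if np.unique(x).size < k:
        raise ValueError(
            f"need at least {k} distinct values for {k} classes, "
            f"got {np.unique(x).size}")

    # prefix sums for O(1) within-class SSD of x[i:j]
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    # cost[m][i]: optimal SSD of partitioning x[:i] into m classes
    cost = np.full((k + 1, n + 1), np.inf)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    idx = np.arange(n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cost[1][1:] = (s2[1:] - s2[0]) - (s1[1:] - s1[0]) ** 2 / idx[1:]
    for m in range(2, k + 1):
        for i in range(m, n + 1):
            j = idx[m - 1:i]  # last class is x[j:i]
            ssd = (s2[i] - s2[j]) - (s1[i] - s1[j]) ** 2 / (i - j)
            c = cost[m - 1][j] + ssd
            best = int(np.argmin(c))  # first minimum: smallest j on ties
            cost[m][i] = c[best]
            cut[m][i] = j[best]

    # backtrack class start indices
    starts = []
    i = n
    for m in range(k, 1, -1):
        j = cut[m][i]
        starts.append(j)
        i = j
    starts.reverse()
    return TemperatureLevels(breaks=tuple(x[j] for j in starts))


def jenks_breaks_sampled(values, k: int, max_n: int = 6000,
                         seed: int = 0) -> TemperatureLevels:
    """Natural breaks for large value sets via a deterministic subsample.

    The exact dynamic program is quadratic in n; for rasters beyond ``max_n``
    valid cells the breaks are computed on a seeded random subsample of that
    size (the common practice for natural-breaks raster classification).
    Below the threshold this is exactly :func:`jenks_breaks`.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if x.size > max_n:
        logger.info("jenks: sampling %d of %d values", max_n, x.size)
        x = np.random.default_rng(seed).choice(x, size=max_n, replace=False)
    return jenks_breaks(x, k)


def within_class_ss(values, levels: TemperatureLevels) -> float:
    """Total within-class sum of squared deviations under a classification.

    Independent scoring helper; used to compare partitions.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[~np.isnan(x)]
    labels = np.digitize(x, levels.breaks)
    total = 0.0
    for lbl in np.unique(labels):
        grp = x[labels == lbl]
        total += float(np.sum((grp - grp.mean()) ** 2))
    return total


def classify_lst(lst: RasterGrid, levels: TemperatureLevels) -> np.ndarray:
    """Assign each LST cell to a temperature level.

    Intervals are lower-closed / upper-open, with the top class closed above;
    a cell exactly on a break goes to the upper class. Returns an int array of
    level indices (0 = lowest); nodata cells get -1.
    """
    out = np.digitize(lst.data, levels.breaks).astype(np.int8)
    out[~lst.valid] = -1
    return out
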