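"""Synthetic land-cover scenes with known ground truth.

Builds five-class mosaics (water, tree canopy, grassland, bare land,
impervious surface) with per-class LST and NDVI fields, then forward-models
thermal radiance through the same single-channel physics the retrieval
inverts:

    L_lambda = (eps * B(T_s) + (1 - eps) * L_down) * tau + L_up

so that every downstream stage — retrieval, patch extraction, zonal
statistics — can be tested against known truth without any satellite data.

Reflectance bands are synthesized as nir = 0.3 (1 + NDVI), red = 0.3 (1 - NDVI),
which yields the target NDVI exactly; only the NDVI ratio matters downstream.
LST noise is Gaussian and independent per cell (no spatial autocorrelation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .raster import LandCover, LandCoverMap, RasterGrid
from .lst_retrieval import (
    KELVIN_OFFSET,
    AtmosphericProfile,
    EmissivityParams,
    PlanckConstants,
    emissivity,
    planck_radiance,
    vegetation_fraction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Rect",
    "Disc",
    "SceneSpec",
    "SyntheticScene",
    "generate_scene",
    "forward_radiance",
    "demo_scene_spec",
    "LUOPING_CLASS_MEAN_LST",
    "DEFAULT_CLASS_NDVI",
]

#: per-class mean LST (deg C) observed over the Luoping County built-up area
LUOPING_CLASS_MEAN_LST: Mapping[LandCover, float] = {
    LandCover.IMPERVIOUS: 31.44,
    LandCover.BARE_LAND: 30.21,
    LandCover.GRASSLAND: 30.09,
    LandCover.TREE_CANOPY: 29.98,
    LandCover.WATER: 28.43,
}

#: plausible per-class NDVI means for an urban mosaic
DEFAULT_CLASS_NDVI: Mapping[LandCover, float] = {
    LandCover.WATER: -0.10,
    LandCover.TREE_CANOPY: 0.70,
    LandCover.GRASSLAND: 0.50,
    LandCover.BARE_LAND: 0.15,
    LandCover.IMPERVIOUS: 0.05,
}


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle: top-left cell (row, col) and size in cells."""

    cls: LandCover
    row: int
    col: int
    height: int
    width: int

    def paint(self, grid: np.ndarray) -> None:
        nr, nc = grid.shape
        if (self.row < 0 or self.col < 0 or self.height <= 0 or self.width <= 0
                or self.row + self.height > nr or self.col + self.width > nc):
            raise ValueError(
                f"rectangle {self.height}x{self.width} at "
                f"({self.row},{self.col}) exceeds the {nr}x{nc} grid")
        grid[self.row:self.row + self.height,
             self.col:self.col + self.width] = int(self.cls)


@dataclass(frozen=True)
class Disc:
    """Disc: centre cell (row, col) and radius in cells."""

    cls: LandCover
    row: int
    col: int
    radius: float

    def paint(self, grid: np.ndarray) -> None:
        nr, nc = grid.shape
        if self.radius <= 0:
            raise ValueError("disc radius must be > 0")
        if (self.row - self.radius < -0.5 or self.row + self.radius > nr - 0.5
                or self.col - self.radius < -0.5
                or self.col + self.radius > nc - 0.5):
            raise ValueError(
                f"disc r={self.radius} at ({self.row},{self.col}) exceeds "
                f"the {nr}x{nc} grid")
        rr, cc = np.ogrid[:nr, :nc]
        mask = (rr - self.row) ** 2 + (cc - self.col) ** 2 <= self.radius ** 2
        grid[mask] = int(self.cls)


@dataclass
class SceneSpec:
    """Recipe for a synthetic scene.

    Shapes are painted in order (later shapes overwrite earlier — painter's
    rule); unassigned cells take the background class. Per-class LST and NDVI
    are (mean, sd) pairs; NDVI draws are clipped to [-1, 1].
    """

    n_rows: int
    n_cols: int
    cell_size: float
    class_layout: Sequence
    per_class_lst: Mapping[LandCover, tuple]
    per_class_ndvi: Mapping[LandCover, tuple]
    background_class: LandCover = LandCover.IMPERVIOUS
    seed: int = 0

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        for name, mapping in (("per_class_lst", self.per_class_lst),
                              ("per_class_ndvi", self.per_class_ndvi)):
            for cls, (_, sd) in mapping.items():
                if sd < 0:
                    raise ValueError(f"{name}[{cls!r}] sd must be >= 0")

    def to_json(self) -> str:
        d = {
            "n_rows": self.n_rows, "n_cols": self.n_cols,
            "cell_size": self.cell_size,
            "background_class": self.background_class.name,
            "seed": self.seed,
            "class_layout": [
                {"kind": type(s).__name__.lower(), "cls": s.cls.name,
                 **{k: v for k, v in vars(s).items() if k != "cls"}}
                for s in self.class_layout],
            "per_class_lst": {c.name: list(v)
                              for c, v in self.per_class_lst.items()},
            "per_class_ndvi": {c.name: list(v)
                               for c, v in self.per_class_ndvi.items()},
        }
        return json.dumps(d, indent=2)


@dataclass
class SyntheticScene:
    """A generated scene: land cover, true LST, reflectances, radiance."""

    landcover: LandCoverMap
    lst_true: RasterGrid
    red: RasterGrid
    nir: RasterGrid
    radiance: RasterGrid
    spec: SceneSpec


def forward_radiance(lst_true: RasterGrid, emissivity_grid: RasterGrid,
                     atmos: AtmosphericProfile = AtmosphericProfile(),
                     planck: PlanckConstants = PlanckConstants()) -> RasterGrid:
    """Forward-model at-sensor thermal radiance from a surface LST field.

    ``lst_true`` is in degrees Celsius; temperatures are converted to kelvin
    internally. Radiance is in W/m^2/sr/um.
    """
    t_kelvin = lst_true.data + KELVIN_OFFSET
    if np.any(t_kelvin[~np.isnan(t_kelvin)] <= 0):
        raise ValueError("surface temperature must be > 0 kelvin")
    eps = emissivity_grid.data
    if np.any((eps <= 0) | (eps > 1)):
        raise ValueError("emissivity must lie in (0, 1]")
    b = planck_radiance(t_kelvin, planck)
    lam = (eps * b + (1.0 - eps) * atmos.L_down) * atmos.tau + atmos.L_up
    return lst_true.like(lam)


def generate_scene(spec: SceneSpec,
                   atmos: AtmosphericProfile = AtmosphericProfile(),
                   planck: PlanckConstants = PlanckConstants(),
                   emis_params: EmissivityParams = EmissivityParams()
                   ) -> SyntheticScene:
    """Generate a scene deterministically from ``spec`` (and its seed).

    The radiance band is forward-modelled with the emissivity implied by the
    scene's own NDVI through ``emis_params``, so retrieval with identical
    parameters recovers ``lst_true``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.full((spec.n_rows, spec.n_cols), int(spec.background_class),
                   dtype=np.int16)
    for shape in spec.class_layout:
        shape.paint(grid)
    landcover = LandCoverMap(grid, cell_size=spec.cell_size)

    lst = np.full(grid.shape, np.nan)
    ndvi = np.full(grid.shape, np.nan)
    # fixed class order so draws are independent of layout order
    for cls in sorted(set(spec.per_class_lst) | set(spec.per_class_ndvi)):
        mask = grid == int(cls)
        n = int(mask.sum())
        if n == 0:
            continue
        mu, sd = spec.per_class_lst[cls]
        lst[mask] = mu + sd * rng.standard_normal(n)
        mu_v, sd_v = spec.per_class_ndvi[cls]
        ndvi[mask] = np.clip(mu_v + sd_v * rng.standard_normal(n), -1.0, 1.0)
    if np.isnan(lst).any():
        raise ValueError("per_class_lst/per_class_ndvi must cover every "
                         "class present in the layout")

    cell = spec.cell_size
    lst_true = RasterGrid(lst, cell_size=cell)
    nir = RasterGrid(0.3 * (1.0 + ndvi), cell_size=cell)
    red = RasterGrid(0.3 * (1.0 - ndvi), cell_size=cell)

    pv = vegetation_fraction(RasterGrid(ndvi, cell_size=cell), emis_params)
    eps = emissivity(pv, emis_params)
    radiance = forward_radiance(lst_true, eps, atmos, planck)
    return SyntheticScene(landcover=landcover, lst_true=lst_true, red=red,
                          nir=nir, radiance=radiance, spec=spec)


def demo_scene_spec(seed: int = 0, lst_sd: float = 0.3,
                    ndvi_sd: float = 0.05, scale: int = 1) -> SceneSpec:
    """Default five-class demo scene.

    A 300x300 mosaic (30 m cells) with >= 10^4 cells per class; class mean
    LSTs are the Luoping built-up-area values so the printed class ordering
    (impervious > bare > grass > canopy > water) is the ground truth. ``scale``
    multiplies the linear dimensions.
    """
    s = scale
    layout = [
        Rect(LandCover.WATER, 0 * s, 0 * s, 100 * s, 100 * s),
        Rect(LandCover.TREE_CANOPY, 0 * s, 120 * s, 100 * s, 120 * s),
        Rect(LandCover.GRASSLAND, 120 * s, 0 * s, 100 * s, 100 * s),
        Rect(LandCover.BARE_LAND, 120 * s, 120 * s, 100 * s, 110 * s),
        # canopy discs inside bare surroundings: distinct patches
        Disc(LandCover.TREE_CANOPY, 260 * s, 40 * s, 18 * s),
        Disc(LandCover.TREE_CANOPY, 260 * s, 150 * s, 25 * s),
    ]
    per_class_lst = {c: (m, lst_sd) for c, m in LUOPING_CLASS_MEAN_LST.items()}
    per_class_ndvi = {c: (m, ndvi_sd) for c, m in DEFAULT_CLASS_NDVI.items()}
    return SceneSpec(n_rows=300 * s, n_cols=300 * s, cell_size=30.0,
                     class_layout=layout, per_class_lst=per_class_lst,
                     per_class_ndvi=per_class_ndvi,
                     background_class=LandCover.IMPERVIOUS, seed=seed)


def write_scene(scene: SyntheticScene, outdir) -> None:
    """Write a scene as text grids plus a JSON sidecar of its spec."""
    from .raster import write_text_grid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_text_grid(outdir / "lst_true.txt", scene.lst_true)
    write_text_grid(outdir / "red.txt", scene.red)
    write_text_grid(outdir / "nir.txt", scene.nir)
    write_text_grid(outdir / "radiance.txt", scene.radiance)
    np.savetxt(outdir / "landcover.txt", scene.landcover.grid, fmt="%d",
               header=f"cell_size={scene.landcover.cell_size!r} legend="
                      + ",".join(f"{c.name}={int(c)}" for c in LandCover))
    (outdir / "scene_spec.json").write_text(scene.spec.to_json())
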