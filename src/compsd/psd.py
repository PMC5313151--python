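"""Potential species distribution (PSD) surfaces.

The original PSD is the cellwise product of the three abiotic response
surfaces; the revised PSD weights it by the species' relative competitive
rating (P100) of the forestland type each cell belongs to, so revision can
only shrink the mapped distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from compsd.raster import RasterSurface, RasterError, require_coregistered

__all__ = [
    "PsdStack",
    "psd_original",
    "psd_original_stack",
    "psd_revised",
    "classify_site_quality",
    "area_fraction_summary",
]

QUALITY_CLASSES = ("low", "moderate", "high")


@dataclass
class PsdStack:
    """Per-species PSD surfaces sharing one georeference."""

    surfaces: dict[str, RasterSurface]
    variant: str = "original"

    def __post_init__(self) -> None:
        if not self.surfaces:
            raise ValueError("PsdStack requires at least one species surface")
        if self.variant not in ("original", "revised"):
            raise ValueError(f"variant must be 'original' or 'revised', got {self.variant!r}")
        codes = list(self.surfaces)
        require_coregistered(*self.surfaces.values(), names=codes)

    @property
    def species(self) -> list[str]:
        return list(self.surfaces)

    def __getitem__(self, code: str) -> RasterSurface:
        return self.surfaces[code]

    def __iter__(self) -> Iterator[str]:
        return iter(self.surfaces)

    def as_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (cells x species matrix over jointly valid cells, mask)."""
        grids = [self.surfaces[c].grid for c in self.surfaces]
        mask = np.all([~np.isnan(g) for g in grids], axis=0)
        mat = np.column_stack([g[mask] for g in grids])
        return mat, mask


def psd_original(
    r_par: RasterSurface, r_swc: RasterSurface, r_gdd: RasterSurface
) -> RasterSurface:
    """Multiply the three response surfaces into one suitability surface."""
    require_coregistered(r_par, r_swc, r_gdd, names=["r_par", "r_swc", "r_gdd"])
    for name, s in (("r_par", r_par), ("r_swc", r_swc), ("r_gdd", r_gdd)):
        vals = s.grid[s.valid_mask]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError(f"{name}: response values must lie in [0, 1]")
    return r_par.copy_with(r_par.grid * r_swc.grid * r_gdd.grid)


def psd_original_stack(
    responses: Mapping[str, tuple[RasterSurface, RasterSurface, RasterSurface]]
) -> PsdStack:
    """Build the original PSD stack from per-species (PAR, SWC, GDD) triples."""
    return PsdStack(
        surfaces={code: psd_original(*triple) for code, triple in responses.items()},
        variant="original",
    )


def psd_revised(
    psd_orig: PsdStack,
    ratings: pd.DataFrame,
    forestland: RasterSurface,
) -> PsdStack:
    """Weight the original PSD by per-type competitive ratings.

    `ratings` is indexed by forestland type id with one column per species
    code (P100 values in [0, 1]); `forestland` holds integer type ids per
    cell.  Cells without an assigned type become nodata in the output.
    """
    if psd_orig.variant != "original":
        raise ValueError("psd_revised expects the original-variant stack")
    first = psd_orig[psd_orig.species[0]]
    require_coregistered(first, forestland, names=["psd", "forestland"])
    type_grid = forestland.grid
    assigned = ~np.isnan(type_grid)
    present = np.unique(type_grid[assigned]).astype(int)
    known = set(int(i) for i in ratings.index)
    missing_ids = [int(t) for t in present if int(t) not in known]
    if missing_ids:
        raise KeyError(
            f"forestland type id(s) {missing_ids} missing from the ratings table"
        )
    vals = ratings.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("P100 ratings must lie in [0, 1]")

    out: dict[str, RasterSurface] = {}
    for code in psd_orig.species:
        if code not in ratings.columns:
            raise KeyError(f"species {code!r} missing from the ratings table")
        weight = np.full(type_grid.shape, np.nan)
        for tid in present:
            weight[type_grid == tid] = float(ratings.loc[int(tid), code])
        out[code] = psd_orig[code].copy_with(weight * psd_orig[code].grid)
    return PsdStack(surfaces=out, variant="revised")


def classify_site_quality(
    psd: RasterSurface, low_cut: float = 0.25, high_cut: float = 0.5
) -> RasterSurface:
    """Bin a PSD surface into {0: low, 1: moderate, 2: high} site quality.

    Cells with psd < low_cut are low, [low_cut, high_cut) moderate and
    >= high_cut high; both cuts are inclusive on the upper class.
    """
    if not (0 <= low_cut < high_cut <= 1):
        raise ValueError(f"require 0 <= low_cut < high_cut <= 1, got ({low_cut}, {high_cut})")
    g = psd.grid
    classes = np.full(g.shape, np.nan)
    classes[g < low_cut] = 0
    classes[(g >= low_cut) & (g < high_cut)] = 1
    classes[g >= high_cut] = 2
    return psd.copy_with(classes)


def area_fraction_summary(categorical: RasterSurface) -> dict[str, float]:
    """Fraction of valid cells per quality class; fractions sum to 1."""
    vals = categorical.grid[categorical.valid_mask]
    if vals.size == 0:
        raise ValueError("area_fraction_summary: raster has no valid cells")
    out = {}
    for code, name in enumerate(QUALITY_CLASSES):
        frac = float(np.mean(vals == code))
        if frac > 0:
            out[name] = frac
    return out
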