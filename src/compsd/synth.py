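"""Synthetic landscapes, species, stands and plot observations.

Every generator is a pure function of its scenario and seed so that the
whole pipeline can be exercised — and its validation statistics predicted
in closed form — without any external data.  Abiotic surfaces are
Gaussian-smoothed white noise rescaled to each variable's range, which
gives spatial autocorrelation with a controllable length scale; plot
observations flip the generating truth with a known error rate so the
expected agreement of a perfect model is exactly 100*(1 - epsilon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from compsd.params import SpeciesParams, light_archetype, params_from_frame
from compsd.psd import PsdStack
from compsd.raster import GridTransform, RasterSurface

__all__ = [
    "SyntheticScenario",
    "generate_surfaces",
    "generate_species_params",
    "generate_plots",
    "generate_initial_stand",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions of a synthetic landscape experiment."""

    nrows: int = 200
    ncols: int = 200
    cellsize: float = 70.0
    npar_range: tuple[float, float] = (0.0, 1.0)
    swc_range: tuple[float, float] = (0.0, 1.0)
    gdd_range: tuple[float, float] = (900.0, 2500.0)
    autocorr_length: float = 10.0  # cells
    n_species: int = 16
    n_plots: int = 1240
    obs_noise: float = 0.0  # epsilon: probability an observation flips truth
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.npar_range, self.swc_range, self.gdd_range):
            if not lo < hi:
                raise ValueError(f"invalid range ({lo}, {hi})")
        if not (0 <= self.obs_noise < 0.5):
            raise ValueError("obs_noise must be in [0, 0.5)")
        if self.autocorr_length <= 0:
            raise ValueError("autocorr_length must be positive")


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], length: float,
    lo: float, hi: float,
) -> np.ndarray:
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=length, mode="reflect")
    mn, mx = smooth.min(), smooth.max()
    return lo + (smooth - mn) / (mx - mn) * (hi - lo)


def generate_surfaces(
    scenario: SyntheticScenario,
) -> tuple[RasterSurface, RasterSurface, RasterSurface]:
    """Generate co-registered nPAR, SWC and GDD surfaces.

    Fields are seeded white noise smoothed with a Gaussian kernel of the
    scenario's autocorrelation length and affinely rescaled to each
    variable's range; identical seeds give identical rasters.
    """
    if scenario.autocorr_length >= min(scenario.nrows, scenario.ncols):
        raise ValueError("autocorr_length must be smaller than the grid")
    rng = np.random.default_rng(scenario.seed)
    shape = (scenario.nrows, scenario.ncols)
    transform = GridTransform(0.0, 0.0, scenario.cellsize)
    out = []
    for lo, hi in (scenario.npar_range, scenario.swc_range, scenario.gdd_range):
        grid = _smooth_field(rng, shape, scenario.autocorr_length, lo, hi)
        out.append(RasterSurface(grid=grid, transform=transform))
    return tuple(out)


def generate_species_params(
    n_species: int,
    seed: int = 0,
    gdd_range: tuple[float, float] = (900.0, 2500.0),
) -> dict[str, SpeciesParams]:
    """Draw a valid synthetic species-parameter table.

    Tolerance classes cycle 1..5 so the community is balanced; light curves
    follow the class archetypes; at least every other species receives a
    degree-day window centred inside the scenario's GDD range so the
    landscape always supports a mixed community.  Shade-tolerant species
    are made longer-lived and slower-growing than intolerant ones, the
    trait trade-off that drives successional replacement.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = gdd_range
    rows = []
    for i in range(n_species):
        cls = (i % 5) + 1
        c1, c2, cp = light_archetype(cls)
        swc_min = rng.uniform(0.0, 0.25)
        swc_max = rng.uniform(0.75, 1.0)
        psi = rng.uniform(swc_min + 0.15, swc_max - 0.15)
        if i % 2 == 0:
            center = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo))
        else:
            center = rng.uniform(lo - 0.3 * (hi - lo), hi + 0.3 * (hi - lo))
        half = rng.uniform(0.4, 0.9) * (hi - lo)
        gdd_min = max(0.0, center - half)
        gdd_max = center + half
        # trait trade-off: tolerance buys longevity, costs growth rate
        g = rng.uniform(180.0, 260.0) - 25.0 * (cls - 1)
        age_max = rng.uniform(100.0, 160.0) + 70.0 * (cls - 1)
        rows.append(
            {
                "species_code": f"sp{i + 1:02d}",
                "shade_tolerance_class": cls,
                "c1": c1, "c2": c2, "cp": cp,
                "swc_min": swc_min, "psi": psi, "swc_max": swc_max,
                "gdd_min": gdd_min, "gdd_max": gdd_max,
                "g_growth": g,
                "d_max": rng.uniform(45.0, 100.0),
                "h_max": rng.uniform(2000.0, 3400.0),
                "age_max": age_max,
                "biomass_a": rng.uniform(0.06, 0.14),
                "biomass_b": rng.uniform(2.2, 2.6),
                "recruit_rate": rng.uniform(0.5, 2.5),
            }
        )
    return params_from_frame(pd.DataFrame(rows), source=f"synthetic(seed={seed})")


def generate_plots(
    scenario: SyntheticScenario,
    true_psd: PsdStack,
    threshold: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample plot locations and noisy presence observations.

    Plots fall at the centers of uniformly sampled jointly-valid cells;
    true presence is (true PSD > threshold); each observation independently
    flips the truth with probability scenario.obs_noise.  Returns
    (observations, truth) frames with columns plot_id, x, y, <species...>.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    _, mask = true_psd.as_matrix()
    rows, cols = np.nonzero(mask)
    if scenario.n_plots > rows.size:
        raise ValueError(
            f"n_plots={scenario.n_plots} exceeds {rows.size} valid cells"
        )
    pick = rng.choice(rows.size, size=scenario.n_plots, replace=False)
    template = true_psd[true_psd.species[0]]
    obs_rows, truth_rows = [], []
    for pid, idx in enumerate(pick, start=1):
        r, c = int(rows[idx]), int(cols[idx])
        x, y = template.cell_center(r, c)
        obs = {"plot_id": pid, "x": x, "y": y}
        tru = {"plot_id": pid, "x": x, "y": y}
        for code in true_psd.species:
            t = bool(true_psd[code].grid[r, c] > threshold)
            flip = rng.random() < scenario.obs_noise
            obs[code] = int(t ^ flip)
            tru[code] = int(t)
        obs_rows.append(obs)
        truth_rows.append(tru)
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


def generate_initial_stand(
    species_codes: list[str],
    n_trees: int,
    dbh_range: tuple[float, float] = (2.0, 20.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform random initial stand table (species_code, dbh_cm, count=1)."""
    if n_trees < 0:
        raise ValueError("n_trees must be >= 0")
    lo, hi = dbh_range
    if not 0 < lo < hi:
        raise ValueError(f"invalid dbh_range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    rows = [
        {
            "species_code": species_codes[int(rng.integers(len(species_codes)))],
            "dbh_cm": float(rng.uniform(lo, hi)),
            "count": 1,
        }
        for _ in range(n_trees)
    ]
    return pd.DataFrame(rows, columns=["species_code", "dbh_cm", "count"])
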