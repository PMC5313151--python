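"""Species parameter containers, validation and table I/O.

Two parameter groups are kept per species: the kernel parameters that shape
the three abiotic response functions (light, soil water, degree days) and
the growth parameters driving the individual-based gap model.  Both can be
read from one CSV/YAML table with a column per field and one row per
species.  GDD tolerance limits are shared between the two groups: the same
window bounds the response kernel and the simulator's establishment filter.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "SpeciesKernelParams",
    "SpeciesGrowthParams",
    "SpeciesParams",
    "SwcDerivedShape",
    "light_archetype",
    "load_species_params",
    "default_species_params",
    "ParamsError",
]


class ParamsError(ValueError):
    """Raised for invalid or inconsistent species parameters."""


#: JABOWA-family light-response archetypes keyed by shade-tolerance class.
#: Class 1 (least tolerant) uses the steep high-compensation-point curve;
#: class 5 (most tolerant) saturates early from a low compensation point.
#: Intermediate classes interpolate linearly between the two end members.
_LIGHT_INTOLERANT = (2.24, 1.136, 0.08)  # c1, c2, cp
_LIGHT_TOLERANT = (1.0, 4.64, 0.05)


def light_archetype(shade_tolerance_class: int) -> tuple[float, float, float]:
    """Return (c1, c2, cp) of the light curve for a tolerance class 1-5."""
    if shade_tolerance_class not in (1, 2, 3, 4, 5):
        raise ParamsError(
            f"shade_tolerance_class must be in 1..5, got {shade_tolerance_class}"
        )
    t = (shade_tolerance_class - 1) / 4.0
    return tuple(
        a + t * (b - a) for a, b in zip(_LIGHT_INTOLERANT, _LIGHT_TOLERANT)
    )


@dataclass(frozen=True)
class SwcDerivedShape:
    """Derived shape constants of the soil-water response curve.

    chi is the optimum position on the normalized moisture axis, alpha the
    shape exponent and kappa_norm the normalizer that makes the response
    exactly 1 at the optimum.
    """

    chi: float
    alpha: float
    kappa_norm: float


@dataclass(frozen=True)
class SpeciesKernelParams:
    """Parameters of one species' abiotic response kernels.

    c1/c2/cp shape the saturating light response (cp is the light
    compensation point on the 0-1 nPAR axis); swc_min < psi < swc_max bound
    the unimodal soil-water response with its optimum at psi; gdd_min and
    gdd_max are the cold and warm degree-day tolerance limits.
    """

    species_code: str
    c1: float
    c2: float
    cp: float
    swc_min: float
    swc_max: float
    psi: float
    gdd_min: float
    gdd_max: float
    shade_tolerance_class: int = 3

    def __post_init__(self) -> None:
        if not (self.c1 > 0):
            raise ParamsError(f"{self.species_code}: c1 must be > 0, got {self.c1}")
        if not (self.c2 > 0):
            raise ParamsError(f"{self.species_code}: c2 must be > 0, got {self.c2}")
        if not (0 <= self.cp < 1):
            raise ParamsError(f"{self.species_code}: cp must be in [0,1), got {self.cp}")
        if not (0 <= self.swc_min < self.psi < self.swc_max <= 1):
            raise ParamsError(
                f"{self.species_code}: require 0 <= swc_min < psi < swc_max <= 1, "
                f"got ({self.swc_min}, {self.psi}, {self.swc_max})"
            )
        if not (0 <= self.gdd_min < self.gdd_max):
            raise ParamsError(
                f"{self.species_code}: require 0 <= gdd_min < gdd_max, "
                f"got ({self.gdd_min}, {self.gdd_max})"
            )
        if self.shade_tolerance_class not in (1, 2, 3, 4, 5):
            raise ParamsError(
                f"{self.species_code}: shade_tolerance_class must be 1..5, "
                f"got {self.shade_tolerance_class}"
            )

    def swc_shape(self) -> SwcDerivedShape:
        chi = (self.psi - self.swc_min) / (self.swc_max - self.swc_min)
        alpha = chi / (1.0 - chi)
        kappa = 1.0 / (chi**alpha * (1.0 - chi) ** (1.0 / alpha))
        return SwcDerivedShape(chi=chi, alpha=alpha, kappa_norm=kappa)


@dataclass(frozen=True)
class SpeciesGrowthParams:
    """Gap-model growth parameters for one species.

    g_growth scales the optimal diameter increment; d_max/h_max/age_max are
    the maximum diameter (cm), height (cm) and age (yr); biomass follows the
    power law AGB = biomass_a * dbh**biomass_b (kg, dbh in cm); recruit_rate
    is the expected number of new saplings per plot and year when the
    species passes the establishment filters.
    """

    species_code: str
    g_growth: float
    d_max: float
    h_max: float
    age_max: float
    shade_tolerance_class: int
    gdd_min: float
    gdd_max: float
    biomass_a: float
    biomass_b: float
    recruit_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (self.d_max > 0):
            raise ParamsError(f"{self.species_code}: d_max must be > 0")
        if not (self.h_max > 137):
            raise ParamsError(
                f"{self.species_code}: h_max must exceed breast height (137 cm)"
            )
        if not (self.age_max > 0):
            raise ParamsError(f"{self.species_code}: age_max must be > 0")
        if not (self.biomass_b > 1):
            raise ParamsError(f"{self.species_code}: biomass_b must be > 1")
        if self.shade_tolerance_class not in (1, 2, 3, 4, 5):
            raise ParamsError(
                f"{self.species_code}: shade_tolerance_class must be 1..5"
            )
        if not (0 <= self.gdd_min < self.gdd_max):
            raise ParamsError(f"{self.species_code}: require 0 <= gdd_min < gdd_max")
        if self.recruit_rate < 0:
            raise ParamsError(f"{self.species_code}: recruit_rate must be >= 0")


@dataclass(frozen=True)
class SpeciesParams:
    """Kernel and growth parameters of one species, loaded from one row."""

    kernel: SpeciesKernelParams
    growth: SpeciesGrowthParams

    @property
    def species_code(self) -> str:
        return self.kernel.species_code


_COLUMNS = [
    "species_code",
    "shade_tolerance_class",
    "c1",
    "c2",
    "cp",
    "swc_min",
    "psi",
    "swc_max",
    "gdd_min",
    "gdd_max",
    "g_growth",
    "d_max",
    "h_max",
    "age_max",
    "biomass_a",
    "biomass_b",
    "recruit_rate",
]


def _row_to_params(row: Mapping, where: str) -> SpeciesParams:
    try:
        kernel = SpeciesKernelParams(
            species_code=str(row["species_code"]),
            c1=float(row["c1"]),
            c2=float(row["c2"]),
            cp=float(row["cp"]),
            swc_min=float(row["swc_min"]),
            swc_max=float(row["swc_max"]),
            psi=float(row["psi"]),
            gdd_min=float(row["gdd_min"]),
            gdd_max=float(row["gdd_max"]),
            shade_tolerance_class=int(row["shade_tolerance_class"]),
        )
        growth = SpeciesGrowthParams(
            species_code=str(row["species_code"]),
            g_growth=float(row["g_growth"]),
            d_max=float(row["d_max"]),
            h_max=float(row["h_max"]),
            age_max=float(row["age_max"]),
            shade_tolerance_class=int(row["shade_tolerance_class"]),
            gdd_min=float(row["gdd_min"]),
            gdd_max=float(row["gdd_max"]),
            biomass_a=float(row["biomass_a"]),
            biomass_b=float(row["biomass_b"]),
            recruit_rate=float(row["recruit_rate"]),
        )
    except (KeyError, ValueError, ParamsError) as exc:
        raise ParamsError(f"{where}: {exc}") from exc
    return SpeciesParams(kernel=kernel, growth=growth)


def params_from_frame(frame: pd.DataFrame, source: str = "<table>") -> dict[str, SpeciesParams]:
    """Validate a parameter table and return species_code -> SpeciesParams."""
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ParamsError(f"{source}: missing columns {missing}")
    table: dict[str, SpeciesParams] = {}
    for i, row in frame.iterrows():
        # +2: header line plus 1-based numbering, matching the file layout
        params = _row_to_params(row, where=f"{source}, line {int(i) + 2}")
        code = params.species_code
        if code in table:
            raise ParamsError(f"{source}: duplicate species_code {code!r}")
        table[code] = params
    if not table:
        raise ParamsError(f"{source}: empty parameter table")
    return table


def params_to_frame(table: Mapping[str, SpeciesParams]) -> pd.DataFrame:
    rows = []
    for sp in table.values():
        k, g = sp.kernel, sp.growth
        rows.append(
            {
                "species_code": k.species_code,
                "shade_tolerance_class": k.shade_tolerance_class,
                "c1": k.c1,
                "c2": k.c2,
                "cp": k.cp,
                "swc_min": k.swc_min,
                "psi": k.psi,
                "swc_max": k.swc_max,
                "gdd_min": k.gdd_min,
                "gdd_max": k.gdd_max,
                "g_growth": g.g_growth,
                "d_max": g.d_max,
                "h_max": g.h_max,
                "age_max": g.age_max,
                "biomass_a": g.biomass_a,
                "biomass_b": g.biomass_b,
                "recruit_rate": g.recruit_rate,
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def load_species_params(path: str | Path) -> dict[str, SpeciesParams]:
    """Load a species parameter table from CSV or YAML.

    YAML files hold a list of mappings (one per species) with the same keys
    as the CSV columns.
    """
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        with open(path) as fh:
            records = yaml.safe_load(fh)
        if not isinstance(records, list):
            raise ParamsError(f"{path}: expected a YAML list of species records")
        frame = pd.DataFrame(records)
    else:
        frame = pd.read_csv(path, comment="#")
    return params_from_frame(frame, source=str(path))


def default_species_params() -> dict[str, SpeciesParams]:
    """Bundled 16-species parameter table (synthetic but plausible values).

    The numeric values are NOT transcriptions of any published table; they
    are synthetic defaults spanning realistic Acadian-forest ranges, with
    light curves taken from the tolerance-class archetypes.  Use your own
    table for real analyses.
    """
    ref = importlib.resources.files("compsd.data").joinpath(
        "species_params_synthetic.csv"
    )
    with importlib.resources.as_file(ref) as p:
        frame = pd.read_csv(p, comment="#")
    return params_from_frame(frame, source="species_params_synthetic.csv")
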