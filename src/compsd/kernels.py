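"""Species response kernels and the growing-degree-day accumulator.

Each kernel maps an abiotic driver to a 0-1 response: a saturating
exponential in normalized PAR, a unimodal beta-like curve in soil water
content, and a symmetric parabola in growing degree days.  All kernels
accept scalars or numpy arrays and propagate NaN (nodata) cells untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from compsd.params import SpeciesKernelParams

__all__ = [
    "DailyTemperatureSeries",
    "growing_degree_days",
    "response_par",
    "response_swc",
    "response_gdd",
]


@dataclass(frozen=True)
class DailyTemperatureSeries:
    """Mean daily temperatures (deg C) over one growing season."""

    values: Sequence[float]
    t_base: float = 5.0

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("temperature series must be non-empty")
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("temperature series contains non-finite values")
        if not np.isfinite(self.t_base):
            raise ValueError("t_base must be finite")


def growing_degree_days(series: DailyTemperatureSeries) -> float:
    """Accumulate degree days: sum of positive exceedances over the base.

    GDD = sum_i max(0, T_avg,i - T_base) with a 5 deg C default base.
    """
    arr = np.asarray(series.values, dtype=float)
    return float(np.maximum(0.0, arr - series.t_base).sum())


def _prepare(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _finish(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def response_par(npar, params: SpeciesKernelParams):
    """Light response: c1 * (1 - exp(-c2 (nPAR - cp))), clamped to [0, 1].

    Below the compensation point cp the raw curve is negative and the
    response is 0; for scaling factors c1 > 1 the raw curve can exceed 1
    and is clamped so the suitability index stays on the 0-1 scale.
    """
    if params.c2 <= 0:
        raise ValueError(f"{params.species_code}: c2 must be positive")
    arr, scalar = _prepare(npar)
    r = params.c1 * (1.0 - np.exp(-params.c2 * (arr - params.cp)))
    r = np.clip(r, 0.0, 1.0)  # clip keeps NaN as NaN
    return _finish(r, scalar)


def response_swc(swc, params: SpeciesKernelParams):
    """Unimodal soil-water response, exactly 1 at the optimum psi.

    The moisture axis is first normalized, xi = (SWC - SWC_min)/(SWC_max -
    SWC_min); inside (0, 1) the response is kappa * xi**alpha *
    (1-xi)**(1/alpha) with shape constants derived from the optimum
    position, and 0 at or beyond the tolerance limits.
    """
    shape = params.swc_shape()
    arr, scalar = _prepare(swc)
    xi = (arr - params.swc_min) / (params.swc_max - params.swc_min)
    inside = (xi > 0.0) & (xi < 1.0)
    r = np.zeros_like(xi)
    xin = np.where(inside, xi, 0.5)  # dummy value avoids 0**negative warnings
    r_in = shape.kappa_norm * xin**shape.alpha * (1.0 - xin) ** (1.0 / shape.alpha)
    r = np.where(inside, r_in, 0.0)
    r = np.where(np.isnan(xi), np.nan, np.clip(r, 0.0, 1.0))
    return _finish(r, scalar)


def response_gdd(gdd, params: SpeciesKernelParams):
    """Parabolic degree-day response, 1 at the window midpoint, 0 at limits.

    R = 4 (GDD - GDD_min)(GDD_max - GDD) / (GDD_max - GDD_min)**2 clamped to
    [0, 1]; outside the tolerance window the parabola is negative and the
    response is 0.
    """
    if params.gdd_min >= params.gdd_max:
        raise ValueError(f"{params.species_code}: gdd_min must be < gdd_max")
    arr, scalar = _prepare(gdd)
    span = params.gdd_max - params.gdd_min
    r = 4.0 * (arr - params.gdd_min) * (params.gdd_max - arr) / span**2
    r = np.clip(r, 0.0, 1.0)
    return _finish(r, scalar)
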