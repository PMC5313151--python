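"""Relative competitive ratings (P100) from simulated stand biomass.

For each forestland type, species biomass shares after the simulation
horizon are rescaled by the row maximum so the best performer scores
exactly 1 and species eliminated from the community score 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["p100_matrix", "read_ratings", "write_ratings", "RatingsError"]


class RatingsError(ValueError):
    pass


def p100_matrix(
    biomass: pd.DataFrame,
    mode: str = "share",
    monoculture_optimum: pd.Series | None = None,
) -> pd.DataFrame:
    """Rescale a forestland-type x species biomass matrix to P100 ratings.

    mode="share" (default): within each type, species shares of total
    biomass are divided by the row-maximum share, so every row has maximum
    exactly 1 (ties all get 1) and zero-biomass species get 0.

    mode="monoculture": biomass is first expressed as a proportion of each
    species' own optimum biomass (`monoculture_optimum`, indexed by species
    code) before the row-max rescaling — an alternative reading of the
    competitive rating based on performance relative to open-grown stands.
    """
    mat = biomass.to_numpy(dtype=float)
    if (mat < 0).any():
        raise RatingsError("biomass values must be non-negative")
    zero_rows = np.where(mat.sum(axis=1) == 0)[0]
    if zero_rows.size:
        names = [str(biomass.index[i]) for i in zero_rows]
        raise RatingsError(f"forestland type(s) with all-zero biomass: {names}")
    if mode == "share":
        shares = mat / mat.sum(axis=1, keepdims=True)
    elif mode == "monoculture":
        if monoculture_optimum is None:
            raise RatingsError("mode='monoculture' requires monoculture_optimum")
        opt = monoculture_optimum.reindex(biomass.columns).to_numpy(dtype=float)
        if np.any(~np.isfinite(opt)) or np.any(opt <= 0):
            raise RatingsError("monoculture_optimum must be positive for every species")
        shares = mat / opt[None, :]
    else:
        raise RatingsError(f"unknown mode {mode!r}")
    p100 = shares / shares.max(axis=1, keepdims=True)
    return pd.DataFrame(p100, index=biomass.index, columns=biomass.columns)


def validate_ratings(frame: pd.DataFrame, source: str = "<ratings>") -> pd.DataFrame:
    """Enforce the P100 contract: cells in [0,1], every row max exactly 1."""
    mat = frame.to_numpy(dtype=float)
    for i, row in enumerate(mat):
        line = i + 2  # header + 1-based
        if np.any(~np.isfinite(row)):
            raise RatingsError(f"{source}, line {line}: non-finite rating")
        if row.min() < 0 or row.max() > 1:
            raise RatingsError(
                f"{source}, line {line}: ratings must lie in [0, 1], "
                f"found {row.min():.3g}..{row.max():.3g}"
            )
        if not np.isclose(row.max(), 1.0, atol=1e-9):
            raise RatingsError(
                f"{source}, line {line}: row maximum must be 1, got {row.max():.6g}"
            )
    return frame


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read and validate a ratings CSV (rows = forestland types, cols = species)."""
    frame = pd.read_csv(path, index_col=0, comment="#")
    return validate_ratings(frame, source=str(path))


def write_ratings(frame: pd.DataFrame, path: str | Path) -> None:
    validate_ratings(frame)
    frame.to_csv(path, index_label="forestland_type")
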