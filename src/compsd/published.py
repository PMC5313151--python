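"""Access to the bundled published assessment tables.

The package ships the per-species contingency counts and printed summary
statistics of the original and competition-revised PSD assessments so the
accuracy module can be exercised against real printed numbers.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from compsd.accuracy import ContingencyTable

__all__ = ["load_published_assessment", "published_tables"]


def load_published_assessment(variant: str) -> pd.DataFrame:
    """Return the published assessment table ('original' or 'revised')."""
    if variant not in ("original", "revised"):
        raise ValueError(f"variant must be 'original' or 'revised', got {variant!r}")
    ref = importlib.resources.files("compsd.data").joinpath(
        f"assessment_{variant}.csv"
    )
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, comment="#")


def published_tables(variant: str) -> dict[str, ContingencyTable]:
    """Per-species ContingencyTable objects from the published counts."""
    frame = load_published_assessment(variant)
    return {
        row["species"]: ContingencyTable(
            n_pp=int(row["n_pp"]), n_pa=int(row["n_pa"]),
            n_ap=int(row["n_ap"]), n_aa=int(row["n_aa"]),
        )
        for _, row in frame.iterrows()
    }
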