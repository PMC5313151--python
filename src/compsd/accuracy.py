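"""Presence/absence accuracy assessment of PSD maps against plot data.

A species is predicted present in a cell when its PSD exceeds 0.25
(strictly).  Per-species 2x2 contingency tables against observed plot
presence yield overall agreement, Cohen's kappa and a Monserud-Leemans
verbal quality class; across-species means are unweighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from compsd.psd import PsdStack

__all__ = [
    "ContingencyTable",
    "presence_from_psd",
    "contingency",
    "overall_accuracy",
    "cohen_kappa",
    "monserud_class",
    "accuracy_report",
    "assess_stack",
    "round_half_up",
]

logger = logging.getLogger(__name__)

#: Monserud-Leemans kappa quality classes, half-open [lower, upper) bins.
MONSERUD_BINS = [
    (0.20, "poor"),
    (0.40, "fair"),
    (0.50, "moderate"),
    (0.70, "good"),
    (0.80, "very good"),
    (float("inf"), "excellent"),
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (81.25 -> 81.3), as printed reports use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 predicted x observed presence counts.

    n_pp: predicted & observed occurrence; n_pa: predicted occurrence,
    observed absence; n_ap: predicted absence, observed occurrence;
    n_aa: predicted & observed absence.
    """

    n_pp: int
    n_pa: int
    n_ap: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_pp, self.n_pa, self.n_ap, self.n_aa) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_pp + self.n_pa + self.n_ap + self.n_aa


def presence_from_psd(psd: float, threshold: float = 0.25) -> bool:
    """Predicted presence iff PSD strictly exceeds the threshold."""
    if np.isnan(psd):
        raise ValueError("presence_from_psd: nodata PSD value; exclude the plot")
    return bool(psd > threshold)


def contingency(
    predicted: Sequence[bool], observed: Sequence[bool]
) -> ContingencyTable:
    """Cross-tabulate paired predicted/observed presence flags."""
    pred = np.asarray(predicted, dtype=bool)
    obs = np.asarray(observed, dtype=bool)
    if pred.shape != obs.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predicted vs {obs.shape[0]} observed"
        )
    if pred.size == 0:
        raise ValueError("contingency requires at least one plot")
    return ContingencyTable(
        n_pp=int(np.sum(pred & obs)),
        n_pa=int(np.sum(pred & ~obs)),
        n_ap=int(np.sum(~pred & obs)),
        n_aa=int(np.sum(~pred & ~obs)),
    )


def overall_accuracy(t: ContingencyTable) -> float:
    """Percent of plots where prediction and observation agree."""
    if t.n == 0:
        raise ValueError("overall_accuracy undefined for an empty table")
    return 100.0 * (t.n_pp + t.n_aa) / t.n


def cohen_kappa(t: ContingencyTable) -> float:
    """Chance-corrected agreement kappa = (P_o - P_e) / (1 - P_e).

    P_e is the agreement expected from the marginal totals.  A degenerate
    table with P_e = 1 returns 1 when observed agreement is also perfect,
    otherwise 0 (with a warning).
    """
    n = t.n
    if n == 0:
        raise ValueError("cohen_kappa undefined for an empty table")
    p_o = (t.n_pp + t.n_aa) / n
    pred_occ = t.n_pp + t.n_pa
    pred_abs = t.n_ap + t.n_aa
    obs_occ = t.n_pp + t.n_ap
    obs_abs = t.n_pa + t.n_aa
    p_e = (pred_occ * obs_occ + pred_abs * obs_abs) / n**2
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        logger.warning("cohen_kappa: degenerate marginals (P_e = 1); returning 0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def monserud_class(kappa: float) -> str:
    """Verbal kappa quality class on the Monserud-Leemans scale."""
    if not np.isfinite(kappa):
        raise ValueError("kappa must be finite")
    for upper, label in MONSERUD_BINS:
        if kappa < upper:
            return label
    return "excellent"  # pragma: no cover


def accuracy_report(tables: Mapping[str, ContingencyTable]) -> pd.DataFrame:
    """Per-species assessment rows plus an unweighted across-species mean.

    Columns mirror the classic assessment-table layout: the four cell
    counts, overall agreement (%), kappa and the verbal class; the final
    row "overall" holds the arithmetic means of agreement and kappa, with
    the mean kappa also classed.
    """
    if not tables:
        raise ValueError("accuracy_report requires at least one species")
    rows = []
    for code, t in tables.items():
        oa = overall_accuracy(t)
        k = cohen_kappa(t)
        rows.append(
            {
                "species_code": code,
                "n_plots": t.n,
                "n_pp": t.n_pp,
                "n_pa": t.n_pa,
                "n_ap": t.n_ap,
                "n_aa": t.n_aa,
                "overall_agreement_pct": oa,
                "kappa": k,
                "assessment": monserud_class(k),
            }
        )
    frame = pd.DataFrame(rows)
    mean_oa = float(frame["overall_agreement_pct"].mean())
    mean_k = float(frame["kappa"].mean())
    overall = {
        "species_code": "overall",
        "n_plots": int(frame["n_plots"].sum()),
        "n_pp": np.nan, "n_pa": np.nan, "n_ap": np.nan, "n_aa": np.nan,
        "overall_agreement_pct": mean_oa,
        "kappa": mean_k,
        "assessment": monserud_class(mean_k),
    }
    return pd.concat([frame, pd.DataFrame([overall])], ignore_index=True)


def assess_stack(
    psd_stack: PsdStack,
    plots: pd.DataFrame,
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Assess a PSD stack against a plot table.

    `plots` has columns plot_id, x, y and one 0/1 observation column per
    species code.  Plots falling off-grid or on nodata cells are excluded
    (logged); returns the accuracy_report frame.
    """
    species = [c for c in psd_stack.species if c in plots.columns]
    if not species:
        raise ValueError("no species columns shared between stack and plots")
    tables: dict[str, ContingencyTable] = {}
    for code in species:
        surf = psd_stack[code]
        pred, obs = [], []
        dropped = 0
        for _, row in plots.iterrows():
            val = surf.value_at(float(row["x"]), float(row["y"]))
            if val is None or np.isnan(val):
                dropped += 1
                continue
            pred.append(val > threshold)
            obs.append(bool(row[code]))
        if dropped:
            logger.warning(
                "assess_stack: %d plot(s) excluded for %s (off-grid or nodata)",
                dropped, code,
            )
        tables[code] = contingency(pred, obs)
    return accuracy_report(tables)
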