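"""Presence thresholding, contingency statistics, kappa and report assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from compsd.accuracy import (
    ContingencyTable,
    accuracy_report,
    assess_stack,
    cohen_kappa,
    contingency,
    monserud_class,
    overall_accuracy,
    presence_from_psd,
    round_half_up,
)
from compsd.psd import PsdStack
from compsd.raster import RasterSurface


def brute_force_kappa(t: ContingencyTable) -> float:
    """Independent oracle: kappa from explicit marginal-product expected counts."""
    n = t.n
    observed_agree = t.n_pp + t.n_aa
    exp_pp = (t.n_pp + t.n_pa) * (t.n_pp + t.n_ap) / n
    exp_aa = (t.n_ap + t.n_aa) * (t.n_pa + t.n_aa) / n
    expected_agree = exp_pp + exp_aa
    if expected_agree == n:
        return 1.0 if observed_agree == n else 0.0
    return (observed_agree - expected_agree) / (n - expected_agree)


class TestPresence:
    def test_threshold_is_strict(self):
        assert presence_from_psd(0.26) is True
        assert presence_from_psd(0.25) is False
        assert presence_from_psd(0.0) is False

    def test_nodata_raises_for_exclusion(self):
        with pytest.raises(ValueError, match="nodata"):
            presence_from_psd(float("nan"))


class TestContingency:
    def test_enumeration(self):
        t = contingency([True, True, False, False], [True, False, True, False])
        assert (t.n_pp, t.n_pa, t.n_ap, t.n_aa) == (1, 1, 1, 1)

    def test_perfect_agreement_off_diagonal_zero(self):
        t = contingency([True, False], [True, False])
        assert t.n_pa == 0 and t.n_ap == 0

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            contingency([True], [True, False])
        with pytest.raises(ValueError, match="at least one"):
            contingency([], [])


class TestStatistics:
    def test_overall_accuracy_values(self):
        assert overall_accuracy(ContingencyTable(14, 4, 38, 102)) == pytest.approx(
            73.4, abs=0.05
        )
        assert overall_accuracy(ContingencyTable(50, 0, 0, 50)) == 100.0
        assert overall_accuracy(ContingencyTable(0, 10, 10, 0)) == 0.0

    def test_kappa_reference_values(self):
        assert cohen_kappa(ContingencyTable(64, 12, 62, 143)) == pytest.approx(
            0.45, abs=0.005
        )
        assert cohen_kappa(ContingencyTable(50, 0, 0, 50)) == 1.0
        assert cohen_kappa(ContingencyTable(25, 25, 25, 25)) == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            overall_accuracy(ContingencyTable(0, 0, 0, 0))

    def test_degenerate_marginals(self):
        assert cohen_kappa(ContingencyTable(10, 0, 0, 0)) == 1.0
        assert cohen_kappa(ContingencyTable(0, 0, 10, 0)) == 0.0

    def test_kappa_matches_brute_force_on_all_small_tables(self):
        # every 2x2 table with N <= 12
        for n_pp, n_pa, n_ap in itertools.product(range(13), repeat=3):
            rest = 12 - n_pp - n_pa - n_ap
            if rest < 0:
                continue
            for n_aa in range(rest + 1):
                t = ContingencyTable(n_pp, n_pa, n_ap, n_aa)
                if t.n == 0:
                    continue
                assert cohen_kappa(t) == pytest.approx(
                    brute_force_kappa(t), abs=1e-12
                )

    def test_kappa_symmetries(self):
        t = ContingencyTable(14, 4, 38, 102)
        swapped = ContingencyTable(14, 38, 4, 102)  # transpose roles
        assert cohen_kappa(t) == pytest.approx(cohen_kappa(swapped))

    def test_kappa_cross_checked_against_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pred = rng.random(60) < 0.4
            obs = rng.random(60) < 0.5
            if pred.all() or (~pred).all() or obs.all() or (~obs).all():
                continue
            t = contingency(pred, obs)
            assert cohen_kappa(t) == pytest.approx(
                cohen_kappa_score(pred, obs), abs=1e-12
            )


class TestMonserudScale:
    @pytest.mark.parametrize(
        "kappa, label",
        [(0.10, "poor"), (0.199, "poor"), (0.20, "fair"), (0.39, "fair"),
         (0.45, "moderate"), (0.55, "good"), (0.78, "very good"),
         (0.85, "excellent"), (-0.3, "poor")],
    )
    def test_bins(self, kappa, label):
        assert monserud_class(kappa) == label


class TestReport:
    def test_single_species_means_equal_species_values(self):
        t = ContingencyTable(5, 0, 4, 18)
        report = accuracy_report({"sM": t})
        sp = report.iloc[0]
        ov = report.iloc[-1]
        assert ov["overall_agreement_pct"] == pytest.approx(sp["overall_agreement_pct"])
        assert ov["kappa"] == pytest.approx(sp["kappa"])

    def test_means_are_unweighted(self):
        tables = {
            "a": ContingencyTable(90, 0, 10, 0),   # 90 % on 100 plots
            "b": ContingencyTable(1, 1, 0, 0),     # 50 % on 2 plots
        }
        report = accuracy_report(tables)
        ov = report[report["species_code"] == "overall"].iloc[0]
        assert ov["overall_agreement_pct"] == pytest.approx((90.0 + 50.0) / 2)

    def test_half_up_rounding_convention(self):
        assert round_half_up(81.25, 1) == 81.3
        assert round_half_up(0.625, 2) == 0.63


class TestAssessStack:
    def test_plots_on_nodata_cells_excluded(self):
        grid = np.array([[0.9, np.nan], [0.1, 0.3]])
        stack = PsdStack({"sp": RasterSurface(grid=grid)})
        surf = stack["sp"]
        rows = []
        for (r, c), obs in [((0, 0), 1), ((0, 1), 1), ((1, 0), 0), ((1, 1), 1)]:
            x, y = surf.cell_center(r, c)
            rows.append({"plot_id": len(rows) + 1, "x": x, "y": y, "sp": obs})
        report = assess_stack(stack, pd.DataFrame(rows))
        sp = report.iloc[0]
        assert sp["n_plots"] == 3  # the nodata plot is dropped
        assert sp["overall_agreement_pct"] == pytest.approx(100.0)

    def test_no_shared_species_rejected(self):
        stack = PsdStack({"sp": RasterSurface(grid=np.full((2, 2), 0.5))})
        with pytest.raises(ValueError, match="no species columns"):
            assess_stack(stack, pd.DataFrame({"plot_id": [1], "x": [35.0], "y": [35.0]}))
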