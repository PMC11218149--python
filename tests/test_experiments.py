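"""Study orchestration and report rendering."""

import numpy as np
import pandas as pd
import pytest

from slicefill import reference_tables as rt
from slicefill.completion_net import NetworkSpec, TrainConfig
from slicefill.experiments import (
    GapSweepResult,
    compare_to_inter_rater,
    render_report,
    run_automatic_study,
    run_gap_sweep,
    run_inter_rater_study,
    sweep_to_patient_table,
)
from slicefill.metrics import aggregate
from slicefill.phantom import generate_cohort

from conftest import small_phantom_config


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(3, seed=6, base=small_phantom_config(), rater_targets=None)


class TestInterRaterStudy:
    def test_identical_raters_give_unity(self, cohort):
        reports = run_inter_rater_study(cohort)  # rater2 == reference here
        for rep in reports.values():
            assert (rep.table.inter_rater == 1.0).all()

    def test_row_count_matches_cohort(self, cohort):
        reports = run_inter_rater_study(cohort)
        assert all(len(r.table) == len(cohort) for r in reports.values())

    def test_calibrated_raters_reproduce_agreement_regime(self):
        calibrated = generate_cohort(14, seed=8, base=small_phantom_config(),
                                     rater_targets=(0.95, 0.87))
        reports = run_inter_rater_study(calibrated)
        assert float(reports["tumor"].mean().iloc[0]) == pytest.approx(0.95, abs=0.02)
        assert float(reports["kidney"].mean().iloc[0]) == pytest.approx(0.87, abs=0.02)


class TestAutomaticStudy:
    def test_report_contract(self, cohort):
        reports = run_automatic_study(cohort, NetworkSpec(depth=2, base_channels=4),
                                      TrainConfig(epochs=2, batch_size=8, seed=0))
        for rep in reports.values():
            assert len(rep.table) == 3
            assert rep.table.automatic.between(0, 1).all()
            assert len(set(rep.table.attrs["fingerprints"])) == 3


class TestGapSweep:
    def test_interp_sweep_contract(self, cohort):
        sweep = run_gap_sweep(cohort, [1, 5, 10], backend="interp")
        assert set(sweep.table.gap) == {1, 5, 10}
        assert sweep.table.dice.between(0, 1).all()
        assert sweep.time_saving_row() == {1: 33, 5: 71, 10: 83}

    def test_constant_shape_is_exact_at_every_gap(self):
        # slice-constant anatomy: interpolation reproduces ground truth
        from slicefill.phantom import CohortPatient
        from slicefill.volume_io import LabelMap, Volume

        sl = np.zeros((30, 30), np.int16)
        sl[8:22, 8:22] = 1
        sl[12:18, 12:18] = 2
        labels = np.repeat(sl[None], 14, axis=0)
        patient = CohortPatient(Volume(np.zeros((14, 30, 30), np.float32)),
                                LabelMap(labels), LabelMap(labels.copy()), None)
        sweep = run_gap_sweep([patient], list(range(1, 11)), backend="interp",
                              eval_scope="withheld", extent=None)
        assert (sweep.table.dice == 1.0).all()

    def test_empty_gap_list_rejected(self, cohort):
        with pytest.raises(ValueError):
            run_gap_sweep(cohort, [])


class TestCompareToInterRater:
    @staticmethod
    def _sweep(mean_by_gap):
        rows = [{"patient": 1, "structure": s, "gap": g, "dice": v}
                for s in ("kidney", "tumor") for g, v in mean_by_gap.items()]
        return GapSweepResult(table=pd.DataFrame(rows), backend="interp", eval_scope="all")

    @staticmethod
    def _inter(value):
        rep = aggregate(pd.DataFrame({"inter_rater": [value]}))
        return {"kidney": rep, "tumor": rep}

    def test_planted_crossing_recovered(self):
        # means fall below the 0.95 reference after gap 7
        means = {g: 0.99 - 0.006 * g for g in range(1, 11)}
        assert all(round(means[g], 2) >= 0.95 for g in range(1, 8))
        assert round(means[8], 2) < 0.95
        result = compare_to_inter_rater(self._sweep(means), self._inter(0.95))
        assert result == {"kidney": 7, "tumor": 7}

    def test_all_above_returns_largest_gap(self):
        result = compare_to_inter_rater(self._sweep({1: 0.99, 5: 0.99, 10: 0.99}),
                                        self._inter(0.9))
        assert result == {"kidney": 10, "tumor": 10}

    def test_all_below_returns_none(self):
        result = compare_to_inter_rater(self._sweep({1: 0.5, 5: 0.4}), self._inter(0.95))
        assert result == {"kidney": None, "tumor": None}


class TestRenderReport:
    def test_published_tumor_table_footer(self):
        rendered = render_report(rt.tumor_table())
        lines = rendered["csv"].strip().splitlines()
        avg = next(l for l in lines if l.startswith("Average"))
        assert avg.split(",")[1:] == ["0.95", "0.69", "0.97", "0.95", "0.94"]
        saving = next(l for l in lines if "time saving" in l)
        assert saving.split(",")[1:] == ["0%", "100%", "33%", "71%", "83%"]

    def test_published_kidney_table_footer(self):
        rendered = render_report(rt.kidney_table())
        avg = next(l for l in rendered["csv"].strip().splitlines()
                   if l.startswith("Average"))
        assert avg.split(",")[1:] == ["0.87", "0.27", "0.94", "0.91", "0.86"]

    def test_markdown_contains_patients_and_footer(self):
        md = render_report(rt.tumor_table())["markdown"]
        assert "Average" in md and "Estimated time saving" in md

    def test_footer_is_consistent_with_aggregate(self, cohort):
        sweep = run_gap_sweep(cohort, [1, 5], backend="interp")
        table = sweep_to_patient_table(sweep, "tumor")
        rendered = render_report(table)
        avg_line = next(l for l in rendered["csv"].splitlines() if l.startswith("Average"))
        expected = aggregate(table).rounded_mean()
        assert avg_line.split(",")[1:] == [f"{v:.2f}" for v in expected]

    def test_no_gap_columns_still_valid(self):
        table = rt.tumor_table()[["inter_rater", "automatic"]]
        rendered = render_report(table)
        assert "gap" not in rendered["csv"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            render_report(pd.DataFrame())
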