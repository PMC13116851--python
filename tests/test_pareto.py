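"""FLOPs accounting, Pareto frontier, and the margin-based selection rule."""

import numpy as np
import pytest

from viewgate.benchmarks import (FLY_BASELINE_FLOPS, FLY_N_VIEWS,
                                 MOSQUITO_BASELINE_FLOPS, MOSQUITO_N_VIEWS,
                                 fly_sweep_table, mosquito_sweep_table)
from viewgate.pareto import (ParetoTable, SweepRecord, accuracy_drop,
                             flops_saved_pct, flops_total, label_configurations,
                             pareto_frontier, run_sweep, select_recommended,
                             table_from_dataframe, table_to_dataframe)


def brute_force_frontier(records):
    """O(n^2) pairwise dominance oracle."""
    kept = []
    for r in records:
        dominated = False
        for o in records:
            if o is r:
                continue
            if o.accuracy >= r.accuracy and o.flops <= r.flops and (
                    o.accuracy > r.accuracy or o.flops < r.flops):
                dominated = True
                break
        if not dominated:
            kept.append(r)
    return kept


def _rec(lam, n, acc, flops):
    return SweepRecord(lambda_sparsity=lam, retained_views=(),
                       view_count=n, accuracy=acc, flops=flops)


class TestFlops:
    def test_fly_survey_costs(self):
        per_view = FLY_BASELINE_FLOPS / FLY_N_VIEWS
        assert per_view == pytest.approx(1.413750)
        assert flops_total(5, per_view) == 7.07
        assert flops_total(7, per_view) == 9.90
        assert flops_total(3, per_view) == 4.24
        assert flops_total(0, per_view) == 0.0

    def test_mosquito_survey_costs(self):
        per_view = MOSQUITO_BASELINE_FLOPS / MOSQUITO_N_VIEWS
        assert flops_total(2, per_view) == 9.01
        assert flops_total(9, per_view) == 40.55
        assert flops_total(3, per_view) == 13.52

    def test_saved_percentages(self):
        assert flops_saved_pct(11.31, 7.07) == 37.49
        assert flops_saved_pct(49.56, 9.01) == 81.82
        assert flops_saved_pct(5.0, 5.0) == 0.0

    def test_saved_requires_positive_baseline(self):
        with pytest.raises(ValueError):
            flops_saved_pct(0.0, 0.0)

    def test_linearity_identity(self):
        # saved(b, total(k)) == (1 - k/N) * 100 up to cell rounding
        per_view = FLY_BASELINE_FLOPS / FLY_N_VIEWS
        for k in range(FLY_N_VIEWS + 1):
            saved = flops_saved_pct(FLY_BASELINE_FLOPS,
                                    flops_total(k, per_view))
            assert saved == pytest.approx((1 - k / FLY_N_VIEWS) * 100,
                                          abs=0.05)


class TestAccuracyDrop:
    def test_printed_drops(self):
        assert accuracy_drop(87.04, 86.11) == 0.93
        assert accuracy_drop(87.04, 84.26) == 2.78
        assert accuracy_drop(55.5, 55.5) == 0.0

    def test_negative_when_config_beats_baseline(self):
        assert accuracy_drop(80.0, 82.5) == -2.5

    def test_range_validation(self):
        with pytest.raises(ValueError):
            accuracy_drop(101.0, 50.0)


class TestFrontier:
    def test_single_record_is_its_own_frontier(self):
        r = _rec(0.1, 3, 90.0, 10.0)
        assert pareto_frontier([r]) == [r]

    def test_strict_dominance(self):
        a, b = _rec(0.1, 2, 90.0, 10.0), _rec(0.2, 3, 80.0, 12.0)
        assert pareto_frontier([a, b]) == [a]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            records = [_rec(0.1 * i, i % 8 + 1,
                            float(np.round(rng.uniform(50, 100), 2)),
                            float(np.round(rng.uniform(1, 12), 2)))
                       for i in range(20)]
            got = pareto_frontier(records)
            expected = brute_force_frontier(records)
            assert {id(r) for r in got} == {id(r) for r in expected}
            flops = [r.flops for r in got]
            assert flops == sorted(flops)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pareto_frontier([])


class TestSelection:
    def test_fly_table_recommends_five_parts_at_lambda_04(self):
        table = fly_sweep_table(as_table=True)
        rec = select_recommended(table, margin_pp=1.0)
        assert rec.lambda_sparsity == 0.4
        assert rec.view_count == 5
        assert rec.accuracy == 86.11

    def test_mosquito_table_recommends_two_parts_at_lambda_020(self):
        table = mosquito_sweep_table(as_table=True)
        rec = select_recommended(table, margin_pp=1.0)
        assert rec.lambda_sparsity == 0.20
        assert rec.view_count == 2

    def test_baseline_only_table_returns_baseline(self):
        base = _rec(0.0, 8, 90.0, 11.31)
        table = ParetoTable(records=[base], baseline=base,
                            per_view_flops=11.31 / 8, n_views=8)
        assert select_recommended(table) is base

    def test_no_qualifier_falls_back_to_baseline(self):
        base = _rec(0.0, 4, 90.0, 8.0)
        worse = _rec(0.3, 2, 70.0, 4.0)
        table = ParetoTable(records=[base, worse], baseline=base,
                            per_view_flops=2.0, n_views=4)
        assert select_recommended(table) is base

    def test_selected_record_lies_on_qualifying_frontier(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            per_view = 1.5
            records = [_rec(round(0.1 * (i + 1), 1), n,
                            float(np.round(rng.uniform(80, 95), 2)),
                            n * per_view)
                       for i, n in enumerate(rng.integers(1, 9, 6))]
            base = _rec(0.0, 8, 90.0, 8 * per_view)
            table = ParetoTable(records=[base] + records, baseline=base,
                                per_view_flops=per_view, n_views=8)
            rec = select_recommended(table, margin_pp=1.0)
            qualifying = [r for r in table.records
                          if accuracy_drop(base.accuracy, r.accuracy) <= 1.0]
            if qualifying:
                assert rec in pareto_frontier(qualifying)


class TestLabels:
    def test_fly_labels_match_published_column(self):
        table = label_configurations(fly_sweep_table(as_table=True))
        by_count = {r.view_count: r.label for r in table.records}
        assert by_count == {8: "all-view", 7: "reduced", 5: "recommended",
                            3: "aggressive", 1: "single-view"}

    def test_mosquito_labels_match_published_column(self):
        table = label_configurations(mosquito_sweep_table(as_table=True))
        labels = {r.lambda_sparsity: r.label for r in table.records}
        assert labels[0.0] == "all-view"
        for lam in (0.05, 0.10, 0.15):
            assert labels[lam] == "reduced"
        assert labels[0.20] == "recommended"
        assert labels[0.25] == "single-view"

    def test_labelling_idempotent(self):
        table = label_configurations(fly_sweep_table(as_table=True))
        before = [r.label for r in table.records]
        label_configurations(table)
        assert [r.label for r in table.records] == before

    def test_one_record_table_is_all_view(self):
        base = _rec(0.0, 6, 91.0, 6.0)
        table = ParetoTable(records=[base], baseline=base, per_view_flops=1.0,
                            n_views=6)
        label_configurations(table)
        assert base.label == "all-view"


class TestRunSweep:
    def test_stub_trainer_produces_table(self):
        outcomes = {0.0: (90.0, ("a", "b", "c")), 0.1: (89.5, ("a", "b")),
                    0.2: (80.0, ("a",))}

        def trainer(lam):
            return outcomes[lam]

        table = run_sweep([0.1, 0.2], trainer, ["a", "b", "c"],
                          per_view_flops=2.0)
        assert len(table.records) == 3
        assert table.baseline.view_count == 3
        rec = select_recommended(table)
        assert rec.view_count == 2  # 0.5 pp drop is within the margin

    def test_single_lambda_grid_gives_two_records(self):
        table = run_sweep([0.3], lambda lam: (90.0, ("a", "b")), ["a", "b"],
                          per_view_flops=1.0)
        assert len(table.records) == 2

    def test_failed_run_marked_but_table_survives(self):
        def trainer(lam):
            if lam == 0.2:
                raise RuntimeError("diverged")
            return 90.0, ("a",)

        table = run_sweep([0.1, 0.2], trainer, ["a"], per_view_flops=1.0)
        failed = [r for r in table.records if r.failed]
        assert len(failed) == 1 and failed[0].lambda_sparsity == 0.2
        assert len(table.ok_records()) == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_sweep([], lambda lam: (0, ()), ["a"], per_view_flops=1.0)


class TestTableIO:
    def test_report_round_trip_preserves_selection(self):
        df = table_to_dataframe(label_configurations(
            fly_sweep_table(as_table=True)))
        rebuilt = table_from_dataframe(df, n_views=FLY_N_VIEWS)
        rec = select_recommended(rebuilt)
        assert rec.view_count == 5 and rec.lambda_sparsity == 0.4

    def test_multi_lambda_cell_expands(self):
        table = fly_sweep_table(as_table=True)
        lams = sorted(r.lambda_sparsity for r in table.records)
        assert lams == [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]

    def test_missing_columns_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError, match="missing columns"):
            table_from_dataframe(pd.DataFrame({"λ": [0.1]}))
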