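import json

import numpy as np
import pytest

import translasso as tl
from translasso.cv import CVGrid, CVRecord

from conftest import brute_force_auc


def _table(rows):
    ids = [r[0] for r in rows]
    return tl.SampleTable(
        ids,
        np.array([r[1] for r in rows], dtype=object),
        np.array([r[2] for r in rows], dtype=object),
        np.array([r[3] for r in rows], dtype=np.int64),
    )


@pytest.fixture
def mixed_table():
    rows = []
    for i in range(10):
        rows.append((f"ctl{i}", "control", "adult" if i % 2 else "child", 0))
    for i in range(10):
        rows.append((f"uc{i}", "UC", "adult" if i % 2 else "child", i % 5))
    for i in range(10):
        rows.append((f"cd{i}", "CD", "adult" if i % 2 else "child", i % 5))
    return _table(rows)


class TestBuildContrast:
    def test_uc_vs_control_excludes_cd(self, mixed_table):
        _, mask, labels = tl.build_contrast(mixed_table, "UC_vs_control")
        included = [s for s, m in zip(mixed_table.sample_ids, mask) if m]
        assert all(not s.startswith("cd") for s in included)
        assert labels.sum() == 10  # UC cases
        assert (labels == 0).sum() == 10  # controls

    def test_children_contrast_excludes_adults(self, mixed_table):
        _, mask, _ = tl.build_contrast(mixed_table, "IBD_vs_control_children")
        ages = mixed_table.age_group[mask]
        assert set(ages) == {"child"}

    def test_active_contrast_controls_and_remission(self, mixed_table):
        _, mask, labels = tl.build_contrast(mixed_table, "active_IBD")
        ids = np.array(mixed_table.sample_ids, dtype=object)[mask]
        act = mixed_table.activity[mask]
        diag = mixed_table.diagnosis[mask]
        # cases: grades 3-4; control class: controls plus remission (0-1);
        # grade 2 excluded by default
        assert np.all(act[labels == 1] >= 3)
        assert np.all((diag[labels == 0] == "control") | (act[labels == 0] <= 1))
        assert 2 not in set(act)
        assert len(ids) == len(labels)

    def test_all_cases_active_leaves_controls_only(self):
        rows = [(f"c{i}", "control", "adult", 0) for i in range(5)]
        rows += [(f"u{i}", "UC", "adult", 4) for i in range(5)]
        table = _table(rows)
        _, mask, labels = tl.build_contrast(table, "active_UC")
        assert labels.sum() == 5
        assert (labels == 0).sum() == 5  # only the controls

    def test_empty_class_raises(self):
        rows = [(f"c{i}", "control", "adult", 0) for i in range(4)]
        table = _table(rows)
        with pytest.raises(tl.TranslassoError, match="UC_vs_control"):
            tl.build_contrast(table, "UC_vs_control")

    def test_unknown_name_rejected(self, mixed_table):
        with pytest.raises(tl.ValidationError, match="unknown contrast"):
            tl.build_contrast(mixed_table, "UC_vs_everything")

    def test_twelve_builtin_contrasts(self):
        assert len(tl.CONTRAST_NAMES) == 12


class TestAssignFolds:
    def test_exact_stratification_when_divisible(self):
        labels = np.array([1] * 50 + [0] * 50)
        folds = tl.assign_folds(labels, 10, seed=0)
        for f in range(10):
            assert (labels[folds == f] == 1).sum() == 5
            assert (labels[folds == f] == 0).sum() == 5

    def test_within_one_of_proportion(self):
        labels = np.array([1] * 52 + [0] * 48)
        folds = tl.assign_folds(labels, 10, seed=1)
        for f in range(10):
            assert (labels[folds == f] == 1).sum() in (5, 6)
            assert (labels[folds == f] == 0).sum() in (4, 5)

    def test_deterministic_given_seed(self):
        labels = np.array([0, 1] * 30)
        f1 = tl.assign_folds(labels, 10, seed=7)
        f2 = tl.assign_folds(labels, 10, seed=7)
        assert np.array_equal(f1, f2)
        assert not np.array_equal(f1, tl.assign_folds(labels, 10, seed=8))

    def test_small_class_raises(self):
        labels = np.array([1] * 5 + [0] * 50)
        with pytest.raises(tl.TranslassoError, match="folds"):
            tl.assign_folds(labels, 10, seed=0)


class TestAUC:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
            ([0.3, 0.7], [1, 0], 0.0),
            ([0.9, 0.5, 0.5, 0.1], [1, 1, 0, 0], 0.875),  # tie counts 1/2
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert tl.auc(np.array(scores), np.array(labels)) == expected

    def test_one_class_rejected(self):
        with pytest.raises(tl.ValidationError):
            tl.auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = np.round(rng.random(60), 1)  # many ties
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        assert tl.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_delong_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(4)
        labels = np.array([1] * 30 + [0] * 30)
        scores = labels + rng.normal(0, 1.0, 60)
        a, lo, hi = tl.auc_ci_delong(scores, labels, 0.90)
        assert lo <= a <= hi
        assert a == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


def _toy_grid(entries, lambda_grid, n_folds):
    """Build a CVGrid from (fold, lam, auc, active, converged) tuples."""
    records = [
        CVRecord(
            fold=f, lam=l, auc=a, active_genes=act, converged=c,
            beta=np.zeros(1), intercept=0.0,
        )
        for f, l, a, act, c in entries
    ]
    return CVGrid(records, np.zeros(1, dtype=np.int64), lambda_grid, n_folds)


class TestSelectLambda:
    def test_largest_lambda_within_tolerance(self):
        cfg = tl.PipelineConfig(lambda_grid=(0.1, 0.2, 0.3), lambda_tolerance=0.01)
        grid = _toy_grid(
            [
                (0, 0.1, 0.85, [], True),
                (0, 0.2, 0.85, [], True),
                (0, 0.3, 0.80, [], True),
            ],
            (0.1, 0.2, 0.3),
            1,
        )
        lam, table = tl.select_lambda(grid, cfg)
        assert lam == 0.2
        assert table == {0.1: 0.85, 0.2: 0.85, 0.3: 0.80}

    def test_single_eligible_lambda(self):
        cfg = tl.PipelineConfig(lambda_grid=(0.1, 0.2))
        grid = _toy_grid(
            [(0, 0.1, 0.9, [], True), (0, 0.2, 0.4, [], True)], (0.1, 0.2), 1
        )
        lam, _ = tl.select_lambda(grid, cfg)
        assert lam == 0.1

    def test_null_cutoff_filters_folds_before_median(self):
        cfg = tl.PipelineConfig(lambda_grid=(0.1,), n_folds=3)
        grid = _toy_grid(
            [
                (0, 0.1, 0.4, [], True),
                (1, 0.1, 0.6, [], True),
                (2, 0.1, 0.8, [], True),
            ],
            (0.1,),
            3,
        )
        _, table = tl.select_lambda(grid, cfg)
        assert table[0.1] == pytest.approx(0.7)  # median over (0.6, 0.8)

    def test_nonconverged_fits_excluded_from_selection(self):
        cfg = tl.PipelineConfig(lambda_grid=(0.1, 0.2))
        grid = _toy_grid(
            [(0, 0.1, 0.7, [], True), (0, 0.2, 0.99, [], False)], (0.1, 0.2), 1
        )
        lam, table = tl.select_lambda(grid, cfg)
        assert lam == 0.1
        assert 0.2 not in table

    def test_no_eligible_lambda_raises(self):
        cfg = tl.PipelineConfig(lambda_grid=(0.1,))
        grid = _toy_grid([(0, 0.1, 0.45, [], True)], (0.1,), 1)
        with pytest.raises(tl.TranslassoError, match="null cutoff"):
            tl.select_lambda(grid, cfg)


class TestOccurrenceCounts:
    def test_hand_tally(self):
        grid = _toy_grid(
            [
                (0, 0.1, 0.9, ["a", "b"], True),
                (1, 0.1, 0.9, ["a"], True),
                (0, 0.2, 0.9, ["a"], False),  # non-converged still counted
                (1, 0.2, 0.9, [], True),
            ],
            (0.1, 0.2),
            2,
        )
        counts = tl.occurrence_counts(grid)
        assert counts == {"a": 3, "b": 1}

    def test_never_active_gene_is_absent(self):
        grid = _toy_grid([(0, 0.1, 0.9, ["a"], True)], (0.1,), 1)
        assert tl.occurrence_counts(grid).get("z", 0) == 0

    def test_invariant_to_record_order(self):
        entries = [
            (0, 0.1, 0.9, ["a", "b"], True),
            (1, 0.1, 0.8, ["b"], True),
            (0, 0.2, 0.7, ["a"], True),
        ]
        g1 = _toy_grid(entries, (0.1, 0.2), 2)
        g2 = _toy_grid(entries[::-1], (0.1, 0.2), 2)
        assert tl.occurrence_counts(g1) == tl.occurrence_counts(g2)


@pytest.fixture(scope="module")
def small_run(small_cohort_module):
    cm, table, truth, nm = small_cohort_module
    config = tl.PipelineConfig(n_folds=5, rng_seed=3)
    _, mask, labels = tl.build_contrast(table, "IBD_vs_control", config)
    sub = tl.NormalizedMatrix(
        list(nm.gene_ids),
        [s for s, m in zip(nm.sample_ids, mask) if m],
        nm.values[:, mask],
        nm.size_factors[mask],
    )
    selection = tl.preselect(sub, config.n_pcs, config.pc_variance_fraction)
    grid = tl.run_cv_grid(sub, selection, labels, config)
    lam, _ = tl.select_lambda(grid, config)
    report = tl.finalize(sub, selection, labels, lam, grid, config, "IBD_vs_control")
    return config, sub, selection, labels, grid, report


@pytest.fixture(scope="module")
def small_cohort_module():
    spec = tl.SimulationSpec(
        n_genes=300, n_cases=40, n_controls=40, n_signal_genes=10, seed=11
    )
    cm, table, truth = tl.simulate_dataset(spec)
    nm = tl.preprocess_counts(cm, 10)
    return cm, table, truth, nm


class TestGridAndFinalize:
    def test_grid_has_folds_times_lambdas_records(self, small_run):
        config, _, _, _, grid, _ = small_run
        assert len(grid.records) == config.n_folds * len(config.lambda_grid)

    def test_empty_fits_score_half_by_tie_convention(self, small_run):
        config, _, _, _, grid, _ = small_run
        for r in grid.records:
            if not r.active_genes:
                assert r.auc == 0.5  # constant scores, ties counted 1/2

    def test_model_table_well_formed(self, small_run):
        config, _, _, _, _, report = small_run
        t = report.model_table
        assert (t["coefficient"].abs() <= config.coef_upper + 1e-12).all()
        assert (t["occurrence_n"] >= 1).all()
        assert list(t["coefficient"]) == sorted(t["coefficient"], reverse=True)
        assert report.ci_lower <= report.final_auc <= report.ci_upper

    def test_occurrence_ceiling(self, small_run):
        config, _, _, _, grid, report = small_run
        ceiling = config.n_folds * len(config.lambda_grid)
        assert all(0 < v <= ceiling for v in report.occurrence.values())

    def test_report_round_trips_through_writer(self, small_run, tmp_path):
        import pandas as pd

        config, _, _, _, grid, report = small_run
        tl.write_report(report, grid, tmp_path)
        model = pd.read_csv(tmp_path / "model.tsv", sep="\t")
        assert list(model["gene"]) == list(report.model_table["gene"])
        np.testing.assert_allclose(
            model["coefficient"], report.model_table["coefficient"], rtol=1e-9
        )
        cv = pd.read_csv(tmp_path / "cv.tsv", sep="\t")
        assert len(cv) == len(grid.records)
        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["selected_lambda"] == report.selected_lambda
        assert summary["auc"] == report.final_auc

    def test_flipping_held_out_label_leaves_training_fits_unchanged(
        self, small_cohort_module
    ):
        cm, table, truth, nm = small_cohort_module
        config = tl.PipelineConfig(
            n_folds=4, rng_seed=5, lambda_grid=(0.05, 0.1, 0.2)
        )
        _, mask, labels = tl.build_contrast(table, "IBD_vs_control", config)
        sub = tl.NormalizedMatrix(
            list(nm.gene_ids),
            [s for s, m in zip(nm.sample_ids, mask) if m],
            nm.values[:, mask],
            nm.size_factors[mask],
        )
        selection = tl.preselect(sub, config.n_pcs, config.pc_variance_fraction)
        folds = tl.assign_folds(labels, config.n_folds, seed=9)
        grid1 = tl.run_cv_grid(sub, selection, labels, config, folds=folds)
        flipped = labels.copy()
        victim = int(np.flatnonzero(folds == 0)[0])
        flipped[victim] = 1 - flipped[victim]
        grid2 = tl.run_cv_grid(sub, selection, flipped, config, folds=folds)
        r1 = [r for r in grid1.records if r.fold == 0]
        r2 = [r for r in grid2.records if r.fold == 0]
        auc_changed = False
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.beta, b.beta)  # fits identical
            assert a.intercept == b.intercept
            if a.auc != b.auc:
                auc_changed = True
        assert auc_changed  # the held-out evaluation did see the flip
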