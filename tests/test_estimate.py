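"""PES estimators, imbalance diagnostics, screening, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peskit import (
    Central,
    Congruency,
    Correction,
    EstimationError,
    FilterConfig,
    Method,
    Role,
    Rsi,
    ScreeningCriteria,
    apply_filters,
    cell_statistics,
    classify_trials,
    constraint_relaxation_imbalance,
    expected_post_correct_counts,
    group_aggregate,
    imbalance_summary,
    mean_bias,
    multilevel_bootstrap_ci,
    pes_bias,
    pes_estimate,
    screen_participant,
)
from peskit.estimate import PESEstimate, RelaxationMode

from conftest import CON, INCON, make_dataset, worked_example_dataset

NO_MAD = FilterConfig(use_mad=False)


def cells_for(dataset, central=Central.MEAN):
    labels = apply_filters(dataset, classify_trials(dataset), NO_MAD)
    return cell_statistics(dataset, labels, central)


def cell_value(cells, role, rsi, congruency):
    for c in cells:
        if c.trial_type is role and c.rsi is rsi and c.congruency is congruency:
            return c
    return None


class TestWorkedExample:
    """The hypothetical 20-error participant with known cell compositions."""

    def test_balanced_robust_uncorrected_is_100ms(self, balanced_example):
        est = pes_estimate(cells_for(balanced_example), method=Method.ROBUST,
                           correction=Correction.UNCORRECTED, rsi=Rsi.LONG)
        assert est.pes_ms == pytest.approx(100.0)
        assert est.baseline_ms == pytest.approx(1100.0)
        assert est.post_error_ms == pytest.approx(1200.0)

    def test_imbalanced_robust_uncorrected_is_inflated_to_150ms(self, imbalanced_example):
        est = pes_estimate(cells_for(imbalanced_example), method=Method.ROBUST,
                           correction=Correction.UNCORRECTED, rsi=Rsi.LONG)
        assert est.baseline_ms == pytest.approx(1050.0)  # pooled pre-error mean
        assert est.pes_ms == pytest.approx(150.0)

    def test_imbalanced_robust_corrected_recovers_100ms(self, imbalanced_example):
        est = pes_estimate(cells_for(imbalanced_example), method=Method.ROBUST,
                           correction=Correction.CORRECTED, rsi=Rsi.LONG)
        assert est.baseline_ms == pytest.approx(1100.0)  # mean of condition means
        assert est.pes_ms == pytest.approx(100.0)

    def test_median_based_uncorrected_is_200ms(self, imbalanced_example):
        cells = cells_for(imbalanced_example, Central.MEDIAN)
        pooled_pre = cell_value(cells, Role.PRE_ERROR, Rsi.LONG, None)
        assert pooled_pre.value_ms == pytest.approx(1000.0)
        est = pes_estimate(cells, method=Method.ROBUST,
                           correction=Correction.UNCORRECTED,
                           central=Central.MEDIAN, rsi=Rsi.LONG)
        assert est.post_error_ms == pytest.approx(1200.0)
        assert est.pes_ms == pytest.approx(200.0)

    def test_mean_bias_pairs(self, balanced_example, imbalanced_example):
        def pair(ds, central):
            cells = cells_for(ds, central)
            kw = dict(method=Method.ROBUST, central=central, rsi=Rsi.LONG)
            return (
                pes_estimate(cells, correction=Correction.UNCORRECTED, **kw),
                pes_estimate(cells, correction=Correction.CORRECTED, **kw),
            )

        assert pes_bias(*pair(balanced_example, Central.MEAN)) == pytest.approx(0.0)
        assert pes_bias(*pair(imbalanced_example, Central.MEAN)) == pytest.approx(50.0)
        assert pes_bias(*pair(imbalanced_example, Central.MEDIAN)) == pytest.approx(100.0)

    def test_bias_matches_cellwise_analytic_prediction(self, imbalanced_example):
        """uncorr - corr == mean_bias(baseline cell) - mean_bias(post cell)."""
        cells = cells_for(imbalanced_example)
        pre_con = cell_value(cells, Role.PRE_ERROR, Rsi.LONG, CON)
        pre_incon = cell_value(cells, Role.PRE_ERROR, Rsi.LONG, INCON)
        interference = pre_incon.value_ms - pre_con.value_ms
        p_con = pre_con.n_trials / (pre_con.n_trials + pre_incon.n_trials)
        predicted = mean_bias(interference, p_con) - mean_bias(200.0, 0.5)
        kw = dict(method=Method.ROBUST, rsi=Rsi.LONG)
        observed = pes_bias(
            pes_estimate(cells, correction=Correction.UNCORRECTED, **kw),
            pes_estimate(cells, correction=Correction.CORRECTED, **kw),
        )
        assert observed == pytest.approx(predicted)


class TestCellStatistics:
    def test_constant_cell(self):
        ds = worked_example_dataset([(CON, 1000.0, 10)], [(CON, 1100.0, 10)])
        cells = cells_for(ds)
        cell = cell_value(cells, Role.PRE_ERROR, Rsi.LONG, CON)
        assert cell.value_ms == pytest.approx(1000.0)
        assert cell.n_trials == 10

    def test_empty_cells_absent_and_estimator_raises(self):
        ds = worked_example_dataset([(CON, 1000.0, 3)], [(CON, 1100.0, 3)])
        cells = cells_for(ds)
        assert cell_value(cells, Role.PRE_ERROR, Rsi.LONG, INCON) is None
        with pytest.raises(EstimationError, match="incongruent"):
            pes_estimate(cells, method=Method.ROBUST,
                         correction=Correction.CORRECTED, rsi=Rsi.LONG)
        with pytest.raises(EstimationError, match="pooled"):
            pes_estimate(cells, method=Method.ROBUST,
                         correction=Correction.UNCORRECTED, rsi=Rsi.SHORT)

    def test_even_count_median_uses_midpoint(self):
        ds = worked_example_dataset([(CON, 1000.0, 1), (INCON, 1200.0, 1)],
                                    [(CON, 1100.0, 2)])
        cells = cells_for(ds, Central.MEDIAN)
        assert cell_value(cells, Role.PRE_ERROR, Rsi.LONG, None).value_ms == 1100.0

    @given(
        con=st.lists(st.floats(200, 1400), min_size=1, max_size=20),
        incon=st.lists(st.floats(200, 1400), min_size=1, max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_pooled_minus_unweighted_identity(self, con, incon):
        """pooled - unweighted == (p_con - 1/2)(mean_con - mean_incon) exactly."""
        pooled = np.mean(con + incon)
        unweighted = (np.mean(con) + np.mean(incon)) / 2
        p_con = len(con) / (len(con) + len(incon))
        identity = (p_con - 0.5) * (np.mean(con) - np.mean(incon))
        assert pooled - unweighted == pytest.approx(identity, abs=1e-9)

    def test_corrected_invariant_to_cell_composition(self):
        """Resampling congruency proportions moves uncorrected, not corrected."""
        kw = dict(method=Method.ROBUST, rsi=Rsi.LONG)
        results = {}
        for n_con, n_incon in [(10, 10), (15, 5), (18, 2)]:
            ds = worked_example_dataset(
                [(CON, 1000.0, n_con), (INCON, 1200.0, n_incon)],
                [(CON, 1100.0, 10), (INCON, 1300.0, 10)],
            )
            cells = cells_for(ds)
            results[(n_con, n_incon)] = (
                pes_estimate(cells, correction=Correction.CORRECTED, **kw).pes_ms,
                pes_estimate(cells, correction=Correction.UNCORRECTED, **kw).pes_ms,
            )
        assert all(v[0] == pytest.approx(100.0) for v in results.values())
        assert len({round(v[1], 6) for v in results.values()}) == 3


class TestImbalance:
    def test_equal_counts_give_50_percent(self):
        ds = worked_example_dataset([(CON, 1000.0, 5), (INCON, 1200.0, 5)],
                                    [(CON, 1100.0, 5), (INCON, 1300.0, 5)])
        labels = apply_filters(ds, classify_trials(ds), NO_MAD)
        imb = imbalance_summary(ds, labels)
        assert imb.percent_congruent[(Role.PRE_ERROR, Rsi.LONG)] == pytest.approx(50.0)

    def test_15_vs_5_gives_75_percent(self, imbalanced_example):
        labels = apply_filters(imbalanced_example, classify_trials(imbalanced_example), NO_MAD)
        imb = imbalance_summary(imbalanced_example, labels)
        assert imb.percent_congruent[(Role.PRE_ERROR, Rsi.LONG)] == pytest.approx(75.0)
        assert imb.n_congruent[(Role.PRE_ERROR, Rsi.LONG)] == 15

    def test_empty_stratum_absent(self, imbalanced_example):
        labels = apply_filters(imbalanced_example, classify_trials(imbalanced_example), NO_MAD)
        imb = imbalance_summary(imbalanced_example, labels)
        assert (Role.PRE_ERROR, Rsi.SHORT) not in imb.percent_congruent


class TestConstraintRelaxation:
    def test_all_correct_dataset_reports_absent(self):
        assert constraint_relaxation_imbalance(make_dataset("CCCC")) == {}

    def test_mode_none_counts_any_trial_before_an_error(self):
        ds = make_dataset("CE", congruencies=[CON, INCON],
                          rsis=[Rsi.SHORT, Rsi.SHORT])
        out = constraint_relaxation_imbalance(ds, RelaxationMode.NONE)
        assert out[Rsi.SHORT] == pytest.approx(100.0)

    def test_hand_built_sequence_all_modes(self):
        # positions:        1    2    3    4    5    6    7    8    9   10   11   12
        acc =             ["C", "C", "E", "E", "C", "E", "C", "C", "E", "N", "E", "C"]
        cong = [CON, CON, INCON, CON, INCON, CON, CON, INCON, CON, CON, INCON, CON]
        ds = make_dataset(acc, congruencies=cong)
        # Candidates (trial before each error, with its own / error-2 accuracy):
        #  e@3: cand 2 (C, em2 1=C)    e@4: cand 3 (E, em2 2=C)
        #  e@6: cand 5 (C, em2 4=E)    e@9: cand 8 (I, em2 7=C)
        #  e@11: cand 10 (N, em2 9=E)
        # full: cands 2(CON), 8(INCON)                      -> 1/2 congruent
        # pre_error_correct_only: 2(CON), 5(INCON), 8(INCON) -> 1/3
        # error_minus2_correct_only: 2(CON), 3(INCON), 8(INCON) -> 1/3
        # none: 2, 3, 5, 8, 10 -> CON, INCON, INCON, INCON, CON -> 2/5
        full = constraint_relaxation_imbalance(ds, RelaxationMode.FULL)
        assert full[Rsi.SHORT] == pytest.approx(50.0)
        pre_only = constraint_relaxation_imbalance(ds, RelaxationMode.PRE_ERROR_CORRECT_ONLY)
        assert pre_only[Rsi.SHORT] == pytest.approx(100 * 1 / 3)
        em2_only = constraint_relaxation_imbalance(ds, RelaxationMode.ERROR_MINUS2_CORRECT_ONLY)
        assert em2_only[Rsi.SHORT] == pytest.approx(100 * 1 / 3)
        none_mode = constraint_relaxation_imbalance(ds, RelaxationMode.NONE)
        assert none_mode[Rsi.SHORT] == pytest.approx(100 * 2 / 5)


def _screen_ready_dataset(n_per_cell=5, drop_one=False):
    """A session with n_per_cell trials in every pre/post-error x cong x RSI cell."""
    pres, posts = [], []
    for rsi in (Rsi.SHORT, Rsi.LONG):
        for cong in (CON, INCON):
            n = n_per_cell - (1 if drop_one and rsi is Rsi.SHORT and cong is CON else 0)
            pres.append((cong, 600.0 if cong is CON else 700.0, n, rsi))
            posts.append((cong, 650.0 if cong is CON else 750.0, n, rsi))
    acc, cong_l, rts, rsis = [], [], [], []
    for (pc, prt, n, rsi), (qc, qrt, m, _) in zip(pres, posts):
        for i in range(max(n, m)):
            acc += ["C", "C", "E", "C", "C"]
            # fillers alternate congruency so congruent accuracy stays high;
            # a "dropped" pre-error trial flips congruency out of its cell
            pre_cong = pc if i < n else (INCON if pc is CON else CON)
            cong_l += [CON, pre_cong, INCON, qc if i < m else CON, INCON]
            rts += [500.0, prt, 800.0, qrt, 550.0]
            rsis += [rsi] * 5
    rsis[0] = None
    return make_dataset(acc, congruencies=cong_l, rts=rts, rsis=rsis)


class TestScreening:
    def test_boundary_counts_and_accuracies_included(self):
        ds = _screen_ready_dataset(5)
        labels = apply_filters(ds, classify_trials(ds), NO_MAD)
        report = screen_participant(ds, labels)
        assert report.included, report.reasons

    def test_four_trials_in_one_cell_excludes(self):
        ds = _screen_ready_dataset(5, drop_one=True)
        labels = apply_filters(ds, classify_trials(ds), NO_MAD)
        report = screen_participant(ds, labels)
        assert not report.included
        assert "too_few_cell_trials" in report.reasons

    def test_79_percent_congruent_accuracy_excludes(self):
        """The 80% congruent-accuracy floor is a strict minimum."""
        ds = make_dataset("C" * 79 + "E" * 21, congruencies=[CON] * 100)
        labels = apply_filters(ds, classify_trials(ds), NO_MAD)
        report = screen_participant(ds, labels)
        assert not report.included
        assert "low_congruent_accuracy" in report.reasons

    def test_low_incongruent_accuracy_excludes(self):
        ds = _screen_ready_dataset(5)  # incongruent accuracy 2/3
        labels = apply_filters(ds, classify_trials(ds), NO_MAD)
        report = screen_participant(
            ds, labels, ScreeningCriteria(min_incongruent_accuracy=0.70)
        )
        assert "low_incongruent_accuracy" in report.reasons

    def test_inverted_interference_flagged(self):
        ds = _screen_ready_dataset(5)
        labels = apply_filters(ds, classify_trials(ds), NO_MAD)
        strict = screen_participant(ds, labels)
        assert "no_interference_effect" not in strict.reasons  # incon slower by design
        relaxed = screen_participant(
            ds, labels,
            ScreeningCriteria(require_interference_effect=False,
                              require_error_rate_order=False),
        )
        assert relaxed.included or "too_few_cell_trials" in relaxed.reasons


def _estimate(pid, correction, pes, method=Method.TRADITIONAL,
              central=Central.MEAN, rsi=Rsi.SHORT):
    return PESEstimate(participant_id=pid, method=method, correction=correction,
                       central=central, rsi=rsi, baseline_ms=400.0,
                       post_error_ms=400.0 + pes)


class TestGroupAggregate:
    def test_symmetric_biases_mean_zero(self):
        ests = []
        for pid, (unc, cor) in [("a", (110, 100)), ("b", (90, 100))]:
            ests.append(_estimate(pid, Correction.UNCORRECTED, unc))
            ests.append(_estimate(pid, Correction.CORRECTED, cor))
        out = group_aggregate(ests)["bias"]
        assert out["bias_mean_ms"].iloc[0] == pytest.approx(0.0)
        assert out["d_z"].iloc[0] == pytest.approx(0.0)

    def test_zero_bias_sd_gives_undefined_dz(self):
        ests = []
        for pid in "abc":
            ests.append(_estimate(pid, Correction.UNCORRECTED, 105))
            ests.append(_estimate(pid, Correction.CORRECTED, 100))
        out = group_aggregate(ests)["bias"]
        assert out["bias_mean_ms"].iloc[0] == pytest.approx(5.0)
        assert np.isnan(out["d_z"].iloc[0])
        assert out["percent_inflation"].iloc[0] == pytest.approx(5.0)

    def test_known_bias_distribution_recovered(self):
        """Monte-Carlo: mean of N(16, 23^2) biases recovered within 3 SE."""
        rng = np.random.default_rng(42)
        n = 100
        biases = rng.normal(16.0, 23.0, size=n)
        ests = []
        for i, b in enumerate(biases):
            ests.append(_estimate(f"p{i}", Correction.UNCORRECTED, 100 + b))
            ests.append(_estimate(f"p{i}", Correction.CORRECTED, 100))
        out = group_aggregate(ests)["bias"]
        assert out["bias_mean_ms"].iloc[0] == pytest.approx(np.mean(biases))
        assert abs(out["bias_mean_ms"].iloc[0] - 16.0) < 3 * 23.0 / np.sqrt(n)


class TestBootstrap:
    def test_identical_observations_zero_width(self):
        lo, hi = multilevel_bootstrap_ci([[5.0, 5.0], [5.0]], np.mean, n_iter=200, seed=1)
        assert lo == hi == 5.0

    def test_single_participant_reduces_to_ordinary_bootstrap(self):
        rng = np.random.default_rng(3)
        obs = rng.normal(10, 2, size=50)
        lo, hi = multilevel_bootstrap_ci([obs], np.mean, n_iter=500, seed=7)
        assert lo < np.mean(obs) < hi
        assert hi - lo < 3.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            multilevel_bootstrap_ci([], np.mean)
        with pytest.raises(ValueError):
            multilevel_bootstrap_ci([[1.0], []], np.mean)

    def test_two_level_coverage_near_nominal(self):
        """~95% of CIs from two-level normal data should contain the true mean."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            means = rng.normal(0.0, 1.0, size=15)
            data = [rng.normal(m, 1.0, size=20) for m in means]
            lo, hi = multilevel_bootstrap_ci(data, np.mean, n_iter=200, seed=rng)
            hits += lo <= 0.0 <= hi
        coverage = hits / n_rep
        assert 0.85 <= coverage <= 1.0


class TestExpectedPostCorrectCounts:
    def test_reference_arithmetic(self):
        assert expected_post_correct_counts(101, 4, 16) == (60.0, 36.0, 24.0)

    def test_symmetric_errors_split_evenly(self):
        total, con, incon = expected_post_correct_counts(101, 10, 10)
        assert (total, con, incon) == (60.0, 30.0, 30.0)

    def test_small_session_matches_hand_arithmetic(self):
        # 41 trials, 10 errors: total 41-20-1=20; con 20-2-5=13; incon 20-8-5=7
        assert expected_post_correct_counts(41, 2, 8) == (20.0, 13.0, 7.0)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            expected_post_correct_counts(20, 10, 10)
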