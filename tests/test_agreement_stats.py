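"""Method-agreement statistics: Bland-Altman, rank tests, errors, tables."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from sprintgc import agreement_stats as ag
from sprintgc.contacts import ContactSegment
from sprintgc.errors import ValidationError


def _pairs(gt, pred, steps=None):
    gt = np.asarray(gt, dtype=float)
    steps = steps if steps is not None else np.arange(1, gt.size + 1)
    return ag.PairedDurations(
        gt, np.asarray(pred, dtype=float), np.asarray(steps),
        np.array(["s"] * gt.size, dtype=object),
    )


def _segs(intervals):
    return [ContactSegment(a, b) for a, b in intervals]


class TestPairDurations:
    def test_perfect_detection_pairs_everything(self):
        true = _segs([(i * 60 + 10, i * 60 + 40) for i in range(10)])
        p = ag.pair_durations(true, true)
        assert len(p) == 10
        assert p.n_unmatched_pred == p.n_unmatched_true == 0
        np.testing.assert_array_equal(p.step_index, np.arange(1, 11))

    def test_spurious_prediction_excluded_and_counted(self):
        true = _segs([(i * 60 + 10, i * 60 + 40) for i in range(10)])
        pred = sorted(true + _segs([(615, 630)]), key=lambda s: s.ic)
        p = ag.pair_durations(pred, true)
        assert len(p) == 10
        assert p.n_unmatched_pred == 1

    def test_open_ended_segments_excluded(self):
        true = _segs([(10, 40)]) + [ContactSegment(60, 80, open_ended=True)]
        p = ag.pair_durations(true, true)
        assert len(p) == 1


class TestBlandAltman:
    def test_perfect_agreement(self):
        p = _pairs([100, 120, 140], [100, 120, 140])
        ba = ag.bland_altman(p)
        assert ba.bias_ms == 0 and ba.loa_low_ms == 0 and ba.loa_high_ms == 0
        assert not ba.heteroscedastic

    def test_alternating_differences_closed_form(self):
        gt = np.array([100.0, 100.0, 100.0, 100.0])
        pred = gt + np.array([4.0, -4.0, 4.0, -4.0])
        ba = ag.bland_altman(_pairs(gt, pred))
        assert ba.bias_ms == pytest.approx(0.0)
        assert ba.sd_ms == pytest.approx(np.sqrt(64.0 / 3.0))  # sample SD 4.6188
        assert ba.loa_high_ms == pytest.approx(1.96 * np.sqrt(64.0 / 3.0))
        assert ba.mean_abs_diff_ms == pytest.approx(4.0)

    def test_loa_coverage_near_95_percent(self):
        """Bland-Altman limits contain ~95% of Gaussian differences."""
        rng = np.random.default_rng(17)
        n = 4000
        gt = rng.uniform(100, 180, size=n)
        pred = gt + rng.normal(0.5, 6.0, size=n)
        p = _pairs(gt, pred, steps=np.ones(n, dtype=int))
        ba = ag.bland_altman(p)
        d = p.diffs_ms
        coverage = np.mean((d >= ba.loa_low_ms) & (d <= ba.loa_high_ms))
        assert abs(coverage - 0.95) < 0.02

    def test_heteroscedasticity_flagged(self):
        rng = np.random.default_rng(3)
        gt = rng.uniform(100, 200, size=200)
        pred = gt + rng.normal(0, 0.3 * (gt - 100) + 0.5)  # spread grows with magnitude
        ba = ag.bland_altman(_pairs(gt, pred, steps=np.ones(200, dtype=int)))
        assert ba.r_squared > 0.1
        assert ba.heteroscedastic

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            ag.bland_altman(_pairs([100, 110], [100, 110]))


def _wilcoxon_exact_oracle(d):
    """Two-sided exact signed-rank p by full sign enumeration (no ties/zeros)."""
    d = np.asarray(d, dtype=float)
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    mean_w = n * (n + 1) / 4
    p = np.mean(np.abs(stats - mean_w) >= abs(w_plus - mean_w) - 1e-9)
    return p


class TestRankStats:
    def test_constant_offset_gives_perfect_rho(self):
        gt = np.array([100, 120, 140, 160, 180], dtype=float)
        rs = ag.rank_stats(_pairs(gt, gt + 5.0))
        assert rs.spearman_rho == pytest.approx(1.0)
        assert rs.spearman_magnitude == "almost perfect"

    def test_symmetric_differences_not_significant(self):
        gt = np.linspace(100, 200, 8)
        pred = gt + np.array([4, -4, 4, -4, 4, -4, 4, -4], dtype=float)
        rs = ag.rank_stats(_pairs(gt, pred))
        assert rs.wilcoxon_p > 0.05

    def test_effect_size_bands(self):
        assert ag.effect_size_label(0.42) == "small"
        assert ag.effect_size_label(0.1) == "trivial"
        assert ag.effect_size_label(0.6) == "medium"
        assert ag.effect_size_label(0.9) == "large"

    def test_spearman_bands(self):
        assert ag.spearman_label(0.95) == "almost perfect"
        assert ag.spearman_label(0.4) == "moderate"

    def test_wilcoxon_matches_exact_enumeration(self):
        """scipy's exact signed-rank p equals brute-force sign enumeration
        for small n, validating the routine this package relies on."""
        rng = np.random.default_rng(5)
        for n in (6, 9, 12):
            d = rng.normal(1.0, 3.0, size=n)
            d = d[np.abs(d) > 1e-6]
            while np.unique(np.abs(d)).size != d.size:
                d = rng.normal(1.0, 3.0, size=n)
            p_scipy = sps.wilcoxon(d, method="exact").pvalue
            assert p_scipy == pytest.approx(_wilcoxon_exact_oracle(d), abs=1e-12)

    def test_identical_pairs_degenerate_but_defined(self):
        gt = np.array([100, 110, 120, 130, 140], dtype=float)
        rs = ag.rank_stats(_pairs(gt, gt))
        assert rs.spearman_rho == pytest.approx(1.0)
        assert rs.wilcoxon_p == 1.0
        assert rs.effect_size == 0.0


class TestErrorMeasures:
    def test_perfect_prediction(self):
        assert ag.error_measures(_pairs([100.0], [100.0])) == (0.0, 0.0)

    def test_hand_arithmetic_case(self):
        mape, rmse = ag.error_measures(_pairs([100.0, 200.0], [110.0, 190.0]))
        assert mape == pytest.approx(7.5)
        assert rmse == pytest.approx(10.0)

    def test_nonpositive_gt_rejected(self):
        with pytest.raises(ValidationError):
            ag.error_measures(_pairs([0.0], [5.0]))


class TestEventDeviations:
    def test_perfect_events_all_zero(self):
        segs = _segs([(10, 40), (70, 100)])
        np.testing.assert_array_equal(ag.event_deviation_summary(segs, segs, "IC"), [0, 0])

    def test_one_frame_late_is_plus_4ms(self):
        true = _segs([(10, 40)])
        pred = _segs([(11, 40)])
        devs = ag.event_deviation_summary(pred, true, "IC", fs=250)
        assert devs.tolist() == [4.0]

    def test_deviations_are_multiples_of_frame_period(self):
        rng = np.random.default_rng(9)
        true = _segs([(i * 80 + 10, i * 80 + 50) for i in range(8)])
        pred = [
            ContactSegment(s.ic + rng.integers(-2, 3), s.tc + rng.integers(-2, 3))
            for s in true
        ]
        for kind in ("IC", "TC"):
            devs = ag.event_deviation_summary(pred, true, kind, fs=250)
            assert np.all(np.mod(devs, 4.0) == 0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(10)
        true = _segs([(i * 80 + 10, i * 80 + 50) for i in range(8)])
        shifts = rng.integers(-2, 3, size=(8, 2))
        pred = [
            ContactSegment(s.ic + int(a), s.tc + int(b))
            for s, (a, b) in zip(true, shifts)
        ]
        ic = ag.event_deviation_summary(pred, true, "IC", fs=250)
        np.testing.assert_allclose(ic, shifts[:, 0] * 4.0)
        tc = ag.event_deviation_summary(pred, true, "TC", fs=250)
        np.testing.assert_allclose(tc, shifts[:, 1] * 4.0)


class TestStepwiseTable:
    def test_generator_step1_mean_near_configured(self):
        from sprintgc.synthetic_gait import GaitSimConfig, generate_run

        cfg = GaitSimConfig(seed=23)
        gt, steps = [], []
        for i in range(150):
            rec = generate_run(cfg, "a09", f"r{i}", "left")
            gt.extend(rec.contact_ms)
            steps.extend(range(1, rec.contact_frames.size + 1))
        p = ag.PairedDurations(
            np.array(gt), np.array(gt), np.array(steps),
            np.array(["s"] * len(gt), dtype=object),
        )
        table = ag.stepwise_table(p)
        step1 = table.loc[table["data"] == "GT", "step_1"].item()
        se = cfg.gc_sd_ms[0] / math.sqrt(150)
        assert abs(step1 - cfg.gc_means_ms[0]) < 3 * se

    def test_single_observation_sd_zero(self):
        p = _pairs([100.0, 120.0], [102.0, 118.0], steps=[1, 2])
        table = ag.stepwise_table(p)
        assert (table["step_1_sd"] == 0).all()

    def test_total_column_pools_all_steps(self):
        p = _pairs([100.0, 120.0, 140.0], [100.0, 120.0, 140.0], steps=[1, 1, 2])
        table = ag.stepwise_table(p)
        assert table.loc[table["data"] == "GT", "total"].item() == pytest.approx(120.0)


class TestQuantizationError:
    @pytest.mark.parametrize(
        "fs,expected", [(100, 21.3), (250, 8.5), (500, 4.3), (1000, 2.1)]
    )
    def test_reported_percentages_for_94ms_contact(self, fs, expected):
        assert round(ag.quantization_error_pct(fs, 94.0), 1) == expected

    def test_strictly_decreasing_in_fs_and_duration(self):
        fss = [100, 200, 400, 800]
        vals = [ag.quantization_error_pct(fs, 94.0) for fs in fss]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        durs = [90, 120, 150, 200]
        vals = [ag.quantization_error_pct(250, d) for d in durs]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_vanishes_at_high_rate(self):
        assert ag.quantization_error_pct(1e9, 94.0) < 1e-5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ag.quantization_error_pct(0, 94)


class TestPlots:
    def test_plot_files_written(self, tmp_path):
        rng = np.random.default_rng(6)
        gt = rng.uniform(100, 180, size=40)
        pred = gt + rng.choice([-4.0, 0.0, 4.0], size=40)
        p = _pairs(gt, pred, steps=rng.integers(1, 10, size=40))
        ba_path = ag.bland_altman_plot(p, tmp_path / "ba.png")
        id_path = ag.identity_plot(p, tmp_path / "identity.png")
        assert ba_path.stat().st_size > 0
        assert id_path.stat().st_size > 0


class TestNormalityGate:
    def test_skewed_sample_takes_nonparametric_branch(self):
        rng = np.random.default_rng(2)
        decision = ag.normality_gate(rng.exponential(1.0, size=100))
        assert decision.nonparametric

    def test_normal_samples_take_parametric_branch(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, size=200)
        b = rng.normal(0, 1, size=200)
        decision = ag.normality_gate(a, b)
        assert not decision.nonparametric

    def test_insufficient_sample_rejected(self):
        with pytest.raises(ValidationError, match="insufficient"):
            ag.normality_gate(np.array([1.0, 2.0]))
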