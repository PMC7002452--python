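"""Null-threshold and t-test pixel classification, group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phimage import InvalidParameterError, SensorGeometry
from phimage import classify as cls
from phimage import synth
from phimage.calibration import convert_voltage_to_ph, fit_standard_curves
from phimage.response import ResponseMaps, compute_response_maps, compute_trial_responses, segment_trials


def _fake_maps(ddph, ddt=None, trial_angles=None, angles=None):
    """ResponseMaps carrying only what classification reads."""
    n_rows, n_cols, n_angles = ddph.shape
    if angles is None:
        angles = np.arange(n_angles) * 45.0
    zeros = np.zeros((n_rows, n_cols))
    n_trials = 0 if ddt is None else ddt.shape[2]
    return ResponseMaps(
        ph_interval_theta=np.zeros_like(ddph),
        ph_interval=zeros,
        delta_ph_trial=np.zeros((n_rows, n_cols, n_trials)),
        delta_ph_theta=np.zeros_like(ddph),
        delta_ph=zeros,
        delta_delta_ph=ddph,
        angles_deg=np.asarray(angles, dtype=float),
        trial_angles=None if trial_angles is None else np.asarray(trial_angles, dtype=float),
        delta_delta_ph_trial=ddt,
    )


def _brain_run(geometry, protocol, amplitude, seed, noise=0.005, angle_means=None):
    field = synth.generate_response_field(
        geometry,
        angles_deg=protocol.angles_deg,
        amplitude_ph=amplitude,
        angle_means=angle_means,
        seed=seed,
    )
    truth = synth.make_ground_truth(
        geometry, response_field=field, angles_deg=protocol.angles_deg, noise_sd_ph=noise
    )
    movie = synth.generate_recording(geometry, protocol, truth, "brain", seed=seed + 1)
    calset, _ = synth.generate_calibration_set(geometry=geometry, seed=seed + 2)
    ph = convert_voltage_to_ph(movie, fit_standard_curves(calset))
    tm = segment_trials(ph, protocol)
    maps = compute_response_maps(tm)
    compute_trial_responses(tm, maps)
    return maps


def _null_run(geometry, protocol, seed, noise=0.005):
    truth = synth.make_ground_truth(geometry, angles_deg=protocol.angles_deg, noise_sd_ph=noise)
    movie = synth.generate_recording(geometry, protocol, truth, "hepes", seed=seed)
    calset, _ = synth.generate_calibration_set(geometry=geometry, seed=seed + 1)
    ph = convert_voltage_to_ph(movie, fit_standard_curves(calset))
    tm = segment_trials(ph, protocol)
    maps = compute_response_maps(tm)
    compute_trial_responses(tm, maps)
    return maps


class TestNullThresholds:
    def test_standard_normal_pool_gives_plus_minus_196(self):
        rng = np.random.default_rng(0)
        maps = _fake_maps(rng.standard_normal((100, 100, 8)))
        thr = cls.compute_null_thresholds([maps])
        assert thr.lower == pytest.approx(-1.96, abs=0.03)
        assert thr.upper == pytest.approx(+1.96, abs=0.03)
        assert thr.n_values == 80_000

    def test_degenerate_pool_rejected(self):
        maps = _fake_maps(np.zeros((4, 4, 2)))
        with pytest.raises(InvalidParameterError):
            cls.compute_null_thresholds([maps])

    def test_fresh_null_exceedance_near_five_percent(self):
        rng = np.random.default_rng(1)
        pool = _fake_maps(rng.standard_normal((100, 100, 8)))
        thr = cls.compute_null_thresholds([pool])
        fresh = _fake_maps(rng.standard_normal((100, 100, 8)))
        cmap = cls.classify_by_threshold(fresh, thr)
        assert cmap.labeled_fraction == pytest.approx(0.05, abs=0.01)

    def test_se_interval_is_much_narrower(self):
        rng = np.random.default_rng(2)
        maps = _fake_maps(rng.standard_normal((50, 50, 8)))
        wide = cls.compute_null_thresholds([maps])
        narrow = cls.compute_null_thresholds([maps], method="se")
        assert narrow.upper < wide.upper / 50


class TestThresholdClassifier:
    def test_unreachable_thresholds_label_nothing(self):
        rng = np.random.default_rng(0)
        maps = _fake_maps(rng.standard_normal((8, 8, 4)))
        thr = cls.NullThresholds(lower=-1e9, upper=1e9, n_values=1)
        cmap = cls.classify_by_threshold(maps, thr)
        assert cmap.labeled_fraction == 0.0

    def test_strong_alkaline_field_dominates_its_angle(self, small_geometry):
        protocol = synth.generate_protocol(
            pre_phase_s=2.0, stim_s=1.0, interval_s=1.0, n_trials_per_angle=5,
            angles_deg=tuple(range(0, 360, 45)), seed=0,
        )
        means = {a: 0.0 for a in protocol.angles_deg}
        means[0.0] = 1.0
        maps = _brain_run(small_geometry, protocol, 0.05, seed=10, angle_means=means)
        null = _null_run(small_geometry, protocol, seed=50)
        thr = cls.compute_null_thresholds([null])
        cmap = cls.classify_by_threshold(maps, thr)
        counts = cmap.per_angle_counts().set_index("angle_deg")
        alk0 = counts.loc[0.0, "n_alkaline"] / counts.loc[0.0, "n_valid"]
        assert alk0 > 0.5
        assert counts.loc[0.0, "n_alkaline"] == counts["n_alkaline"].max()


class TestTTestClassifier:
    def test_statistic_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        n_trials = 30
        vals = rng.standard_normal((3, 3, n_trials)) * 0.01 + 0.004
        ddph = vals.mean(axis=2, keepdims=True)
        maps = _fake_maps(
            ddph, ddt=vals, trial_angles=np.zeros(n_trials), angles=[0.0]
        )
        cmap = cls.classify_by_ttest(maps, alpha=0.05)
        for r in range(3):
            for c in range(3):
                x = vals[r, c]
                t = x.mean() / (x.std(ddof=1) / np.sqrt(n_trials))
                p = 2 * stats.t.sf(abs(t), n_trials - 1)
                expected = 0
                if p < 0.05:
                    expected = 1 if x.mean() > 0 else -1
                assert cmap.labels[r, c, 0] == expected

    def test_zero_variance_is_not_significant(self):
        vals = np.full((2, 2, 10), 0.02)  # constant non-zero responses
        maps = _fake_maps(
            vals.mean(axis=2, keepdims=True), ddt=vals, trial_angles=np.zeros(10), angles=[0.0]
        )
        cmap = cls.classify_by_ttest(maps)
        assert cmap.labeled_fraction == 0.0

    def test_single_trial_rejected(self):
        vals = np.zeros((2, 2, 1))
        maps = _fake_maps(
            vals, ddt=vals, trial_angles=np.zeros(1), angles=[0.0]
        )
        with pytest.raises(InvalidParameterError):
            cls.classify_by_ttest(maps)


class TestClassifierProperties:
    def test_scaling_response_never_decreases_labels(self, small_geometry):
        protocol = synth.generate_protocol(
            pre_phase_s=2.0, stim_s=1.0, interval_s=1.0, n_trials_per_angle=5,
            angles_deg=(0.0, 90.0), seed=0,
        )
        null = _null_run(small_geometry, protocol, seed=30)
        thr = cls.compute_null_thresholds([null])
        counts = []
        for amp in (0.003, 0.01, 0.03):
            maps = _brain_run(small_geometry, protocol, amp, seed=77)
            cmap = cls.classify_by_threshold(maps, thr)
            counts.append(int((cmap.labels != 0).sum()))
        assert counts[0] <= counts[1] <= counts[2]

    def test_methods_agree_on_polarity_where_both_label(self, small_geometry):
        protocol = synth.generate_protocol(
            pre_phase_s=2.0, stim_s=1.0, interval_s=1.0, n_trials_per_angle=10,
            angles_deg=(0.0, 90.0), seed=0,
        )
        maps = _brain_run(small_geometry, protocol, 0.05, seed=21)
        null = _null_run(small_geometry, protocol, seed=60)
        thr = cls.compute_null_thresholds([null])
        ci = cls.classify_by_threshold(maps, thr)
        tt = cls.classify_by_ttest(maps)
        both = (ci.labels != 0) & (tt.labels != 0)
        assert both.sum() > 10
        assert np.all(ci.labels[both] == tt.labels[both])


def _count_df(run, condition, counts_by_angle):
    return pd.DataFrame(
        {
            "run": run,
            "condition": condition,
            "angle_deg": [a for a in counts_by_angle],
            "count": [counts_by_angle[a] for a in counts_by_angle],
            "n_valid": 100,
        }
    )


class TestGroupComparison:
    def test_identical_tables_give_zero_condition_effect(self):
        table_a = {0.0: 5, 45.0: 8, 90.0: 3, 135.0: 10}
        table_b = {0.0: 7, 45.0: 6, 90.0: 4, 135.0: 12}
        tables = [
            _count_df("brain_0", "brain", table_a),
            _count_df("brain_1", "brain", table_b),
            _count_df("hepes_0", "hepes", table_a),
            _count_df("hepes_1", "hepes", table_b),
        ]
        comp = cls.compare_brain_vs_null(tables)
        f_cond, p_cond = comp.effect("condition")
        assert f_cond == pytest.approx(0.0, abs=1e-10)
        assert comp.t_stat == pytest.approx(0.0, abs=1e-10)

    def test_anova_matches_cell_means_decomposition(self):
        rng = np.random.default_rng(4)
        angles = [0.0, 45.0, 90.0, 135.0]
        tables, data = [], []
        for cond, mu in (("brain", 20), ("hepes", 5)):
            for i in range(3):
                counts = {a: int(rng.poisson(mu + 2 * k)) for k, a in enumerate(angles)}
                tables.append(_count_df(f"{cond}_{i}", cond, counts))
                for a, c in counts.items():
                    data.append((cond, a, c))
        comp = cls.compare_brain_vs_null(tables)

        # balanced two-way ANOVA by explicit sums of squares
        arr = np.array([c for _, _, c in data], dtype=float).reshape(2, 3, 4)
        arr = np.moveaxis(arr, 1, 2)  # (cond, angle, rep)
        grand = arr.mean()
        m_c = arr.mean(axis=(1, 2))
        m_a = arr.mean(axis=(0, 2))
        m_ca = arr.mean(axis=2)
        n_rep, n_ang, n_cond = 3, 4, 2
        ss_c = n_rep * n_ang * np.sum((m_c - grand) ** 2)
        ss_a = n_rep * n_cond * np.sum((m_a - grand) ** 2)
        ss_i = n_rep * np.sum((m_ca - m_c[:, None] - m_a[None, :] + grand) ** 2)
        ss_e = np.sum((arr - m_ca[:, :, None]) ** 2)
        df_c, df_a, df_i, df_e = 1, 3, 3, 16
        assert comp.effect("condition")[0] == pytest.approx((ss_c / df_c) / (ss_e / df_e), rel=1e-9)
        assert comp.effect("angle")[0] == pytest.approx((ss_a / df_a) / (ss_e / df_e), rel=1e-9)
        assert comp.effect("interaction")[0] == pytest.approx((ss_i / df_i) / (ss_e / df_e), rel=1e-9)

    def test_single_run_condition_rejected(self):
        tables = [
            _count_df("brain_0", "brain", {0.0: 5}),
            _count_df("hepes_0", "hepes", {0.0: 5}),
            _count_df("hepes_1", "hepes", {0.0: 6}),
        ]
        with pytest.raises(InvalidParameterError):
            cls.compare_brain_vs_null(tables)

    def test_power_against_strong_responses(self):
        """Replicated strong-effect studies always separate brain from null."""
        geom = SensorGeometry(n_rows=12, n_cols=8, frame_rate_hz=25.0)
        protocol = synth.generate_protocol(
            pre_phase_s=2.0, stim_s=1.0, interval_s=1.0, n_trials_per_angle=3,
            angles_deg=tuple(range(0, 360, 45)), seed=0,
        )
        for rep in range(5):
            tables = []
            nulls = [_null_run(geom, protocol, seed=1000 * rep + 500 + 10 * i) for i in range(3)]
            thr = cls.compute_null_thresholds(nulls)
            for i in range(3):
                maps = _brain_run(geom, protocol, 0.03, seed=1000 * rep + 10 * i)
                tables.append(
                    cls.count_table(cls.classify_by_threshold(maps, thr), f"brain_{i}", "brain")
                )
            for i, null in enumerate(nulls):
                tables.append(
                    cls.count_table(cls.classify_by_threshold(null, thr), f"hepes_{i}", "hepes")
                )
            comp = cls.compare_brain_vs_null(tables)
            assert comp.effect("condition")[1] < 0.05
            assert comp.t_p < 0.05
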