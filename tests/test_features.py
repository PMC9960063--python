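import numpy as np
import pandas as pd
import pytest

from gazeintent.features import (
    aoi_history_features,
    build_design_matrix,
    component_history_features,
    extract_instances,
    feature_registry,
    heat_aoi,
    kinematics_features,
    oculomotor_features,
    window_features,
)
from gazeintent.gaze_io import Fixation, prepare_recording
from gazeintent.layout import LayoutState
from gazeintent.windows import assign_folds, segment_windows
from conftest import make_recording


class TestAOIHistory:
    def test_time_since_last_visit(self):
        # Last AOI-3 fixation at 12.0 s; window 4 starts at 15.0 s.
        spans = [(12_000.0, 12_200.0, 3)]
        out = aoi_history_features(np.zeros((3, 6)), spans, t=4, tau_s=5.0, n_aois=6)
        assert out["AOI_3_tslv"] == pytest.approx(3.0)

    def test_never_visited_aoi_reports_zero(self):
        out = aoi_history_features(np.zeros((3, 6)), [], t=4, tau_s=5.0, n_aois=6)
        assert all(out[f"AOI_{j}_tslv"] == 0.0 for j in range(1, 7))

    def test_lag_flags_echo_label_history(self):
        labels = np.zeros((3, 6))
        labels[2, 0] = 1  # window 3 visited AOI 1
        labels[0, 4] = 1  # window 1 visited AOI 5
        out = aoi_history_features(labels, [], t=4, tau_s=5.0, n_aois=6)
        assert out["AOI_1_r1"] == 1.0 and out["AOI_5_r3"] == 1.0
        assert out["AOI_1_r2"] == 0.0

    def test_lag_beyond_recording_start_is_zero(self):
        labels = np.ones((1, 6))
        out = aoi_history_features(labels, [], t=2, tau_s=5.0, n_aois=6)
        assert out["AOI_1_r1"] == 1.0
        assert out["AOI_1_r2"] == 0.0 and out["AOI_1_r3"] == 0.0

    def test_end_r1_indicator(self):
        # Previous window [10, 15) ends with a fixation in AOI 3.
        spans = [(11_000.0, 11_300.0, 1), (14_000.0, 14_500.0, 3)]
        out = aoi_history_features(np.zeros((3, 6)), spans, t=4, tau_s=5.0, n_aois=6)
        assert out["AOI_3_end_r1"] == 1.0
        assert sum(out[f"AOI_{j}_end_r1"] for j in range(1, 7)) == 1.0
        assert out["End_r1"] == 3.0

    def test_window_ending_on_whitespace_onehots_nothing(self):
        spans = [(11_000.0, 11_300.0, 2), (14_000.0, 14_500.0, None)]
        out = aoi_history_features(np.zeros((3, 6)), spans, t=4, tau_s=5.0, n_aois=6)
        assert all(out[f"AOI_{j}_end_r1"] == 0.0 for j in range(1, 7))
        assert out["End_r1"] == 0.0


class TestComponentHistory:
    IDS = {"Logo": 1, "Banner": 2}

    def test_average_time_of_visits(self):
        spans = [(1_000.0, 1_200.0, "Banner"), (3_000.0, 3_400.0, "Banner")]
        out = component_history_features(spans, t=3, tau_s=5.0, comp_ids=self.IDS)
        assert out["Banner_atv"] == pytest.approx(300.0)

    def test_average_time_between_visits(self):
        # Gaps: 5.0 - 2.0 = 3.0 s and 9.5 - 5.5 = 4.0 s -> mean 3.5 s (in ms).
        spans = [
            (1_000.0, 2_000.0, "Logo"),
            (5_000.0, 5_500.0, "Logo"),
            (9_500.0, 9_800.0, "Logo"),
        ]
        out = component_history_features(spans, t=4, tau_s=5.0, comp_ids=self.IDS)
        assert out["Logo_atbv"] == pytest.approx(3_500.0)

    def test_never_fixated_component_all_zero(self):
        out = component_history_features([], t=3, tau_s=5.0, comp_ids=self.IDS)
        for c in self.IDS:
            assert out[f"{c}_his"] == 0.0
            assert out[f"{c}_tslv"] == 0.0
            assert out[f"{c}_atv"] == 0.0
            assert out[f"{c}_atbv"] == 0.0
        assert out["Component_end"] == 0.0

    def test_component_end_is_last_of_previous_window(self):
        spans = [(11_000.0, 11_200.0, "Logo"), (13_000.0, 13_200.0, "Banner")]
        out = component_history_features(spans, t=4, tau_s=5.0, comp_ids=self.IDS)
        assert out["Component_end"] == 2.0
        assert out["Banner_end_r1"] == 1.0 and out["Logo_end_r1"] == 0.0


class TestHeatAOI:
    def test_training_frequency(self):
        ls = [np.array([[1, 0]] * 3), np.array([[0, 1]] * 3),
              np.array([[1, 0]] * 3), np.array([[1, 1]] * 3)]
        np.testing.assert_allclose(heat_aoi(ls, t=2, n_aois=2), [0.75, 0.5])

    def test_all_zero_training_labels(self):
        assert heat_aoi([np.zeros((4, 3))], t=1, n_aois=3).tolist() == [0, 0, 0]

    def test_window_beyond_training_recordings_is_zero(self):
        assert heat_aoi([np.ones((2, 3))], t=9, n_aois=3).tolist() == [0, 0, 0]

    def test_short_recordings_excluded_from_mean(self):
        ls = [np.ones((5, 1)), np.zeros((1, 1))]
        assert heat_aoi(ls, t=3, n_aois=1)[0] == 1.0


def _uniform_samples(t0_ms, t1_ms, fx, fy, rate=120.0):
    ts = np.arange(t0_ms, t1_ms, 1000.0 / rate)
    return pd.DataFrame(
        {"t_ms": ts, "x_px": fx(ts / 1000.0), "y_px": fy(ts / 1000.0),
         "valid": np.ones(len(ts), bool)}
    )


class TestKinematics:
    def test_constant_position(self):
        s = _uniform_samples(0, 5000, lambda t: 512.0 + 0 * t, lambda t: 300.0 + 0 * t)
        out = kinematics_features(s, 0, 5000)
        assert out["coordX"] == 512.0 and out["coordY"] == 300.0
        assert out["StdX"] == 0.0
        assert out["VelX"] == pytest.approx(0.0, abs=1e-6)
        assert out["AclX"] == pytest.approx(0.0, abs=1e-6)

    def test_linear_motion_exact_velocity(self):
        s = _uniform_samples(0, 5000, lambda t: 100.0 * t, lambda t: 0 * t)
        out = kinematics_features(s, 0, 5000)
        assert out["VelX"] == pytest.approx(100.0, abs=1e-6)
        assert out["MeanVelX"] == pytest.approx(100.0, abs=1e-6)
        assert out["AclX"] == pytest.approx(0.0, abs=1e-6)

    def test_quadratic_motion_exact_acceleration(self):
        s = _uniform_samples(0, 5000, lambda t: 50.0 * t**2, lambda t: 0 * t)
        out = kinematics_features(s, 0, 5000)
        assert out["AclX"] == pytest.approx(100.0, abs=1e-6)
        assert out["MeanAclX"] == pytest.approx(100.0, abs=1e-6)

    def test_empty_window_yields_zeros(self):
        s = _uniform_samples(0, 1000, lambda t: t, lambda t: t)
        out = kinematics_features(s, 5000, 10000)
        assert all(v == 0.0 for v in out.values())

    def test_xy_symmetry(self):
        rng = np.random.default_rng(3)
        ts = np.arange(0, 3000, 1000.0 / 120)
        xs, ys = rng.normal(size=(2, len(ts))).cumsum(axis=1)
        s = pd.DataFrame({"t_ms": ts, "x_px": xs, "y_px": ys, "valid": np.ones(len(ts), bool)})
        swapped = pd.DataFrame({"t_ms": ts, "x_px": ys, "y_px": xs, "valid": np.ones(len(ts), bool)})
        a, b = kinematics_features(s, 0, 3000), kinematics_features(swapped, 0, 3000)
        for stat in ("coord", "Mean", "Std", "Vel", "MeanVel", "StdVel", "Acl", "MeanAcl", "StdAcl"):
            assert a[f"{stat}X"] == b[f"{stat}Y"]
            assert a[f"{stat}Y"] == b[f"{stat}X"]

    def test_gap_breaks_difference_chain(self):
        # Two chains at distant positions; no spurious cross-gap velocity.
        a = _uniform_samples(0, 1000, lambda t: 0 * t, lambda t: 0 * t)
        b = _uniform_samples(2000, 3000, lambda t: 0 * t + 5000, lambda t: 0 * t)
        s = pd.concat([a, b], ignore_index=True)
        out = kinematics_features(s, 0, 3000)
        assert out["VelX"] == pytest.approx(0.0, abs=1e-6)
        assert out["StdVelX"] == pytest.approx(0.0, abs=1e-6)


class TestOculomotor:
    def test_fixation_statistics(self):
        rec = make_recording(
            fixations=[Fixation(0, 100, 0, 0), Fixation(200, 400, 0, 0), Fixation(500, 800, 0, 0)],
            duration_ms=10_000,
        )
        prepare_recording(rec)
        out = oculomotor_features(rec, 5_000)
        assert out["NFix"] == 3
        assert out["TPromFix"] == pytest.approx(200.0)
        assert out["TMaxFix"] == 300.0 and out["TMinFix"] == 100.0

    def test_no_saccades_yet(self):
        rec = make_recording(fixations=[Fixation(0, 200, 0, 0)], duration_ms=10_000)
        prepare_recording(rec)
        out = oculomotor_features(rec, 5_000)
        assert out["NSac"] == 0 and out["APromSac"] == 0.0

    def test_saccade_amplitude_statistics(self):
        rec = make_recording(
            fixations=[
                Fixation(0, 200, 0, 0),
                Fixation(250, 450, 500, 0),
                Fixation(500, 700, 400, 0),
            ],
            duration_ms=10_000,
        )
        prepare_recording(rec)
        out = oculomotor_features(rec, 5_000)
        assert out["NSac"] == 2
        assert out["APromSac"] == pytest.approx(300.0)
        assert out["AMaxSac"] == 500.0 and out["AMinSac"] == 100.0


class TestDesignMatrix:
    def test_first_window_contributes_no_instance(self, layout, small_cohort):
        _, recs = small_cohort
        rec = prepare_recording(recs[0])
        inst = extract_instances(rec, layout, 5.0)
        n_windows = len(segment_windows(rec.duration_ms, 5.0))
        assert list(inst.features.index) == list(range(2, n_windows + 1))

    def test_registry_size_and_composition(self, layout):
        reg = feature_registry(layout)
        n, C = 6, len(layout.components)
        assert len(reg) == (5 * n + 1) + (5 * C + 1) + n + 18 + 8
        assert len(set(reg)) == len(reg)
        assert "AOI_3_tslv" in reg and "Heat_AOI_2" in reg and "coordX" in reg

    def test_heat_depends_on_fold_other_features_do_not(self, layout, small_cohort):
        _, recs = small_cohort
        insts = [extract_instances(prepare_recording(r), layout, 5.0) for r in recs]
        counts = {}
        for r in recs:
            counts[r.user_id] = counts.get(r.user_id, 0) + len(segment_windows(r.duration_ms, 5.0))
        fa = assign_folds(counts, 5)
        fd0 = build_design_matrix(insts, layout, fa, 0)
        fd1 = build_design_matrix(insts, layout, fa, 1)
        heat_cols = [c for c in fd0.train_X.columns if c.startswith("Heat_AOI")]
        other = [c for c in fd0.train_X.columns if not c.startswith("Heat_AOI")]
        # same instance key set overall, identical base features regardless of fold
        all0 = pd.concat([fd0.train_X, fd0.test_X]).reset_index(drop=True)
        key0 = fd0.train_keys + fd0.test_keys
        all1 = pd.concat([fd1.train_X, fd1.test_X]).reset_index(drop=True)
        key1 = fd1.train_keys + fd1.test_keys
        order0 = np.argsort(np.array([str(k) for k in key0]))
        order1 = np.argsort(np.array([str(k) for k in key1]))
        b0 = all0.iloc[order0][other].reset_index(drop=True)
        b1 = all1.iloc[order1][other].reset_index(drop=True)
        pd.testing.assert_frame_equal(b0, b1)
        h0 = all0.iloc[order0][heat_cols].reset_index(drop=True)
        h1 = all1.iloc[order1][heat_cols].reset_index(drop=True)
        assert not h0.equals(h1)

    def test_heat_in_unit_interval_flags_binary(self, layout, small_cohort):
        _, recs = small_cohort
        insts = [extract_instances(prepare_recording(r), layout, 5.0) for r in recs]
        counts = {r.user_id: 20 for r in recs}
        fa = assign_folds(counts, 5)
        fd = build_design_matrix(insts, layout, fa, 0)
        X = fd.train_X
        for c in X.columns:
            if c.startswith("Heat_AOI"):
                assert ((X[c] >= 0) & (X[c] <= 1)).all()
            if c != "End_r1" and c.endswith(("_r1", "_r2", "_r3", "_his")):
                assert set(np.unique(X[c])) <= {0.0, 1.0}
            if c.startswith("Std"):
                assert (X[c] >= 0).all()
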