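"""Activity simulation, residence times, S-value algebra, effective dose, limits."""

import numpy as np
import pandas as pd
import pytest

from tetrodose.dosimetry import (
    LAMBDA_TC99M,
    TC99M_HALF_LIFE_MIN,
    ActivityProfile,
    SourceRegistryError,
    SValueMatrix,
    TissueWeights,
    absorbed_doses,
    effective_dose,
    interpolate_max_activity,
    load_icrp103_weights,
    map_sources,
    max_activity,
    residence_times,
    simulate_activity,
)
from tetrodose.model import IDX, STATES, simulate_closed_loop

NO_RESETS = {"bladder": 1e9, "gi_contents": 1e9}


class TestSimulateActivity:
    def test_total_activity_decays_with_half_life(self, adult_phys, drug):
        prof = simulate_activity(adult_phys, drug, dose=1.0, schedule=NO_RESETS,
                                 horizon_min=2 * TC99M_HALF_LIFE_MIN, dt_min=2.0)
        total = prof.activity.sum(axis=1)
        # without resets, total activity = conserved amount * e^-lambda*t:
        # it halves every 361.2 min
        assert np.interp(TC99M_HALF_LIFE_MIN, prof.t, total) == pytest.approx(
            0.5, rel=1e-4)
        assert total[-1] == pytest.approx(0.25, rel=1e-6)
        np.testing.assert_allclose(total, np.exp(-LAMBDA_TC99M * prof.t), rtol=1e-9)

    def test_zero_dose_zero_activity(self, adult_phys, drug):
        prof = simulate_activity(adult_phys, drug, dose=0.0, horizon_min=720.0)
        assert np.all(prof.activity == 0.0)

    def test_lambda_zero_no_resets_reproduces_kinetics(self, adult_phys, drug):
        prof = simulate_activity(adult_phys, drug, dose=100.0, decay_constant=0.0,
                                 schedule=NO_RESETS, horizon_min=1440.0, dt_min=10.0)
        sim = simulate_closed_loop(adult_phys, drug, dose=100.0, t_grid=prof.t)
        np.testing.assert_allclose(prof.activity, sim.states, rtol=1e-9, atol=1e-12)

    def test_bladder_zero_after_each_void(self, adult_phys, drug):
        prof = simulate_activity(adult_phys, drug, dose=1.0, horizon_min=720.0)
        bladder = prof.series("urine")
        for t_void in (180.0, 360.0, 540.0):
            hits = np.where(prof.t == t_void)[0]
            assert len(hits) == 2  # pre- and post-void samples
            assert bladder[hits[0]] > 0.0
            assert bladder[hits[1]] == 0.0

    def test_gi_contents_reset_every_24h(self, adult_phys, drug):
        prof = simulate_activity(adult_phys, drug, dose=1.0, horizon_min=2000.0)
        hits = np.where(prof.t == 1440.0)[0]
        assert prof.series("gi_contents")[hits[0]] > 0.0
        assert prof.series("gi_contents")[hits[1]] == 0.0


class TestResidenceTimes:
    def _mono_exponential_profile(self, lam, t_end=3600.0, dt=2.0):
        t = np.arange(0.0, t_end + dt, dt)
        act = np.zeros((t.size, len(STATES)))
        act[:, IDX["liver"]] = np.exp(-lam * t)
        return ActivityProfile(t=t, activity=act, decay_constant=lam, dose=1.0)

    def test_exponential_closed_form(self):
        prof = self._mono_exponential_profile(LAMBDA_TC99M)
        n, report = residence_times(prof)
        # N = 1/lambda = 521.2 min = 8.686 h
        assert n["liver"] == pytest.approx(1.0 / LAMBDA_TC99M / 60.0, rel=1e-4)
        assert n["liver"] == pytest.approx(8.686, abs=2e-3)
        assert not report["warnings"]

    def test_zero_activity_zero_residence(self):
        prof = self._mono_exponential_profile(LAMBDA_TC99M)
        prof.activity[:] = 0.0
        n, _ = residence_times(prof)
        assert all(v == 0.0 for v in n.values())

    def test_total_bounded_by_total_decay(self, adult_phys, drug):
        prof = simulate_activity(adult_phys, drug, dose=1.0)
        n, report = residence_times(prof)
        assert sum(n.values()) <= report["total_decay_bound_h"] + 1e-9

    def test_default_matches_fine_grid_brute_force_oracle(self, adult_phys, drug):
        default = simulate_activity(adult_phys, drug, dose=1.0, dt_min=2.0)
        n_d, _ = residence_times(default)
        # brute-force oracle: drop the analytic segment integrals and
        # integrate an event-resolved fine grid numerically
        fine = simulate_activity(adult_phys, drug, dose=1.0, dt_min=0.05)
        fine.metadata.pop("segment_integral_min")
        n_f, _ = residence_times(fine)
        assert n_d["urine"] == pytest.approx(n_f["urine"], rel=1e-3)
        for state in ("liver", "gi_contents", "muscle", "ven"):
            assert n_d[state] == pytest.approx(n_f[state], rel=1e-3)

    def test_short_horizon_rejected(self, adult_phys, drug):
        prof = simulate_activity(adult_phys, drug, dose=1.0)
        with pytest.raises(ValueError):
            residence_times(prof, horizon_min=600.0)


class TestMapSources:
    def test_identity_mapping_on_toy_registry(self):
        n = {"liver": 1.0, "gi": 2.0, "urine": 3.0}
        mapping = {"liver": "liver", "gi": "gi_wall", "urine": "bladder_contents"}
        out = map_sources(n, ("liver", "gi_wall", "bladder_contents"), mapping)
        assert out == {"liver": 1.0, "gi_wall": 2.0, "bladder_contents": 3.0}

    def test_equal_split_preserves_sum(self):
        n = {"gi_contents": 2.0}
        mapping = {"gi_contents": {"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25}}
        out = map_sources(n, ("a", "b", "c", "d"), mapping)
        assert all(v == pytest.approx(0.5) for v in out.values())
        assert sum(out.values()) == pytest.approx(sum(n.values()))

    def test_default_mapping_preserves_total(self, adult_phys, drug):
        prof = simulate_activity(adult_phys, drug, dose=1.0)
        n_state, _ = residence_times(prof)
        n_source = map_sources(n_state)
        assert sum(n_source.values()) == pytest.approx(sum(n_state.values()), rel=1e-12)
        # blood, muscle, adipose and the lumped remainder all pool there
        assert n_source["rest_of_body"] > 0

    def test_unmapped_compartment_raises(self):
        with pytest.raises(SourceRegistryError, match="mystery"):
            map_sources({"mystery": 1.0}, ("liver",), {"liver": "liver"})

    def test_bad_split_weights(self):
        with pytest.raises(SourceRegistryError):
            map_sources({"gi": 1.0}, ("a", "b"), {"gi": {"a": 0.6, "b": 0.6}})


class TestDoseAlgebra:
    def _toy_matrix(self):
        return SValueMatrix(
            age_label="toy", targets=["a", "b", "c"], sources=["a", "b", "c"],
            values=np.array([[3.0, 1.0, 0.5], [1.0, 4.0, 0.25], [0.5, 0.25, 5.0]]) * 1e-3)

    def test_zero_residence_zero_dose(self):
        h = absorbed_doses({"a": 0.0, "b": 0.0, "c": 0.0}, self._toy_matrix())
        assert all(v == 0.0 for v in h.values())

    def test_single_source_arithmetic(self):
        sv = SValueMatrix(age_label="toy", targets=["t"], sources=["s"],
                          values=np.array([[0.003]]))
        h = absorbed_doses({"s": 2.0}, sv)
        assert h["t"] == pytest.approx(0.006)

    def test_toy_matrix_matches_hand_sums(self):
        sv = self._toy_matrix()
        n = {"a": 1.0, "b": 2.0, "c": 0.5}
        h = absorbed_doses(n, sv)
        for i, target in enumerate(sv.targets):
            expected = sum(sv.values[i, j] * n[s] for j, s in enumerate(sv.sources))
            assert h[target] == pytest.approx(expected, rel=1e-12)

    def test_registry_mismatch(self):
        with pytest.raises(SourceRegistryError):
            absorbed_doses({"unknown": 1.0}, self._toy_matrix())

    def test_effective_dose_equal_absorbed_doses(self):
        w = load_icrp103_weights()
        h = {t: 0.007 for t in w.weights}
        assert effective_dose(h, w) == pytest.approx(0.007)

    def test_effective_dose_missing_target(self):
        w = load_icrp103_weights()
        with pytest.raises(SourceRegistryError):
            effective_dose({"liver": 0.01}, w)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TissueWeights(weights={"liver": 0.5, "lungs": 0.3})


class TestSValueIO:
    def test_round_trip_and_unit_conversion(self, tmp_path):
        df = pd.DataFrame({
            "target": ["a", "a", "b", "b"],
            "source": ["a", "b", "a", "b"],
            "svalue": [3.0e-3, 1.0e-3, 1.0e-3, 4.0e-3],
            "unit": ["mGy/MBq/h"] * 4,
        })
        p = tmp_path / "sv.csv"
        df.to_csv(p, index=False)
        sv = SValueMatrix.from_csv(p, age_label="adult")
        assert sv.values[sv.targets.index("b"), sv.sources.index("b")] == 4.0e-3
        # same matrix in per-second units must ingest identically
        df2 = df.assign(svalue=df["svalue"] / 3600.0, unit="mGy/MBq/s")
        p2 = tmp_path / "sv2.csv"
        df2.to_csv(p2, index=False)
        sv2 = SValueMatrix.from_csv(p2)
        np.testing.assert_allclose(sv2.values, sv.values, rtol=1e-12)

    def test_unknown_unit_rejected(self, tmp_path):
        p = tmp_path / "sv.csv"
        pd.DataFrame({"target": ["a"], "source": ["a"], "svalue": [1.0],
                      "unit": ["rad/uCi/h"]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="unit"):
            SValueMatrix.from_csv(p)

    def test_self_dose_dominance_warning(self):
        sv = SValueMatrix(age_label="toy", targets=["a", "b"], sources=["a", "b"],
                          values=np.array([[1.0, 2.0], [0.5, 3.0]]))
        assert sv.sanity_warnings()


class TestActivityLimits:
    def test_equal_doses_give_adult_limit(self):
        assert max_activity(0.006, 0.006) == pytest.approx(1200.0)

    def test_double_dose_halves_activity(self):
        assert max_activity(0.012, 0.006) == pytest.approx(600.0)

    def test_zero_child_dose_rejected(self):
        with pytest.raises(ValueError):
            max_activity(0.0, 0.006)

    def test_interpolation_at_anchor(self):
        anchors = {1: 248.0, 5: 466.0, 10: 694.0, 15: 1011.0, 18: 1200.0}
        assert interpolate_max_activity(10.0, anchors) == 694.0

    def test_interpolation_midpoints(self):
        anchors = {1: 248.0, 5: 466.0, 10: 694.0, 15: 1011.0, 18: 1200.0}
        assert interpolate_max_activity(7.5, anchors) == pytest.approx(580.0)
        assert interpolate_max_activity(3.0, anchors) == pytest.approx(357.0)

    def test_no_extrapolation_below_one_year(self):
        with pytest.raises(ValueError):
            interpolate_max_activity(0.5, {1: 248.0, 18: 1200.0})
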