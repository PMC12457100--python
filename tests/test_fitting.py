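"""Initial-condition allocation, proportion regression, RMSE fits."""

import numpy as np
import pytest

from gliotwin import (
    DEFAULT_FRACTIONS,
    InitialFractions,
    ModelParams,
    ProportionMaps,
    SubjectRecord,
    Trajectory,
    allocate_initial_state,
    fit_control,
    fit_treated,
    proportion_regression,
    simulate,
    standard_course,
    volume,
)
from gliotwin.fitting import records_from_frame
import pandas as pd


class TestAllocation:
    def test_equal_unit_volume_simplification(self):
        p = ModelParams(v_T=1e-6, v_M=1e-6)
        fr = InitialFractions(0.5, 0.3, 0.2)
        s = allocate_initial_state(2.0, fr, p)
        assert s.T == pytest.approx(0.5 * 2.0 / 1e-6)
        assert s.A == pytest.approx(0.3 * 2.0 / 1e-6)
        assert s.P1 + s.P2 == pytest.approx(0.2 * 2.0 / 1e-6)

    def test_experimental_fractions_arithmetic(self):
        """Hand-computed allocation of a 3 mm^3 tumor at the measured
        control fractions with 1e-6 mm^3 unit volumes."""
        p = ModelParams(v_T=1e-6, v_M=1e-6)
        s = allocate_initial_state(3.0, DEFAULT_FRACTIONS, p)
        assert s.T == pytest.approx(2.88e6, rel=1e-12)
        assert s.A == pytest.approx(1.05e5, rel=1e-12)
        assert s.P1 == pytest.approx(7.5e3, rel=1e-12)
        assert s.P2 == pytest.approx(7.5e3, rel=1e-12)

    def test_equal_p_split(self, params):
        s = allocate_initial_state(10.0, DEFAULT_FRACTIONS, params)
        assert s.P1 == s.P2
        assert s.TD == 0.0 and s.MD == 0.0

    @pytest.mark.parametrize("v0", [0.5, 3.0, 41.5, 120.0])
    def test_volume_reconstruction_identity(self, v0, params):
        s = allocate_initial_state(v0, DEFAULT_FRACTIONS, params)
        assert volume(s, params) == pytest.approx(v0, rel=1e-12)

    def test_nonpositive_volume_rejected(self, params):
        with pytest.raises(ValueError):
            allocate_initial_state(0.0, DEFAULT_FRACTIONS, params)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            InitialFractions(0.9, 0.2, 0.2)  # does not sum to 1


class TestProportionRegression:
    def _make_traj(self, params, rel_vols, fracs):
        """Trajectory whose count fractions follow a known line."""
        vmax = 100.0
        states = []
        n_total = 1e6
        for rv, (fT, fA, fP) in zip(rel_vols, fracs):
            states.append(
                [fT * n_total, fP * n_total / 2, fP * n_total / 2,
                 fA * n_total, 0.0, 0.0]
            )
        states = np.asarray(states)
        # scale so volume matches rel_vol * vmax
        for i, rv in enumerate(rel_vols):
            v = params.v_T * states[i, 0] + params.v_M * states[i, 1:4].sum()
            states[i] *= rv * vmax / v
        return Trajectory(
            times=np.arange(len(rel_vols), dtype=float),
            states=states,
            params=params,
        )

    def test_constant_fractions_give_flat_lines(self, params):
        fr = (0.9, 0.07, 0.03)
        trajs = [
            self._make_traj(params, [0.2, 0.6, 1.0], [fr] * 3),
            self._make_traj(params, [0.3, 0.8, 1.0], [fr] * 3),
        ]
        maps = proportion_regression(trajs)
        for key, target in zip(("f_T", "f_A", "f_P"), fr):
            slope, intercept = maps.coef[key]
            assert slope == pytest.approx(0.0, abs=1e-9)
            assert intercept == pytest.approx(target, rel=1e-9)

    def test_known_line_recovered_exactly(self, params):
        """Fractions generated from a line are recovered to 1e-6."""

        def line(rv):
            fT = 0.95 - 0.2 * rv
            fP = 0.02 + 0.15 * rv
            return (fT, 1.0 - fT - fP, fP)

        rels_a = [0.1, 0.4, 0.7, 1.0]
        rels_b = [0.2, 0.5, 0.9, 1.0]
        trajs = [
            self._make_traj(params, rels_a, [line(r) for r in rels_a]),
            self._make_traj(params, rels_b, [line(r) for r in rels_b]),
        ]
        maps = proportion_regression(trajs)
        assert maps.coef["f_T"][0] == pytest.approx(-0.2, abs=1e-6)
        assert maps.coef["f_T"][1] == pytest.approx(0.95, abs=1e-6)
        assert maps.coef["f_P"][0] == pytest.approx(0.15, abs=1e-6)
        pred = maps.predict(0.5)
        fT, fA, fP = line(0.5)
        assert pred.f_T == pytest.approx(fT, abs=1e-6)
        assert pred.f_P == pytest.approx(fP, abs=1e-6)

    def test_prediction_renormalizes_to_one(self):
        maps = ProportionMaps(
            coef={"f_T": (0.0, 1.2), "f_A": (0.0, 0.2), "f_P": (0.0, 0.2)}
        )
        pred = maps.predict(0.5)  # f_T clipped to 1 then renormalized
        assert pred.f_T + pred.f_A + pred.f_P == pytest.approx(1.0)

    def test_degenerate_predictor_rejected(self, params):
        tr = self._make_traj(params, [1.0, 1.0, 1.0], [(0.9, 0.07, 0.03)] * 3)
        with pytest.raises(ValueError):
            proportion_regression([tr, tr])

    def test_single_trajectory_rejected(self, params):
        tr = self._make_traj(params, [0.5, 1.0], [(0.9, 0.07, 0.03)] * 2)
        with pytest.raises(ValueError):
            proportion_regression([tr])


def _control_record(params, rho_T, times, v0=3.0):
    p = params.replace(rho_T=rho_T)
    init = allocate_initial_state(v0, DEFAULT_FRACTIONS, p)
    grid = np.union1d(np.linspace(0, times[-1], 200), times)
    traj = simulate(init, p, horizon=times[-1], output_grid=grid)
    return SubjectRecord(
        subject_id="ctrl",
        group="control",
        times=tuple(times),
        volumes=tuple(traj.volume_at(np.asarray(times))),
    )


class TestControlFit:
    def test_noiseless_recovery(self, params):
        true_rho = 2.6e-4
        rec = _control_record(params, true_rho, [0.0, 4.0, 8.0, 12.0, 16.0])
        res = fit_control(rec, params)
        assert res.rho_T == pytest.approx(true_rho, rel=1e-3)
        assert res.rmse < 0.05

    def test_objective_matches_residuals(self, params):
        rec = _control_record(params, 3.1e-4, [0.0, 5.0, 10.0, 15.0])
        res = fit_control(rec, params)
        assert res.objective_from_residuals() == pytest.approx(
            res.rmse, abs=1e-10
        )

    def test_two_fold_rho_preserves_order(self, params):
        times = [0.0, 4.0, 8.0, 12.0]
        rec_lo = _control_record(params, 1.8e-4, times)
        rec_hi = _control_record(params, 3.6e-4, times)
        res_lo = fit_control(rec_lo, params)
        res_hi = fit_control(rec_hi, params)
        assert res_hi.rho_T > res_lo.rho_T

    def test_wrong_group_rejected(self, params):
        rec = SubjectRecord("x", "treated", (0.0, 1.0, 2.0), (1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            fit_control(rec, params)

    def test_too_few_points_rejected(self, params):
        rec = SubjectRecord("x", "control", (0.0, 1.0), (1.0, 2.0))
        with pytest.raises(ValueError):
            fit_control(rec, params)


def _treated_record(params, rho_T, s_t, times, v0=41.5):
    p = params.replace(rho_T=rho_T)
    init = allocate_initial_state(v0, DEFAULT_FRACTIONS, p)
    sched = standard_course(s_t)
    grid = np.union1d(np.linspace(0, times[-1], 400), times)
    traj = simulate(init, p, schedule=sched, horizon=times[-1],
                    output_grid=grid)
    return SubjectRecord(
        subject_id="irx",
        group="treated",
        times=tuple(times),
        volumes=tuple(traj.volume_at(np.asarray(times))),
    )


class TestTreatedFit:
    times = [0.0, 3.0, 8.0, 15.0, 25.0, 40.0]

    def test_noiseless_joint_recovery(self, treated_params):
        true_rho, true_st = 5.5e-6, 0.62
        rec = _treated_record(treated_params, true_rho, true_st, self.times)
        res = fit_treated(
            rec, treated_params, standard_course(0.7),
            fractions=DEFAULT_FRACTIONS, rho_T_init=5e-6,
        )
        assert res.rho_T == pytest.approx(true_rho, rel=1e-2)
        assert res.s_t == pytest.approx(true_st, rel=1e-2)
        assert res.rmse < 0.1

    def test_no_treatment_effect_recovers_high_s_t(self, treated_params):
        """Generated with S_T=1 the fitted radiosensitivity stays near 1."""
        rec = _treated_record(treated_params, 5e-6, 1.0, self.times)
        res = fit_treated(
            rec, treated_params, standard_course(0.7),
            fractions=DEFAULT_FRACTIONS, rho_T_init=5e-6,
        )
        assert res.s_t >= 0.95

    def test_self_generated_record_has_zero_rmse(self, treated_params):
        rec = _treated_record(treated_params, 4e-6, 0.7, self.times)
        res = fit_treated(
            rec, treated_params, standard_course(0.7),
            fractions=DEFAULT_FRACTIONS, rho_T_init=5e-6,
        )
        assert res.rmse == pytest.approx(0.0, abs=0.05)

    def test_missing_fraction_inputs_rejected(self, treated_params):
        rec = _treated_record(treated_params, 5e-6, 0.7, self.times)
        with pytest.raises(ValueError):
            fit_treated(rec, treated_params, standard_course(0.7))


class TestRecordIO:
    def test_records_from_long_frame(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "a", "a", "b", "b", "b"],
                "group": ["control"] * 3 + ["treated"] * 3,
                "day": [0, 2, 5, 0, 3, 6],
                "volume_mm3": [3.0, 4.0, 6.0, 40.0, 30.0, 20.0],
            }
        )
        recs = records_from_frame(df)
        assert [r.subject_id for r in recs] == ["a", "b"]
        assert recs[0].group == "control"
        assert recs[1].volumes == (40.0, 30.0, 20.0)

    def test_missing_column_named_in_error(self):
        df = pd.DataFrame({"subject_id": ["a"], "day": [0], "group": ["control"]})
        with pytest.raises(ValueError, match="volume_mm3"):
            records_from_frame(df)
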