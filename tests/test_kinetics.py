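"""Initial rates, Michaelis-Menten fitting, effector analysis, optima."""

import numpy as np
import pytest

from cladekin import (
    ActivityProfile,
    AssayTrace,
    Condition,
    DataError,
    FitError,
    KineticFit,
    RateMeasurement,
    classify_inhibition_mode,
    find_optimum,
    fit_michaelis_menten,
    inhibition_vs_ph,
    initial_rate,
    relative_activity,
    specific_activity,
)
from cladekin.kinetics import measurements_from_table, read_assay_table
from cladekin.synth import (
    AssaySimConfig,
    EffectorSpec,
    generate_assay_dataset,
    generate_effector_panel,
    generate_trace,
)


def mm_measurements(vmax, km, substrates, noise=None):
    out = []
    for s in substrates:
        v = vmax * s / (km + s)
        if noise is not None:
            v *= noise.pop(0)
        out.append(RateMeasurement(substrate_mM=s, velocity_units=v,
                                   condition=Condition(substrate_mM=s)))
    return out


class TestInitialRate:
    def test_linear_trace_gives_exact_velocity(self):
        # slope -0.0622 A/min over 1 mL, 1 cm -> 0.0100 units
        t = np.arange(0, 300, 20.0)
        a = 1.0 - 0.0622 * t / 60.0
        trace = AssayTrace(time_s=t, A340=a)
        assert initial_rate(trace).velocity_units == pytest.approx(0.01, rel=1e-12)

    def test_flat_trace_gives_zero(self):
        trace = AssayTrace(time_s=np.arange(4.0), A340=np.full(4, 0.8))
        assert initial_rate(trace).velocity_units == 0.0

    def test_rising_trace_warns_and_reports_zero(self):
        trace = AssayTrace(time_s=np.arange(4.0), A340=np.linspace(0.5, 0.9, 4))
        with pytest.warns(UserWarning, match="increases"):
            assert initial_rate(trace).velocity_units == 0.0

    def test_max_linear_window_excludes_curved_tail(self):
        # linear at -0.0622 A/min for 6 points, then the trace flattens
        t = np.arange(0, 240, 20.0)
        a = 1.0 - 0.0622 * np.minimum(t, 100.0) / 60.0
        trace = AssayTrace(time_s=t, A340=a)
        v = initial_rate(trace).velocity_units
        assert v == pytest.approx(0.01, rel=1e-6)

    def test_roundtrip_through_synthetic_trace(self):
        for v_true in (5e-4, 1.044e-3, 0.02):
            trace = generate_trace(v_true)
            assert initial_rate(trace).velocity_units == pytest.approx(
                v_true, abs=1e-9
            )

    def test_noisy_trace_recovered_within_5pct(self):
        trace = generate_trace(0.01, noise_sd=2e-4, n_points=31, seed=4)
        v = initial_rate(trace, window=31).velocity_units
        assert v == pytest.approx(0.01, rel=0.05)

    def test_too_short_window_rejected(self):
        trace = AssayTrace(time_s=np.arange(5.0), A340=np.linspace(1, 0.9, 5))
        with pytest.raises(DataError):
            initial_rate(trace, window=2)


class TestSpecificActivity:
    def test_paper_protein_amounts_imply_150_kda(self):
        per_mg, per_pmol, kda = specific_activity(1.044e-3, 4.0, 0.6)
        assert per_mg == pytest.approx(1.74)
        assert per_pmol == pytest.approx(2.61e-4)
        assert kda == pytest.approx(150.0)

    def test_doubling_protein_halves_specific_activity(self):
        a = specific_activity(1.0, 4.0, 0.6)[0]
        b = specific_activity(1.0, 8.0, 1.2)[0]
        assert b == pytest.approx(a / 2)

    def test_zero_protein_rejected(self):
        with pytest.raises(DataError):
            specific_activity(1.0, 0.0, 0.6)


class TestMichaelisMentenFit:
    grid = [0.125, 0.25, 0.5, 1, 2, 4]

    @pytest.mark.parametrize("method", ["LB", "NLS"])
    @pytest.mark.parametrize("vmax,km", [(2.0, 0.5), (1.044e-3, 0.34), (37.0, 8.0)])
    def test_noiseless_round_trip_is_exact(self, method, vmax, km):
        fit = fit_michaelis_menten(mm_measurements(vmax, km, self.grid), method)
        assert fit.Vmax == pytest.approx(vmax, rel=1e-9)
        assert fit.Km == pytest.approx(km, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_lb_and_nls_agree_on_noiseless_data(self):
        for vmax, km in [(1.74, 0.34), (2.6, 1.1), (0.3, 5.0)]:
            m = mm_measurements(vmax, km, self.grid)
            lb = fit_michaelis_menten(m, "LB")
            nls = fit_michaelis_menten(m, "NLS")
            assert lb.Km == pytest.approx(nls.Km, rel=1e-6)
            assert lb.Vmax == pytest.approx(nls.Vmax, rel=1e-6)

    def test_scale_equivariance(self):
        m1 = mm_measurements(1.0, 0.7, self.grid)
        m2 = [
            RateMeasurement(x.substrate_mM, x.velocity_units * 37.0)
            for x in m1
        ]
        f1 = fit_michaelis_menten(m1, "LB")
        f2 = fit_michaelis_menten(m2, "LB")
        assert f2.Vmax == pytest.approx(37.0 * f1.Vmax)
        assert f2.Km == pytest.approx(f1.Km)

    def test_specific_activity_conversion_attached(self):
        fit = fit_michaelis_menten(
            mm_measurements(1.044e-3, 0.34, self.grid),
            "LB", protein_pmol=4.0, protein_ug=0.6,
        )
        assert fit.Vmax_per_mg == pytest.approx(1.74)
        assert fit.Vmax_per_pmol == pytest.approx(1.044e-3 / 4.0)

    def test_inactive_enzyme_is_a_fit_failure(self):
        # velocities decreasing with [S]: double-reciprocal intercept < 0
        meas = [
            RateMeasurement(s, v)
            for s, v in [(0.5, 0.9), (1.0, 0.45), (2.0, 0.22), (4.0, 0.11)]
        ]
        with pytest.raises(FitError, match="intercept|non-positive"):
            fit_michaelis_menten(meas, "LB")

    def test_nonpositive_velocity_dropped_with_warning(self):
        meas = mm_measurements(2.0, 0.5, self.grid)
        meas[0] = RateMeasurement(meas[0].substrate_mM, 0.0)
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_michaelis_menten(meas, "LB")
        assert fit.n_points == len(self.grid) - 1
        assert fit.Km == pytest.approx(0.5, rel=1e-9)

    def test_fewer_than_three_concentrations_rejected(self):
        with pytest.raises(DataError, match="3 distinct"):
            fit_michaelis_menten(mm_measurements(1, 1, [0.5, 1.0]), "LB")

    def test_replicates_averaged_before_reciprocal(self):
        # replicate velocities at each [S]; averaging on the velocity
        # scale then fitting equals fitting the per-[S] means
        rng = np.random.default_rng(0)
        meas = []
        for s in self.grid:
            v = 2.0 * s / (0.5 + s)
            for _ in range(3):
                meas.append(
                    RateMeasurement(s, v * (1 + 0.05 * rng.standard_normal()))
                )
        fit = fit_michaelis_menten(meas, "LB")
        means = {}
        for m in meas:
            means.setdefault(m.substrate_mM, []).append(m.velocity_units)
        manual = fit_michaelis_menten(
            [RateMeasurement(s, float(np.mean(v))) for s, v in means.items()], "LB"
        )
        assert fit.Km == pytest.approx(manual.Km)

    def test_parameter_recovery_under_noise(self):
        """5% CV, triplicates, 200 seeded simulations: both estimators
        recover Km with <= 10% median relative error.

        Under constant-CV (multiplicative) noise the double-reciprocal
        regression is not the pathological estimator it is under
        additive noise, so NLS and LB are comparably accurate here; the
        median bound is the meaningful recovery guarantee.
        """
        km_true, vmax_true = 0.34, 1.044e-3
        nls_err, lb_err = [], []
        for seed in range(200):
            cfg = AssaySimConfig(
                variants={"wt": (vmax_true, km_true)},
                substrate_mM=self.grid, seed=seed,
                noise_cv=0.05, n_replicates=3,
            )
            table, _ = generate_assay_dataset(cfg)
            meas = measurements_from_table(table)
            nls = fit_michaelis_menten(meas, "NLS")
            lb = fit_michaelis_menten(meas, "LB")
            nls_err.append(abs(nls.Km - km_true))
            lb_err.append(abs(lb.Km - km_true))
        assert np.median(np.array(nls_err) / km_true) <= 0.10
        assert np.median(np.array(lb_err) / km_true) <= 0.10

    def test_single_noisy_dataset_within_15pct(self):
        cfg = AssaySimConfig(
            variants={"wt": (1.044e-3, 0.34)},
            substrate_mM=self.grid, seed=0, noise_cv=0.05, n_replicates=3,
        )
        table, _ = generate_assay_dataset(cfg)
        meas = measurements_from_table(table)
        for method in ("LB", "NLS"):
            fit = fit_michaelis_menten(meas, method)
            assert fit.Km == pytest.approx(0.34, rel=0.15)
            assert fit.Vmax == pytest.approx(1.044e-3, rel=0.15)


class TestRelativeActivity:
    def test_effector_equal_to_mock_is_100(self):
        eff = relative_activity([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert eff.relative_activity == pytest.approx(100.0)

    def test_noiseless_table1_style_reconstruction(self):
        eff = relative_activity([0.852] * 3, [1.0] * 3, effector="aspartate")
        assert eff.relative_activity == pytest.approx(85.2)
        assert eff.sd == pytest.approx(0.0)
        assert eff.p_value is None  # degenerate pairing, no fabricated p

    def test_hand_computed_mean_and_sd(self):
        mock = [1.0, 1.1, 0.9]
        eff_reps = [0.7, 0.8, 0.75]
        eff = relative_activity(eff_reps, mock)
        rel = [100 * v / np.mean(mock) for v in eff_reps]
        assert eff.relative_activity == pytest.approx(np.mean(rel))
        assert eff.sd == pytest.approx(np.std(rel, ddof=1))
        assert eff.n == 3 and eff.p_value is not None

    def test_zero_mock_mean_rejected(self):
        with pytest.raises(DataError):
            relative_activity([1.0], [0.0])


class TestInhibitionMode:
    mock = KineticFit(Vmax=1.74, Km=0.34, method="LB", r_squared=1.0, n_points=6)

    def fit(self, vmax, km):
        return KineticFit(Vmax=vmax, Km=km, method="LB", r_squared=1.0, n_points=6)

    @pytest.mark.parametrize(
        "vmax,km,label",
        [
            (1.74 * 1.3, 0.34 * 2.4, "Km-and-Vmax-increase (malate/fumarate-type)"),
            (1.74, 0.34, "no-effect"),
            (1.74, 0.68, "competitive-like"),
            (1.0, 0.34, "noncompetitive-like"),
            (1.0, 0.17, "uncompetitive-like"),
        ],
    )
    def test_rule_table(self, vmax, km, label):
        assert classify_inhibition_mode(self.mock, self.fit(vmax, km)) == label

    def test_changes_inside_tolerance_are_no_effect(self):
        assert (
            classify_inhibition_mode(self.mock, self.fit(1.74 * 1.1, 0.34 * 0.95))
            == "no-effect"
        )


class TestActivityProfiles:
    def test_argmax_of_measured_grid(self):
        prof = ActivityProfile(
            axis="pH", grid=[7.0, 7.3, 8.0, 9.0], mean_activity=[0.8, 1.0, 0.9, 0.6]
        )
        assert find_optimum(prof) == (7.3, 1.0)

    def test_monotone_profile_flags_boundary(self):
        prof = ActivityProfile(
            axis="temperature", grid=[20, 25, 30], mean_activity=[0.2, 0.5, 0.9]
        )
        with pytest.warns(UserWarning, match="boundary"):
            value, _ = find_optimum(prof)
        assert value == 30

    def test_tie_resolves_to_lower_grid_value(self):
        prof = ActivityProfile(
            axis="pH", grid=[7.0, 7.5, 8.0], mean_activity=[1.0, 1.0, 0.4]
        )
        with pytest.warns(UserWarning):
            value, _ = find_optimum(prof)
        assert value == 7.0


class TestInhibitionVsPh:
    def test_enhancement_flagged_with_delta(self):
        lo = relative_activity([0.85] * 3, [1, 1, 1.0], "malate", 1.0, pH=7.3)
        hi = relative_activity([0.61, 0.60, 0.59], [1, 1, 1.0], "malate", 1.0, pH=9.0)
        table = inhibition_vs_ph([lo, hi])
        assert bool(table["enhanced_at_higher_ph"].iloc[0])
        assert table["delta_vs_lowest_pH"].iloc[-1] == pytest.approx(-25.0)

    def test_identical_activities_not_flagged(self):
        lo = relative_activity([0.8, 0.9, 0.7], [1, 1, 1.0], "malate", 1.0, pH=7.3)
        hi = relative_activity([0.8, 0.9, 0.7], [1, 1, 1.0], "malate", 1.0, pH=9.0)
        assert not bool(inhibition_vs_ph([lo, hi])["enhanced_at_higher_ph"].iloc[0])

    def test_mismatched_conditions_rejected(self):
        a = relative_activity([0.8], [1.0], "malate", 1.0, pH=7.3)
        b = relative_activity([0.8], [1.0], "aspartate", 1.0, pH=9.0)
        with pytest.raises(DataError, match="mismatched"):
            inhibition_vs_ph([a, b])

    def test_ph_dependent_generator_truth_matches_flag(self):
        spec = EffectorSpec(by_ph={7.3: (1.0, 1.6), 9.0: (0.7, 2.5)},
                            vmax_factor=1.0, km_factor=1.6)
        effects = []
        for ph in (7.3, 9.0):
            cfg = AssaySimConfig(
                variants={"wt": (1.0, 0.34)}, substrate_mM=[0.5],
                seed=3, noise_cv=0.0, n_replicates=3,
                effectors={"malate": spec}, pH=ph,
            )
            table, _ = generate_assay_dataset(cfg)
            eff_v = table[table.effector == "malate"]["velocity_units"].tolist()
            mock_v = table[table.effector == "MOCK"]["velocity_units"].tolist()
            effects.append(
                relative_activity(eff_v, mock_v, "malate", 1.0, pH=ph)
            )
        table = inhibition_vs_ph(effects)
        # the generator makes inhibition stronger at pH 9 by construction
        assert bool(table["enhanced_at_higher_ph"].iloc[0])


class TestAssayTableIO:
    def test_velocity_table_round_trip(self, tmp_path):
        cfg = AssaySimConfig(
            variants={"wt": (1.044e-3, 0.34)},
            substrate_mM=[0.125, 0.25, 0.5, 1, 2, 4],
            seed=0, noise_cv=0.0, n_replicates=1,
        )
        table, _ = generate_assay_dataset(cfg)
        p = tmp_path / "assay.csv"
        table.to_csv(p, index=False)
        meas = measurements_from_table(read_assay_table(p))
        fit = fit_michaelis_menten(meas, "LB")
        assert fit.Km == pytest.approx(0.34, rel=1e-9)

    def test_trace_table_reduces_through_initial_rate(self, tmp_path):
        import pandas as pd

        rows = []
        for s, rep in [(0.5, 1), (1.0, 1), (2.0, 1)]:
            v = 0.01 * s / (0.5 + s)
            trace = generate_trace(v, condition=Condition(substrate_mM=s))
            for t, a in zip(trace.time_s, trace.A340):
                rows.append(dict(
                    variant="wt", effector="MOCK", effector_mM=0.0,
                    substrate="PEP", substrate_mM=s, pH=7.3, temp_C=30.0,
                    replicate=rep, time_s=t, A340=a,
                ))
        p = tmp_path / "traces.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        meas = measurements_from_table(read_assay_table(p))
        for m in meas:
            v_true = 0.01 * m.substrate_mM / (0.5 + m.substrate_mM)
            assert m.velocity_units == pytest.approx(v_true, abs=1e-9)

    def test_malformed_table_names_missing_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("foo,bar\n1,2\n")
        with pytest.raises(DataError, match="missing required columns"):
            read_assay_table(p)
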