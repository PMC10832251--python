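"""Bottle bioassay: validation, Abbott correction, diagnostics, classification."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from kdrkit.bioassay import (
    TIME_GRID,
    AssayRun,
    DiagnosticParams,
    MortalitySeries,
    NoDiagnosticError,
    SeriesValidationError,
    abbott_correct,
    calls_to_frame,
    classify_run,
    diagnostic_from_susceptible,
    prevalence,
    read_mortality_csv,
    time_to_full_mortality,
    validate_series,
)
from kdrkit.synthetic import (
    BIOASSAY_TABLE,
    DIAGNOSTIC_DOSE,
    DIAGNOSTIC_TIME,
    KillCurve,
    SimulationConfig,
    bioassay_survey_runs,
    make_susceptible_panel,
    simulate_bioassay,
)


def series(dead, n=25, dose=4.5, bottle="b1", location="x"):
    return MortalitySeries(
        bottle_id=bottle, location=location, dose=dose, n_insects=n,
        time_points=TIME_GRID, cumulative_dead=tuple(dead),
    )


def control_series(n=25, dead=None):
    return series(dead or (0,) * len(TIME_GRID), n=n, dose=0, bottle="ctl")


class TestValidateSeries:
    def test_monotone_full_kill_series_is_valid(self):
        s = series((0, 2, 8, 15, 25, 25, 25, 25, 25))
        assert validate_series(s) is s

    def test_dead_above_n_insects_rejected(self):
        with pytest.raises(SeriesValidationError, match="26"):
            validate_series(series((0, 2, 8, 15, 26, 26, 26, 26, 26)))

    def test_decreasing_deaths_rejected(self):
        with pytest.raises(SeriesValidationError, match="decreased"):
            validate_series(series((0, 10, 8, 15, 25, 25, 25, 25, 25)))

    def test_off_grid_time_lookup_fails(self):
        s = series((0, 2, 8, 15, 25, 25, 25, 25, 25))
        with pytest.raises(SeriesValidationError, match="grid"):
            s.mortality_at(62)


class TestAbbottCorrection:
    def test_identity_at_zero_control(self):
        assert abbott_correct(1.0, 0.0) == 1.0
        assert abbott_correct(0.42, 0.0) == pytest.approx(0.42)

    def test_formula(self):
        assert abbott_correct(0.9, 0.05) == pytest.approx(0.8947, abs=1e-4)

    def test_full_control_mortality_undefined(self):
        with pytest.raises(ValueError):
            abbott_correct(0.5, 1.0)

    @given(
        st.floats(0, 1), st.floats(0, 0.99),
    )
    def test_bounded_and_monotone_in_treated(self, treated, control):
        corrected = abbott_correct(treated, control)
        assert 0.0 <= corrected <= 1.0
        higher = abbott_correct(min(1.0, treated + 0.05), control)
        assert higher >= corrected - 1e-12


class TestDiagnosticFromSusceptible:
    def test_packaged_panel_resolves_to_published_parameters(self):
        params = diagnostic_from_susceptible(make_susceptible_panel())
        assert (params.dose, params.time) == (DIAGNOSTIC_DOSE, DIAGNOSTIC_TIME)

    def test_lowest_dose_killing_everything_wins(self):
        full_at_15 = KillCurve(midpoint=5.0, slope=3.0, full_kill_time=15)
        panel = [
            simulate_bioassay("susceptible", dose=d, curve=full_at_15,
                              location=f"s{d}")
            for d in (0.5, 1.0)
        ]
        params = diagnostic_from_susceptible(panel)
        assert (params.dose, params.time) == (0.5, 15)

    def test_no_full_kill_anywhere_is_an_error(self):
        plateau = KillCurve(midpoint=60.0, slope=10.0, full_kill_time=None)
        panel = [
            simulate_bioassay("susceptible", dose=d, curve=plateau, location=f"s{d}")
            for d in (1.0, 2.0)
        ]
        with pytest.raises(NoDiagnosticError):
            diagnostic_from_susceptible(panel)

    def test_single_dose_panel_rejected(self):
        panel = [simulate_bioassay("susceptible", dose=4.5)]
        with pytest.raises(ValueError, match="two doses"):
            diagnostic_from_susceptible(panel)


class TestClassifyRun:
    params = DiagnosticParams(dose=4.5, time=60)

    def test_susceptible_run(self):
        run = simulate_bioassay("susceptible")
        call = classify_run(run, self.params)
        assert call.status == "susceptible"
        assert call.time_to_full_mortality == 60
        assert call.mortality_at_diagnostic == 100.0

    def test_resistant_run_reaches_full_kill_late(self):
        run = simulate_bioassay("resistant")
        call = classify_run(run, self.params)
        assert call.status == "resistant"
        assert call.time_to_full_mortality == 90

    def test_run_never_reaching_full_kill(self):
        plateau = KillCurve(midpoint=70.0, slope=15.0, full_kill_time=None)
        run = simulate_bioassay("resistant", curve=plateau)
        call = classify_run(run, self.params)
        assert call.status == "resistant"
        assert call.time_to_full_mortality is None

    def test_dose_mismatch_rejected(self):
        run = simulate_bioassay("susceptible", dose=9.0)
        with pytest.raises(ValueError, match="dose"):
            classify_run(run, self.params)

    def test_high_control_mortality_invalidates_run(self):
        treated = [series((0, 5, 10, 15, 25, 25, 25, 25, 25), bottle=f"b{i}")
                   for i in range(4)]
        bad_control = control_series(dead=(0, 1, 2, 3, 5, 5, 5, 5, 5))  # 20% at 60
        run = AssayRun(location="x", treated=tuple(treated), control=bad_control)
        call = classify_run(run, self.params)
        assert call.status == "invalid"

    def test_moderate_control_mortality_applies_abbott_with_warning(self):
        treated = [series((0, 5, 10, 15, 24, 25, 25, 25, 25), bottle=f"b{i}")
                   for i in range(4)]
        control = control_series(dead=(0, 0, 0, 1, 2, 2, 2, 2, 2))  # 8% at 60
        run = AssayRun(location="x", treated=tuple(treated), control=control)
        with pytest.warns(UserWarning, match="Abbott"):
            call = classify_run(run, self.params)
        # raw 96% -> corrected (0.96-0.08)/0.92 = 95.7% < 100%
        assert call.status == "resistant"
        assert call.mortality_at_diagnostic == pytest.approx(95.65, abs=0.01)

    def test_monotone_in_treated_deaths(self):
        """Raising any cumulative death count never flips resistant ->
        susceptible at a later time nor susceptible -> resistant."""
        base_dead = (0, 5, 10, 15, 20, 22, 25, 25, 25)  # resistant profile
        base = AssayRun(
            location="x",
            treated=(series(base_dead),),
            control=control_series(),
        )
        base_call = classify_run(base, self.params)
        assert base_call.status == "resistant"
        for idx in range(len(TIME_GRID)):
            bumped = list(base_dead)
            delta = 25 - bumped[idx]
            for j in range(idx, len(bumped)):
                bumped[j] = min(25, bumped[j] + delta)
            run = AssayRun(
                location="x", treated=(series(tuple(bumped)),),
                control=control_series(),
            )
            call = classify_run(run, self.params)
            if base_call.time_to_full_mortality is not None:
                assert call.time_to_full_mortality <= base_call.time_to_full_mortality
            if base_call.status == "susceptible":
                assert call.status == "susceptible"


class TestPrevalence:
    def test_published_survey(self):
        params = DiagnosticParams(DIAGNOSTIC_DOSE, DIAGNOSTIC_TIME)
        calls = [classify_run(r, params) for r in bioassay_survey_runs()]
        statuses = {c.location: c.status for c in calls}
        for location, _date, status, time100 in BIOASSAY_TABLE:
            assert statuses[location] == status
        assert sum(1 for c in calls if c.status == "resistant") == 2
        assert prevalence(calls) == 12.5

    def test_all_susceptible(self):
        params = DiagnosticParams(4.5, 60)
        calls = [classify_run(simulate_bioassay("susceptible"), params)]
        assert prevalence(calls) == 0.0

    def test_one_of_three(self):
        params = DiagnosticParams(4.5, 60)
        runs = [simulate_bioassay("resistant"), simulate_bioassay("susceptible"),
                simulate_bioassay("susceptible")]
        assert prevalence([classify_run(r, params) for r in runs]) == 33.3

    def test_all_invalid_is_error(self):
        from kdrkit.bioassay import ResistanceCall

        with pytest.warns(UserWarning, match="invalid"), pytest.raises(ValueError):
            prevalence([ResistanceCall("x", "invalid", None, None)])


class TestParameterRecovery:
    def test_stochastic_resistant_populations_classified_resistant(self):
        """Simulated resistant populations (kill completing only after the
        diagnostic time) are recovered as resistant in >= 95% of replicates."""
        params = DiagnosticParams(DIAGNOSTIC_DOSE, DIAGNOSTIC_TIME)
        hits = 0
        n_replicates = 500
        for i in range(n_replicates):
            config = SimulationConfig(seed=700_000 + i, binomial_sampling=True)
            run = simulate_bioassay("resistant", config)
            if classify_run(run, params).status == "resistant":
                hits += 1
        assert hits / n_replicates >= 0.95

    def test_diagnostic_then_classify_panel_is_all_susceptible(self):
        panel = make_susceptible_panel()
        params = diagnostic_from_susceptible(panel)
        at_dose = [r for r in panel if r.dose == params.dose]
        assert at_dose
        for run in at_dose:
            assert classify_run(run, params).status == "susceptible"


class TestCsv:
    def test_round_trip_through_frame_and_csv(self, tmp_path):
        from kdrkit.synthetic import _runs_to_frame

        runs = bioassay_survey_runs(seed=1)
        csv = tmp_path / "runs.csv"
        _runs_to_frame(runs).to_csv(csv, index=False)
        loaded = read_mortality_csv(csv)
        assert len(loaded) == len(runs)
        params = DiagnosticParams(DIAGNOSTIC_DOSE, DIAGNOSTIC_TIME)
        calls = [classify_run(r, params) for r in loaded]
        assert prevalence(calls) == 12.5
        frame = calls_to_frame(calls)
        assert list(frame["status"]).count("resistant") == 2

    def test_missing_time_column_is_schema_error(self, tmp_path):
        csv = tmp_path / "bad.csv"
        csv.write_text("location,date,bottle_id,dose_ug_ml,n_insects,dead_0\nx,d,b,4.5,25,0\n")
        with pytest.raises(ValueError, match="dead_15"):
            read_mortality_csv(csv)

    def test_missing_control_bottle_rejected(self, tmp_path):
        cols = "location,date,bottle_id,dose_ug_ml,n_insects," + ",".join(
            f"dead_{t}" for t in TIME_GRID
        )
        csv = tmp_path / "noctl.csv"
        csv.write_text(cols + "\nx,d,b1,4.5,25,0,0,0,0,25,25,25,25,25\n")
        with pytest.raises(SeriesValidationError, match="control"):
            read_mortality_csv(csv)
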