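"""Generator determinism, noiseless model identities, and parameter-recovery
closure of the synthetic-data module."""

import math

import numpy as np
import pandas as pd
import pytest

from punctakit import frap, puncta, survival
from punctakit.simulate import (
    CohortSimParams,
    DecaySimParams,
    FrapSimParams,
    ImageSimParams,
    SimulationError,
    simulate_cell_image,
    simulate_cohort,
    simulate_decay_traces,
    simulate_event_cohort,
    simulate_frap_trace,
    simulate_frap_traces,
)


class TestFrapGenerator:
    def test_noiseless_trace_is_model_identity(self):
        tau = math.log(2) / 30
        trace = simulate_frap_trace(FrapSimParams(mobile_fraction=0.7, rate_per_s=tau))
        norm = frap.normalize_frap_trace(trace)
        t = trace.times[trace.post_mask]
        np.testing.assert_allclose(
            norm[trace.post_mask], 0.7 * (1 - np.exp(-tau * t)), atol=1e-12
        )

    def test_zero_mobile_fraction_gives_flat_floor(self):
        trace = simulate_frap_trace(FrapSimParams(mobile_fraction=0.0))
        norm = frap.normalize_frap_trace(trace)
        np.testing.assert_allclose(norm[trace.post_mask], 0.0, atol=1e-12)

    def test_monte_carlo_mean_matches_model(self):
        """Per-time sample mean of 1000 noisy traces within 3 SE of the model."""
        params = FrapSimParams(noise_sd=0.02, seed=123)
        traces = simulate_frap_traces(params, 1000)
        # invert the raw scaling using the emitted ground truth
        truth = traces[0].truth
        stack = np.vstack(
            [
                (tr.bleached_intensity - tr.truth["floor"])
                / (tr.truth["scale"] * tr.truth["depth"])
                for tr in traces
            ]
        )
        t_post = traces[0].times[traces[0].post_mask]
        model = 0.7 * (1 - np.exp(-truth["rate_per_s"] * t_post))
        post = traces[0].post_mask
        se = 0.02 / math.sqrt(len(traces))
        assert np.all(np.abs(stack[:, post].mean(axis=0) - model) <= 3 * se)

    def test_determinism(self):
        a = simulate_frap_trace(FrapSimParams(noise_sd=0.05, seed=7))
        b = simulate_frap_trace(FrapSimParams(noise_sd=0.05, seed=7))
        np.testing.assert_array_equal(a.bleached_intensity, b.bleached_intensity)

    def test_parameter_validation(self):
        with pytest.raises(SimulationError):
            FrapSimParams(schedule=(0.0, 5.0, 5.0))
        with pytest.raises(SimulationError):
            FrapSimParams(noise_sd=-0.1)


class TestImageGenerator:
    def test_diffuse_noiseless_cv_zero(self):
        params = ImageSimParams(puncta_count=0, read_noise_sd=0.0)
        _, _, mask, truth = simulate_cell_image(params)
        assert truth.realized_cv == 0.0

    def test_punctate_preset_exceeds_threshold(self):
        params = ImageSimParams(
            puncta_count=5, puncta_amplitude=8000.0, read_noise_sd=0.0, seed=2
        )
        reporter, _, mask, truth = simulate_cell_image(params)
        assert puncta.cell_cv(reporter[mask]) > 0.62
        assert truth.realized_cv == pytest.approx(puncta.cell_cv(reporter[mask]))

    def test_design_cv_solved_for_target(self):
        for target, maker in [
            (0.35, ImageSimParams.diffuse_preset),
            (1.0, ImageSimParams.punctate_preset),
        ]:
            _, _, _, truth = simulate_cell_image(maker(target_cv=target, seed=3))
            assert truth.realized_cv == pytest.approx(target, abs=0.05)

    def test_intensity_scaling_leaves_cv_unchanged(self):
        params = ImageSimParams(puncta_count=3, read_noise_sd=0.0, seed=5)
        reporter, _, mask, _ = simulate_cell_image(params)
        assert puncta.cell_cv(reporter[mask] * 10) == pytest.approx(
            puncta.cell_cv(reporter[mask])
        )

    def test_puncta_centers_inside_mask(self):
        _, _, mask, truth = simulate_cell_image(
            ImageSimParams(puncta_count=8, seed=11)
        )
        for py, px in truth.puncta_centers:
            assert mask[int(round(py)), int(round(px))]

    def test_cell_must_fit_in_frame(self):
        with pytest.raises(SimulationError, match="fit"):
            ImageSimParams(image_shape=(32, 32), cell_radius=30.0)

    def test_determinism(self):
        a = simulate_cell_image(ImageSimParams(puncta_count=4, seed=9))[0]
        b = simulate_cell_image(ImageSimParams(puncta_count=4, seed=9))[0]
        np.testing.assert_array_equal(a, b)


class TestCohortGenerator:
    def test_every_cell_observed_alive_on_day_one(self):
        tracks, truth = simulate_cohort(CohortSimParams(n_cells=300, seed=1))
        day1 = tracks[tracks.day == 1.0]
        assert set(day1.cell_id) == set(truth.cell_id)
        assert day1["alive"].all()

    def test_cv_regimes_follow_latent_puncta_state(self):
        params = CohortSimParams(n_cells=300, seed=2)
        tracks, truth = simulate_cohort(params)
        merged = tracks[tracks.alive].merge(
            truth[["cell_id", "puncta_time"]], on="cell_id"
        )
        punctate = merged[merged.puncta_time <= merged.day]
        diffuse = merged[merged.puncta_time > merged.day]
        assert (punctate["cv"] > 0.62).all()
        assert diffuse["cv"].mean() < 0.5

    def test_null_cohort_hazard_near_one(self):
        params = CohortSimParams(
            n_cells=2000,
            groups=("A", "B"),
            log_hazard_death={"A": 0.0, "B": 0.0},
            log_hazard_puncta={"A": 0.0, "B": 0.0},
            seed=3,
        )
        events = simulate_event_cohort(params)
        res = survival.fit_cox(events, reference="A")[0]
        assert abs(res.beta) <= 3 * res.se

    def test_track_pipeline_recovers_simulated_hazard(self):
        """Day-grid observation, event extraction, and a stratified Cox fit
        recover the simulated death log-hazard within 3 SE."""
        params = CohortSimParams(
            n_cells=2000,
            groups=("A", "B"),
            log_hazard_death={"A": 0.0, "B": math.log(1.6)},
            log_hazard_puncta={"A": 0.0, "B": 0.0},
            seed=4,
        )
        tracks, _ = simulate_cohort(params)
        events = puncta.extract_event_table(tracks)
        events = events.rename(columns={"death_time": "time", "death_event": "event"})
        res = survival.fit_cox(
            events, group_col="group", reference="A", strata_col="stratum"
        )[0]
        assert abs(res.beta - math.log(1.6)) <= 3 * res.se

    def test_censor_before_first_imaging_day_rejected(self):
        with pytest.raises(SimulationError, match="censor_day"):
            CohortSimParams(censor_day=0.5)

    def test_empty_groups_rejected(self):
        with pytest.raises(SimulationError, match="non-empty"):
            CohortSimParams(groups=())

    def test_determinism(self):
        a, _ = simulate_cohort(CohortSimParams(n_cells=100, seed=5))
        b, _ = simulate_cohort(CohortSimParams(n_cells=100, seed=5))
        pd.testing.assert_frame_equal(a, b)


class TestDecayGenerator:
    def test_noiseless_model_identity(self):
        traces, _ = simulate_decay_traces(DecaySimParams(half_life_h=10.0))
        tr = traces[0]
        k = math.log(2) / 10.0
        np.testing.assert_allclose(
            tr.values, (tr.t1 - tr.t0) * np.exp(-k * tr.times_h) + tr.t0
        )

    def test_per_experiment_recovery_within_5_percent(self):
        traces, _ = simulate_decay_traces(
            DecaySimParams(half_life_h=10.0, noise_cv=0.02, seed=6)
        )
        from punctakit import flux

        per_exp, _ = flux.aggregate_flux(
            [flux.analyze_trace(t, mode="background-subtracted") for t in traces]
        )
        assert np.all(np.abs(per_exp["mean"] - 10.0) / 10.0 <= 0.05)

    def test_invalid_half_life_rejected(self):
        with pytest.raises(SimulationError):
            DecaySimParams(half_life_h=0.0)

    def test_determinism(self):
        a, _ = simulate_decay_traces(DecaySimParams(noise_cv=0.05, seed=7))
        b, _ = simulate_decay_traces(DecaySimParams(noise_cv=0.05, seed=7))
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.values, tb.values)
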