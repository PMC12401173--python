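"""Generator contracts: round-trips, determinism, validation, convergence."""

import dataclasses

import numpy as np
import pytest

from spermfx.errors import SpecValidationError
from spermfx.motility_kinematics import analyze_tracks, compute_kinematics
from spermfx.synthetic_data import (
    CalTraceTruth,
    CohortSpec,
    P4TraceTruth,
    TrackSpec,
    calibration_trace_spec,
    make_calibration_trace,
    make_cohort,
    make_p4_trace,
    make_tracks,
    make_tracks_with_truth,
    p4_trace_spec,
)
from spermfx.trace_io import read_trace, write_trace


class TestTraceGenerators:
    def test_events_lie_on_sample_boundaries(self, noiseless_cal_trace):
        dt = noiseless_cal_trace.dt
        for e in noiseless_cal_trace.events:
            assert (e.time / dt) == pytest.approx(round(e.time / dt), abs=1e-9)

    def test_events_preserved_through_serialization(self, tmp_path, noiseless_cal_trace):
        path = tmp_path / "cal.tsv"
        write_trace(noiseless_cal_trace, path)
        back = read_trace(path)
        assert back.events == noiseless_cal_trace.events

    def test_seeded_determinism_bit_identical(self, cal_truth, p4_truth):
        spec = calibration_trace_spec(cal_truth, noise_sd=1.0)
        a = make_calibration_trace(cal_truth, spec, seed=9)
        b = make_calibration_trace(cal_truth, spec, seed=9)
        np.testing.assert_array_equal(a.fluorescence, b.fluorescence)
        pspec = p4_trace_spec(p4_truth, noise_sd=2.0)
        np.testing.assert_array_equal(
            make_p4_trace(p4_truth, pspec, seed=9).fluorescence,
            make_p4_trace(p4_truth, pspec, seed=9).fluorescence,
        )

    def test_schedule_with_tiny_plateau_rejected(self, cal_truth):
        spec = calibration_trace_spec(cal_truth, sampling_rate=5.0, step_interval=0.6)
        with pytest.raises(SpecValidationError):
            make_calibration_trace(cal_truth, spec)

    def test_kcl_steps_must_increase_and_exceed_baseline(self):
        with pytest.raises(SpecValidationError):
            CalTraceTruth(resting_em=-50, fluorescence_per_mv=1.0,
                          kcl_steps=(12.5, 7.5))
        with pytest.raises(SpecValidationError):
            CalTraceTruth(resting_em=-50, fluorescence_per_mv=1.0,
                          kcl_steps=(4.0, 7.5), baseline_k=5.0)

    def test_mn_level_above_baseline_rejected(self, p4_truth):
        truth = dataclasses.replace(p4_truth, mn_level=150.0)
        with pytest.raises(SpecValidationError):
            make_p4_trace(truth, p4_trace_spec(truth, baseline_fluorescence=100.0))

    def test_unresolvable_half_times_rejected(self, p4_truth):
        truth = dataclasses.replace(p4_truth, tau_up=0.05)
        with pytest.raises(SpecValidationError):
            make_p4_trace(truth, p4_trace_spec(truth, sampling_rate=10.0))


class TestTrackGenerator:
    def test_immotile_only_zero_noise_gives_zero_vcl(self):
        spec = TrackSpec(n_tracks=20, class_mix={"immotile": 1.0},
                         position_noise_sd=0.0)
        for track in make_tracks(spec, seed=1):
            assert compute_kinematics(track).vcl == 0.0

    def test_fast_targeting_spec_classified_fast(self):
        # all motile tracks above the 35 µm/s cut-off
        spec = TrackSpec(
            n_tracks=300,
            class_mix={"progressive": 0.5, "non_progressive": 0.5},
            speed_ranges={"progressive": (40.0, 80.0),
                          "non_progressive": (40.0, 80.0),
                          "immotile": (0.0, 0.0)},
        )
        summaries, _ = analyze_tracks(make_tracks(spec, seed=2))
        frac_fast = np.mean([s.velocity_class == "fast" for s in summaries])
        assert frac_fast >= 0.95

    def test_fixed_seed_identical_coordinates(self):
        spec = TrackSpec(n_tracks=10)
        a = make_tracks(spec, seed=3)
        b = make_tracks(spec, seed=3)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(SpecValidationError):
            TrackSpec(class_mix={"progressive": 0.5, "immotile": 0.2})

    def test_truth_labels_match_empirical_speed(self):
        spec = TrackSpec(n_tracks=100, position_noise_sd=0.0)
        tracks, labels = make_tracks_with_truth(spec, seed=4)
        for track, label in zip(tracks, labels):
            vcl = compute_kinematics(track).vcl
            lo, hi = spec.speed_ranges[label]
            if label == "immotile":
                assert vcl == 0.0
            else:
                # VCL estimates the generating speed up to turning discretization
                assert lo * 0.9 <= vcl <= hi * 1.1


class TestCohortGenerator:
    def _spec(self, **kw):
        base = dict(n_subjects=10, sample_class="Nz", variable="v", units="u",
                    dgc_median=36.0, dgc_mad=9.0, ca0_median=52.0, ca0_mad=13.0,
                    seed=0)
        base.update(kw)
        return CohortSpec(**base)

    def test_zero_dispersion_gives_constant_arms(self):
        c = make_cohort(self._spec(dgc_mad=0.0, ca0_mad=0.0))
        assert set(c.dgc) == {36.0}
        assert set(c.ca0) == {52.0}

    def test_medians_converge_at_n200(self):
        c = make_cohort(self._spec(n_subjects=200, seed=6))
        assert np.median(c.dgc) == pytest.approx(36.0, rel=0.10)
        assert np.median(c.ca0) == pytest.approx(52.0, rel=0.10)

    def test_mad_converges_at_n2000(self):
        c = make_cohort(self._spec(n_subjects=2000, seed=6))
        mad = np.median(np.abs(c.dgc - np.median(c.dgc)))
        assert mad == pytest.approx(9.0, rel=0.15)

    def test_identical_arms_full_correlation_gives_zero_differences(self):
        c = make_cohort(self._spec(ca0_median=36.0, ca0_mad=9.0, correlation=1.0))
        np.testing.assert_allclose(c.dgc - c.ca0, 0.0, atol=1e-12)

    def test_calibrated_sample_median_is_exact(self):
        c = make_cohort(self._spec(n_subjects=11, calibrate_median=True))
        assert np.median(c.dgc) == pytest.approx(36.0, abs=1e-9)
        assert np.median(c.ca0) == pytest.approx(52.0, abs=1e-9)

    def test_negative_median_variables(self):
        c = make_cohort(self._spec(dgc_median=-78.9, dgc_mad=8.1,
                                   ca0_median=-66.8, ca0_mad=8.6, n_subjects=500,
                                   seed=8))
        assert np.all(c.dgc < 0)
        assert np.median(c.dgc) == pytest.approx(-78.9, rel=0.1)

    def test_mad_larger_than_median_rejected(self):
        with pytest.raises(SpecValidationError):
            make_cohort(self._spec(dgc_mad=40.0))

    def test_seeded_determinism(self):
        a = make_cohort(self._spec(seed=13))
        b = make_cohort(self._spec(seed=13))
        np.testing.assert_array_equal(a.dgc, b.dgc)
        np.testing.assert_array_equal(a.ca0, b.ca0)
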