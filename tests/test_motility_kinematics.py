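"""CASA kinematics geometry, classification rules, and sample profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermfx.errors import TrackTooShortError
from spermfx.motility_kinematics import (
    CasaConfig,
    KinematicSummary,
    analyze_tracks,
    classify_track,
    compute_kinematics,
    summarize_motility,
)
from spermfx.synthetic_data import TrackSpec, make_tracks
from spermfx.trace_io import SpermTrack


def _track(positions, frame_rate=1.0, tid="t"):
    return SpermTrack(track_id=tid, frame_rate=frame_rate,
                      positions=np.asarray(positions, dtype=float))


def _summary(str_pct, vcl):
    return KinematicSummary(track_id="s", vcl=vcl, vsl=0.0, vap=0.0,
                            str_pct=str_pct, velocity_class="fast",
                            motility_class="immotile")


class TestGeometry:
    def test_straight_line_all_velocities_equal(self):
        # 10 µm per frame at 1 Hz: collinear geometry forces VCL = VSL = VAP
        p = np.column_stack([10.0 * np.arange(11), np.zeros(11)])
        k = compute_kinematics(_track(p))
        assert k.vcl == pytest.approx(10.0)
        assert k.vsl == pytest.approx(10.0)
        assert k.vap == pytest.approx(10.0)
        assert k.str_pct == pytest.approx(100.0)
        assert k.velocity_class == "medium"  # VCL of 10 sits at the slow/medium edge
        assert k.motility_class == "progressive"

    def test_stationary_track_is_immotile(self):
        p = np.zeros((10, 2))
        k = compute_kinematics(_track(p))
        assert k.vcl == 0.0 and k.vsl == 0.0 and k.str_pct == 0.0
        assert k.motility_class == "immotile"

    def test_closed_square_path(self):
        # perimeter 40 µm over 4 s: VCL 10, zero net displacement, STR 0
        p = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], dtype=float)
        k = compute_kinematics(_track(p))
        assert k.vcl == pytest.approx(10.0)
        assert k.vsl == pytest.approx(0.0)
        assert k.str_pct == pytest.approx(0.0)

    def test_velocity_ordering_on_random_walks(self, rng):
        for _ in range(200):
            steps = rng.normal(0, 2.0, size=(30, 2))
            k = compute_kinematics(_track(np.cumsum(steps, axis=0)))
            assert k.vsl <= k.vap * 1.01
            assert k.vap <= k.vcl * 1.01

    @given(st.floats(min_value=0, max_value=2 * np.pi),
           st.floats(min_value=-500, max_value=500),
           st.floats(min_value=-500, max_value=500))
    @settings(max_examples=30, derandomize=True)
    def test_rigid_motion_invariance(self, angle, dx, dy):
        rng = np.random.default_rng(7)
        p = np.cumsum(rng.normal(0, 1.5, size=(25, 2)), axis=0)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = p @ rot.T + [dx, dy]
        a = compute_kinematics(_track(p))
        b = compute_kinematics(_track(moved))
        for attr in ("vcl", "vsl", "vap", "str_pct"):
            assert getattr(b, attr) == pytest.approx(getattr(a, attr), rel=1e-9, abs=1e-9)

    def test_time_rescaling_equivariance(self):
        rng = np.random.default_rng(3)
        p = np.cumsum(rng.normal(0, 1.5, size=(25, 2)), axis=0)
        slow = compute_kinematics(_track(p, frame_rate=1.0))
        fast = compute_kinematics(_track(p, frame_rate=2.0))
        assert fast.vcl == pytest.approx(2 * slow.vcl)
        assert fast.vsl == pytest.approx(2 * slow.vsl)
        assert fast.str_pct == pytest.approx(slow.str_pct)

    def test_too_few_frames_rejected(self):
        with pytest.raises(TrackTooShortError):
            compute_kinematics(_track(np.zeros((4, 2))))


class TestClassification:
    @pytest.mark.parametrize(
        "str_pct, vcl, expected",
        [
            (85.0, 40.0, "progressive"),
            (0.0, 40.0, "immotile"),
            (80.0, 40.0, "non_progressive"),  # boundary is strict
            (50.0, 20.0, "non_progressive"),
            (90.0, 5.0, "immotile"),  # below the VCL floor
        ],
    )
    def test_floor_mode(self, str_pct, vcl, expected):
        assert classify_track(_summary(str_pct, vcl)) == expected

    def test_strict_mode_follows_str_literally(self):
        cfg = CasaConfig(immotile_mode="strict")
        assert classify_track(_summary(90.0, 5.0), cfg) == "progressive"
        assert classify_track(_summary(0.0, 40.0), cfg) == "immotile"

    def test_classes_partition_random_tracks(self):
        tracks = make_tracks(TrackSpec(n_tracks=300), seed=5)
        summaries, profile = analyze_tracks(tracks)
        assert len(summaries) == 300
        total = (profile.pct_progressive + profile.pct_non_progressive
                 + profile.pct_immotile)
        assert total == pytest.approx(100.0)


class TestProfiles:
    def test_all_progressive(self):
        s = [KinematicSummary("t", 50, 48, 49, 95, "fast", "progressive")
             for _ in range(300)]
        p = summarize_motility(s)
        assert (p.pct_progressive, p.pct_non_progressive, p.pct_immotile) == (100, 0, 0)

    def test_single_track(self):
        p = summarize_motility([KinematicSummary("t", 5, 0, 0, 0, "slow", "immotile")])
        assert p.pct_immotile == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_motility([])

    def test_short_tracks_disclosed_not_dropped_silently(self):
        good = SpermTrack("g", 50.0, np.cumsum(np.ones((20, 2)), axis=0))
        short = SpermTrack("s", 50.0, np.ones((3, 2)))
        _, profile = analyze_tracks([good, short])
        assert profile.n_tracks == 1
        assert profile.n_unanalyzed == 1

    def test_generated_mix_recovered_within_3_points(self):
        spec = TrackSpec(n_tracks=1000)  # 79/13/8 mix
        _, profile = analyze_tracks(make_tracks(spec, seed=11))
        assert profile.pct_progressive == pytest.approx(79, abs=3)
        assert profile.pct_non_progressive == pytest.approx(13, abs=3)
        assert profile.pct_immotile == pytest.approx(8, abs=3)
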