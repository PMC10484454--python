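import numpy as np
import pytest
from hypothesis import given, strategies as st

from wormscore import (SwimVideoTruth, WormTrack, binarize_frames,
                       count_body_bends, defect_fraction, generate_swim_video,
                       records_from_video, render_clean_frame,
                       swim_defect_test, track_worms)


# ------------------------------------------------------------ simulator

def test_frame_count_is_fps_times_duration():
    truth = SwimVideoTruth(fps=30, duration_s=30, frame_shape=(128, 128),
                           worm_length_px=40, amplitude_px=5)
    assert truth.n_frames == 900


def test_nyquist_margin_enforced():
    with pytest.raises(ValueError, match="fps/4"):
        SwimVideoTruth(bend_freq_hz=10.0, fps=30)


def test_static_worm_shape_identical_every_frame():
    truth = SwimVideoTruth(bend_freq_hz=0.0, fps=30, duration_s=3,
                           frame_shape=(128, 128), worm_length_px=40,
                           amplitude_px=5, seed=4, drift_px_per_s=0.0,
                           noise_sd=0.0)
    frames, _ = generate_swim_video(truth, 1)
    assert all((frames[k] == frames[0]).all() for k in range(len(frames)))


def test_overcrowded_placement_raises():
    truth = SwimVideoTruth(frame_shape=(128, 128), duration_s=2)
    with pytest.raises(ValueError, match="cannot place"):
        generate_swim_video(truth, 50)


# ------------------------------------------------------------ binarize

def test_binarize_recovers_rendered_worm_pixels(small_video):
    truth, frames, worms = small_video
    binary = binarize_frames(frames)
    for k in (50, 150, 250):
        mask_true = render_clean_frame(truth, worms, k) > 0
        overlap = (binary[k] & mask_true).sum() / mask_true.sum()
        assert overlap >= 0.90


def test_binarize_component_count_matches_worm_count(small_video):
    from wormscore.motility import _frame_components
    _, frames, _ = small_video
    binary = binarize_frames(frames)
    for k in range(0, len(binary), 25):
        assert len(_frame_components(binary[k], min_area=20)) == 2


def test_fixed_threshold_on_black_stack_is_all_background():
    frames = np.zeros((5, 32, 32), dtype=np.uint8)
    out = binarize_frames(frames, threshold="fixed", level=0.5)
    assert not out.any()


def test_otsu_on_constant_stack_raises():
    frames = np.full((5, 32, 32), 7, dtype=np.uint8)
    with pytest.raises(ValueError, match="[Oo]tsu"):
        binarize_frames(frames, threshold="otsu")


def test_binarize_rejects_tiny_stack():
    with pytest.raises(ValueError):
        binarize_frames(np.zeros((1, 8, 8), dtype=np.uint8))


# ------------------------------------------------------------ tracking

def test_two_worms_give_two_tracks_matching_truth(small_video):
    truth, frames, worms = small_video
    binary = binarize_frames(frames)
    tracks = track_worms(binary, fps=truth.fps)
    assert len(tracks) == 2
    # greedily pair tracks to ground-truth worms by initial position
    for tr in tracks:
        x0, y0 = tr.centroids[0]
        dists = np.hypot(worms["cx"] - x0, worms["cy"] - y0)
        w = worms.iloc[int(dists.idxmin())]
        t_s = tr.frames / truth.fps
        ex = w["cx"] + w["drift_dx"] * t_s
        ey = w["cy"] + w["drift_dy"] * t_s
        rms = np.sqrt(np.mean((tr.centroids[:, 0] - ex) ** 2
                              + (tr.centroids[:, 1] - ey) ** 2))
        assert rms < 2.0
        assert tr.n_frames == truth.n_frames


def test_worm_leaving_field_truncates_track():
    truth = SwimVideoTruth(bend_freq_hz=1.0, fps=30, duration_s=10,
                           frame_shape=(128, 128), worm_length_px=40,
                           amplitude_px=5, seed=9, drift_px_per_s=12.0)
    # placed near the edge, drifting out (drift is perpendicular to theta=0,
    # i.e. straight down toward y=128)
    frames, _ = generate_swim_video(truth, 1, positions=[(64.0, 100.0, 0.0)])
    binary = binarize_frames(frames)
    tracks = track_worms(binary, fps=truth.fps)
    main = max(tracks, key=lambda t: t.n_frames)
    assert main.frames[-1] < truth.n_frames - 1  # gone before the video ends
    assert main.n_frames < truth.n_frames


# ------------------------------------------------------------ bend count

def _track_from_signal(sig, fps=30.0):
    n = len(sig)
    return WormTrack(0, np.arange(n), np.zeros((n, 2)), np.asarray(sig), fps)


def test_constant_signal_counts_zero_bends():
    rec = count_body_bends(_track_from_signal(np.full(120, 0.8)))
    assert rec.bbps == 0.0


def test_sinusoidal_signal_recovers_its_frequency():
    t = np.arange(0, 20, 1 / 30)
    rec = count_body_bends(_track_from_signal(0.9 + 0.05 * np.sin(2 * np.pi * 1.5 * t)))
    assert rec.bbps == pytest.approx(1.5, rel=0.05)


def test_too_short_track_rejected():
    with pytest.raises(ValueError, match="at least 1 s"):
        count_body_bends(_track_from_signal(np.ones(10)))


def test_full_chain_recovers_wild_type_magnitude():
    """A worm thrashing at the wild-type rate (1.86 bends/s) is recovered
    within 10% by the complete video chain."""
    truth = SwimVideoTruth(bend_freq_hz=1.86, fps=30, duration_s=10,
                           frame_shape=(256, 256), seed=21)
    frames, _ = generate_swim_video(truth, 2)
    recs = records_from_video(frames, fps=30)
    assert len(recs) == 2
    for r in recs:
        assert abs(r.bbps - 1.86) / 1.86 < 0.10


# ------------------------------------------------------- defect fraction

def test_defect_fraction_examples():
    assert defect_fraction([2.0, 2.0, 2.0]) == 0.0
    # boundary values count as defective ("at or below")
    assert defect_fraction([0.5, 1.1, 2.0]) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        defect_fraction([])


@given(st.lists(st.floats(0, 4, allow_nan=False), min_size=1, max_size=30),
       st.floats(0.1, 2.0), st.floats(0.1, 2.0))
def test_defect_fraction_monotone_in_threshold_and_order_invariant(vals, t1, t2):
    lo, hi = sorted([t1, t2])
    assert defect_fraction(vals, lo) <= defect_fraction(vals, hi)
    assert defect_fraction(vals, t1) == defect_fraction(vals[::-1], t1)


# ------------------------------------------------------------ chi-squared

def test_identical_defect_fractions_give_p_one():
    res = swim_defect_test([0.5] * 10 + [2.0] * 10, [0.5] * 10 + [2.0] * 10)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_raw == pytest.approx(1.0)


def test_degenerate_table_flagged_not_raised():
    res = swim_defect_test([2.0] * 10, [2.0] * 10)  # no defectives anywhere
    assert res.p_raw == 1.0 and "degenerate" in res.note


def test_chi_squared_matches_hand_computed_pearson_value():
    # table [[10,30],[2,38]]: chi2 = 80*(10*38-30*2)^2/(40*40*12*68)
    variant = [1.0] * 10 + [2.0] * 30
    wildtype = [1.0] * 2 + [2.0] * 38
    res = swim_defect_test(variant, wildtype)
    assert res.statistic == pytest.approx(6.2745098, abs=1e-6)


def test_chi_squared_symmetric_under_group_swap():
    a = [0.3] * 12 + [2.0] * 28
    b = [0.3] * 4 + [2.0] * 36
    assert (swim_defect_test(a, b).statistic
            == pytest.approx(swim_defect_test(b, a).statistic))
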