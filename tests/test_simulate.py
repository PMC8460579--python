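"""Synthetic generator: determinism, grid structure, planted lag model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from binocsync.pairing import pair_streams
from binocsync.simulate import (
    SimConfig,
    simulate_count_table,
    simulate_reading_session,
)


def make_cfg(**kw):
    base = dict(n_participants=2, n_articles=2, pages_per_article=2, seed=5)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="module")
def unbiased_session():
    """~10^4 fixation pairs with zero planted bias."""
    cfg = make_cfg(
        n_participants=2,
        n_articles=14,
        pages_per_article=5,
        lag_scale_ms=4.0,
        start_bias_slope=0.0,
        end_bias_slope=0.0,
        sweep_advantage_ms=0.0,
        seed=11,
    )
    return simulate_reading_session(cfg)


def test_determinism_same_seed_identical_streams():
    a = simulate_reading_session(make_cfg())
    b = simulate_reading_session(make_cfg())
    pd.testing.assert_frame_equal(a.fixations, b.fixations)
    c = simulate_reading_session(make_cfg(seed=6))
    assert not a.fixations.equals(c.fixations)


def test_times_on_grid_and_streams_ordered(small_session):
    fx = small_session.fixations
    q = small_session.config.quantum_ms
    assert np.all(fx["start_ms"] % q == 0)
    assert np.all(fx["end_ms"] % q == 0)
    assert np.all(fx["start_ms"] >= 0)
    for _, grp in fx.groupby(["participant_id", "article_id", "page_id", "eye"]):
        s = grp["start_ms"].to_numpy()
        e = grp["end_ms"].to_numpy()
        assert np.all(e > s)
        assert np.all(s[1:] >= e[:-1])  # non-overlapping within the eye
        assert np.all(np.diff(s) > 0)


def test_positions_within_screen(small_session):
    fx = small_session.fixations
    scr = small_session.config.screen
    assert fx["x_px"].between(0, scr.width_px).all()
    assert fx["y_px"].between(0, scr.height_px).all()


def test_truth_round_trips_config_values():
    cfg = make_cfg(start_bias_slope=2.5, end_bias_slope=1.25, lag_scale_ms=3.0)
    sess = simulate_reading_session(cfg)
    assert sess.truth.start_bias_slope == 2.5
    assert sess.truth.end_bias_slope == 1.25
    assert sess.truth.lag_scale_ms == 3.0


def test_no_noise_limit_all_offsets_zero():
    cfg = make_cfg(
        lag_scale_ms=1e-6, start_bias_slope=0.0, end_bias_slope=0.0,
        sweep_advantage_ms=0.0,
    )
    sess = simulate_reading_session(cfg)
    pairs, unpaired = pair_streams(sess.fixations)
    assert unpaired == {"L": 0, "R": 0}
    assert np.all(pairs["start_offset_ms"] == 0)
    assert np.all(pairs["end_offset_ms"] == 0)


def test_degenerate_config_rejected():
    # lag scale comparable to fixation durations would consume fixations
    with pytest.raises(ValueError, match="degenerate"):
        make_cfg(lag_scale_ms=60.0)
    with pytest.raises(ValueError):
        make_cfg(lines_per_page=9)
    with pytest.raises(ValueError):
        make_cfg(line_length_px=3000)
    with pytest.raises(ValueError):
        make_cfg(n_participants=0)


def test_zero_bias_offsets_symmetric_about_zero(unbiased_session):
    pairs, _ = pair_streams(unbiased_session.fixations)
    assert len(pairs) >= 5000
    off = pairs["start_offset_ms"].to_numpy()
    nz = off[off != 0]
    # two-sided sign test at alpha = 0.01
    p = stats.binomtest(int((nz > 0).sum()), len(nz), 0.5).pvalue
    assert p > 0.01


def test_offset_median_matches_planted_laplace_scale():
    # fine time quantum so the 2 ms lattice does not mask the scale;
    # median |Laplace(scale)| = scale * ln 2
    cfg = make_cfg(
        n_participants=2,
        n_articles=14,
        pages_per_article=5,
        lag_scale_ms=4.0,
        start_bias_slope=0.0,
        end_bias_slope=0.0,
        sweep_advantage_ms=0.0,
        quantum_ms=0.0625,
        seed=13,
    )
    sess = simulate_reading_session(cfg)
    left, right = sess.left, sess.right
    assert len(left) == len(right)
    off = right["start_ms"].to_numpy(float) - left["start_ms"].to_numpy(float)
    assert len(off) >= 10_000
    med = np.median(np.abs(off))
    assert med == pytest.approx(4.0 * np.log(2), rel=0.10)


def test_start_bias_shifts_sign_probability_with_mc_oracle():
    slope = 6.0
    cfg = make_cfg(
        n_participants=4, n_articles=10, pages_per_article=5,
        lag_scale_ms=4.0, start_bias_slope=slope, end_bias_slope=0.0,
        sweep_advantage_ms=0.0, seed=17,
    )
    sess = simulate_reading_session(cfg)
    pairs, _ = pair_streams(sess.fixations)
    assert len(pairs) >= 10_000
    width = cfg.screen.width_px
    x = pairs["x_px"].to_numpy()
    right_early = pairs["start_offset_ms"].to_numpy() < 0
    p_right_third = right_early[x >= 2 * width / 3].mean()
    p_left_third = right_early[x < width / 3].mean()
    assert p_right_third - p_left_third > 0

    # independent Monte-Carlo of the planted location-shift lag model
    rng = np.random.default_rng(99)
    xnorm_r, xnorm_l = 2 * (5 / 6) - 1, 2 * (1 / 6) - 1
    mc_r = rng.laplace(-slope * xnorm_r, 4.0, 200_000)
    mc_l = rng.laplace(-slope * xnorm_l, 4.0, 200_000)
    mc_gap = (mc_r < 0).mean() - (mc_l < 0).mean()
    assert mc_gap > 0  # oracle confirms the direction
    assert (p_right_third - p_left_third) == pytest.approx(mc_gap, abs=0.1)


# ---------------------------------------------------------------------------
# direct count-table generator


def test_count_table_poisson_mean():
    df, _ = simulate_count_table(
        {}, {}, n_participants=50, n_articles=2, n_pages=4,
        intercept=np.log(4), seed=3,
    )
    n = len(df)
    assert abs(df["count"].mean() - 4) < 3 * np.sqrt(4 / n)


def test_count_table_planted_rate_ratio():
    df, truth = simulate_count_table(
        {"left": 0.46, "right": -0.13}, {}, n_participants=100,
        n_articles=2, n_pages=10, intercept=1.0, seed=4,
    )
    by_region = df.groupby("region")["count"].mean()
    ratio = by_region["left"] / by_region["middle"]
    se = np.sqrt(1 / by_region.sum())  # crude Poisson error on the log ratio
    assert np.log(ratio) == pytest.approx(0.46, abs=5 * max(se, 0.02))
    assert truth.region_effects == {"left": 0.46, "right": -0.13}


def test_count_table_grouping_variance_moment():
    df, _ = simulate_count_table(
        {}, {"participant": 0.2}, n_participants=100, n_articles=1,
        n_pages=100, intercept=np.log(10), seed=8,
    )
    log_means = np.log(df.groupby("participant_id")["count"].mean())
    assert log_means.var(ddof=1) == pytest.approx(0.04, rel=0.35)


def test_count_table_validation():
    with pytest.raises(ValueError):
        simulate_count_table({}, {"participant": -0.1})
    with pytest.raises(ValueError):
        simulate_count_table({"left": np.inf}, {})


def test_session_write_includes_truth_sidecar(tmp_path):
    sess = simulate_reading_session(make_cfg(n_participants=1, n_articles=1))
    sess.write(tmp_path / "fx.csv", tmp_path / "truth.json")
    import json

    side = json.loads((tmp_path / "truth.json").read_text())
    assert side["truth"]["start_bias_slope"] == sess.config.start_bias_slope
    assert side["config"]["seed"] == sess.config.seed
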