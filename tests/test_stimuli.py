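"""Geometry, placement constraints, dichoptic assignments, and schedules."""

import json

import numpy as np
import pytest

from ocusearch import ConfigurationError, TransientProfile
from ocusearch.stimuli import (
    ConditionCell,
    SessionSpec,
    TargetPlacement,
    assign_contrast_heterogeneity_e4,
    assign_disparity,
    assign_identities,
    assign_ocularity,
    choose_singleton_position,
    choose_target_position,
    e1_session_cells,
    experiment_config,
    generate_trial,
    grid_rowcol,
    jitter_positions,
    make_grid,
    place_vergence_anchors,
    rc_to_index,
    schedule_session,
    standard_cells,
)

ALL_EXPERIMENTS = ["E1", "E2", "E3", "E4"]


# ---------------------------------------------------------------------------
# grid geometry


def test_grid_centres_span_extent():
    cfg = experiment_config("E2", rows=3, cols=3, extent_x=2.0, extent_y=2.0)
    grid = make_grid(cfg)
    assert sorted(map(tuple, grid)) == sorted(
        (x, y) for x in (-1.0, 0.0, 1.0) for y in (-1.0, 0.0, 1.0)
    )


def test_e2_grid_corner():
    grid = make_grid(experiment_config("E2"))
    assert tuple(grid[0]) == pytest.approx((-9.2, 9.2))


def test_degenerate_single_row():
    cfg = experiment_config("E2", rows=1, cols=5, extent_x=4.0, extent_y=0.0)
    grid = make_grid(cfg)
    assert np.all(grid[:, 1] == 0.0)
    with pytest.raises(ConfigurationError):
        experiment_config("E2", rows=1, cols=5, extent_x=4.0, extent_y=2.0)


@pytest.mark.parametrize("exp, bound", [("E1", 0.24), ("E2", 0.05), ("E3", 0.064), ("E4", 0.077)])
def test_jitter_within_bound(exp, bound, rng):
    cfg = experiment_config(exp)
    assert cfg.jitter_bound == bound
    grid = make_grid(cfg)
    deltas = []
    while sum(d.size for d in deltas) < 100_000:
        deltas.append(jitter_positions(grid, cfg, rng) - grid)
    deltas = np.concatenate([d.ravel() for d in deltas])
    assert np.max(np.abs(deltas)) <= bound
    assert np.max(np.abs(deltas)) > 0.9 * bound  # the full range is exercised


def test_zero_jitter_identity(rng):
    cfg = experiment_config("E2", jitter_bound=0.0)
    grid = make_grid(cfg)
    assert np.array_equal(jitter_positions(grid, cfg, rng), grid)


# ---------------------------------------------------------------------------
# target and singleton placement


def _placement_samples(exp, n=300):
    cfg = experiment_config(exp)
    rng = np.random.default_rng(7)
    return cfg, [choose_target_position(cfg, rng) for _ in range(n)]


def test_e2_target_on_nearest_ring_cells():
    cfg, samples = _placement_samples("E2")
    r_c, c_c = cfg.centre_rc
    # brute-force oracle: the minimal |distance - 10| over all eligible cells
    gaps = [
        abs(np.hypot(r - r_c, c - c_c) - 10.0)
        for r in range(4, 21)
        for c in range(1, cfg.cols + 1)
        if abs(c - c_c) >= 6
    ]
    best = min(gaps)
    for r, c in samples:
        assert 4 <= r <= 20
        assert abs(c - c_c) >= 6
        assert abs(np.hypot(r - r_c, c - c_c) - 10.0) <= best + 1e-9


def test_e3_target_constraints():
    cfg, samples = _placement_samples("E3")
    r_c, c_c = cfg.centre_rc
    for r, c in samples:
        assert 4 <= r <= 14
        assert abs(c - c_c) >= 5


def test_e4_target_annulus():
    cfg, samples = _placement_samples("E4")
    r_c, c_c = cfg.centre_rc
    for r, c in samples:
        assert 4 <= r <= 11
        assert 2 <= abs(c - c_c) <= 5
        assert 3 <= np.hypot(r - r_c, c - c_c) <= 6


def test_e1_target_eccentricity():
    cfg, samples = _placement_samples("E1")
    grid = make_grid(cfg)
    for r, c in samples:
        x, y = grid[rc_to_index(cfg, r, c)]
        assert abs(x) >= 12.0
        assert 13.5 <= np.hypot(x, y) <= 16.5


def test_infeasible_placement_errors():
    bad = TargetPlacement(mode="ring", row_band=(1, 2), ring_radius=10.0, min_horizontal_units=50.0)
    cfg = experiment_config("E2", target_placement=bad)
    with pytest.raises(ConfigurationError):
        choose_target_position(cfg, np.random.default_rng(0))


def test_singleton_mirror_policy(rng):
    cfg = experiment_config("E2")
    grid = make_grid(cfg)
    for _ in range(100):
        t_rc = choose_target_position(cfg, rng)
        s_rc = choose_singleton_position(t_rc, cfg, rng, policy="mirror")
        xt = grid[rc_to_index(cfg, *t_rc), 0]
        xs = grid[rc_to_index(cfg, *s_rc), 0]
        assert xs == pytest.approx(-xt)  # mirrored: opposite half, same |x|
        assert s_rc[0] == t_rc[0]


def test_singleton_sampling_policy_opposite_half():
    cfg = experiment_config("E2")
    grid = make_grid(cfg)
    rng = np.random.default_rng(3)
    for _ in range(10_000):
        t_rc = choose_target_position(cfg, rng)
        s_rc = choose_singleton_position(t_rc, cfg, rng, policy="sample")
        xt = grid[rc_to_index(cfg, *t_rc), 0]
        xs = grid[rc_to_index(cfg, *s_rc), 0]
        assert np.sign(xs) == -np.sign(xt)


# ---------------------------------------------------------------------------
# identities, ocularity, disparity, anchors


def test_bar_identities_opposite_tilts(rng):
    cfg = experiment_config("E1")
    tilts = assign_identities(cfg.n_items, 5, cfg, rng)
    assert set(np.abs(tilts)) == {10.0}
    assert tilts[5] == -tilts[0]
    assert np.sum(tilts == tilts[5]) == 1


def test_letter_identities_one_t_among_ls(rng):
    cfg = experiment_config("E3")
    glyphs = assign_identities(cfg.n_items, 17, cfg, rng)
    assert glyphs[17] == "T"
    assert np.sum(glyphs == "L") == 288  # 17*17 - 1


def test_e2_bar_tilt_is_45():
    assert experiment_config("E2").bar_tilt == 45.0


@pytest.mark.parametrize("condition, unique_is_target", [("DC", True), ("DI", False)])
def test_sign_flip_unique_sign(condition, unique_is_target, rng):
    n, target, singleton = 50, 7, 31
    O = assign_ocularity(n, target, singleton, condition, 1 / 5, "sign_flip", rng)
    values, counts = np.unique(O, return_counts=True)
    assert np.allclose(np.abs(values), 0.2)
    unique_idx = int(np.nonzero(O == values[np.argmin(counts)])[0][0])
    assert unique_idx == (target if unique_is_target else singleton)
    # DC at |O| = 1/5: target eye weight is 0.6 or 0.4
    if condition == "DC":
        assert (1 + O[target]) / 2 in (pytest.approx(0.6), pytest.approx(0.4))


def test_eye_dominance_nine_to_one(rng):
    # 9:1 dominance ratio corresponds to |O| = 0.8: s_dom = 9 * s_other
    O = assign_ocularity(20, 3, None, "baseline", 0.8, "sign_flip", rng)
    s_L = (1 + O) / 2
    ratios = np.where(s_L > 0.5, s_L / (1 - s_L), (1 - s_L) / s_L)
    assert ratios == pytest.approx(np.full(20, 9.0))


def test_e4_baseline_all_zero(rng):
    O = assign_ocularity(196, 10, None, "baseline", 0.0, "target_only", rng)
    assert np.all(O == 0.0)


def test_monocular_and_binocular_singleton_schemes(rng):
    O = assign_ocularity(30, 2, None, "DC", 1.0, "zero_among_full", rng)
    assert O[2] == 0.0 and set(np.abs(np.delete(O, 2))) == {1.0}
    O = assign_ocularity(30, 2, None, "DC", 1.0, "full_among_zero", rng)
    assert abs(O[2]) == 1.0 and np.all(np.delete(O, 2) == 0.0)


def test_disparity_borders_and_symmetry(rng):
    cfg = experiment_config("E2")
    d = assign_disparity(cfg, rng)
    cols = grid_rowcol(cfg)[:, 1]
    assert np.all(d[(cols == 1) | (cols == cfg.cols)] == 0.0)
    assert np.max(np.abs(d)) <= 0.21
    trial = generate_trial(cfg, ConditionCell("baseline", 1 / 5), seed=4)
    mean_pos = (trial.eye_positions("left") + trial.eye_positions("right")) / 2
    assert np.allclose(mean_pos, trial.positions, atol=1e-9)
    # disparity sign convention: d = x_R - x_L
    d_rec = trial.eye_positions("right")[:, 0] - trial.eye_positions("left")[:, 0]
    assert np.allclose(d_rec, trial.disparity, atol=1e-12)


def test_vergence_anchor_layout(rng):
    cfg = experiment_config("E2", rows=3, cols=3, extent_x=2.0, extent_y=2.0)
    anchors = place_vergence_anchors(np.asarray(make_grid(cfg)), cfg)
    assert anchors["dots"].shape == (4, 2)  # (rows-1) * (cols-1)
    e2 = experiment_config("E2")
    trial = generate_trial(e2, ConditionCell("baseline", 1 / 5), seed=1)
    fx, fy = trial.anchors["frame_extent_deg"]
    assert fx == pytest.approx(1.1 * 18.4)
    e1 = experiment_config("E1")
    trial = generate_trial(e1, ConditionCell("baseline", 1.0), seed=1)
    assert trial.anchors["corner_disks"].shape == (4, 2)
    assert trial.anchors["dots"].shape == ((22 - 1) * (30 - 1), 2)


# ---------------------------------------------------------------------------
# E4 contrast heterogeneity


def test_e4_target_contrast_strictly_between(rng):
    for _ in range(200):
        _, c = assign_contrast_heterogeneity_e4(196, 40, rng)
        others = np.delete(c, 40)
        assert others.min() < c[40] < others.max()


def test_e4_expected_contrast_equality():
    rng = np.random.default_rng(21)
    t_sums, nt_sums = [], []
    for _ in range(4000):
        _, c = assign_contrast_heterogeneity_e4(196, 0, rng)
        t_sums.append(c[0])
        nt_sums.append(np.delete(c, 0).mean())
    # both formulas have expectation 1 (in units of the increment scale)
    assert np.mean(t_sums) == pytest.approx(np.mean(nt_sums), abs=0.01)
    assert np.mean(t_sums) == pytest.approx(1.0, abs=0.01)


def test_e4_trial_has_195_jittered_nontargets():
    cfg = experiment_config("E4")
    trial = generate_trial(cfg, ConditionCell("DC", 3 / 5, scheme="target_only"), seed=9)
    nt = np.delete(trial.lum_jitter, trial.target_index)
    assert nt.size == 195
    assert np.unique(nt).size == 195  # independent draws


# ---------------------------------------------------------------------------
# schedules and whole-trial invariants


@pytest.mark.parametrize("exp, n_cells, expected", [("E2", 9, 450), ("E3", 8, 400)])
def test_session_sizes(exp, n_cells, expected):
    cells = standard_cells(exp)
    assert len(cells) == n_cells
    session = SessionSpec(experiment_config(exp), cells, 50, rng_seed=5)
    assert session.n_trials == expected
    assert len(schedule_session(session)) == expected


def test_schedule_deterministic():
    session = SessionSpec(experiment_config("E2"), standard_cells("E2"), 3, rng_seed=8)
    a = schedule_session(session)
    b = schedule_session(session)
    for ta, tb in zip(a, b):
        assert ta.condition == tb.condition
        assert np.array_equal(ta.positions, tb.positions)
        assert np.array_equal(ta.O, tb.O)
        assert np.array_equal(ta.disparity, tb.disparity)
        assert ta.target_index == tb.target_index


def test_e4_condition_grid():
    cells = standard_cells("E4")
    assert len(cells) == 10
    assert sum(c.condition == "baseline" for c in cells) == 1
    labels = {(round(c.O_mag, 3), c.transient.label) for c in cells if c.condition == "DC"}
    assert labels == {
        (round(m, 3), lab)
        for m in (1 / 5, 1 / 3, 3 / 5)
        for lab in ("static", "smooth_0.1", "smooth_0.5")
    }


def _unique_sign_index(O):
    signs = np.sign(O)
    pos = np.nonzero(signs > 0)[0]
    neg = np.nonzero(signs < 0)[0]
    if len(pos) == 1 and len(neg) > 1:
        return int(pos[0])
    if len(neg) == 1 and len(pos) > 1:
        return int(neg[0])
    return None


@pytest.mark.parametrize("exp", ["E1", "E2", "E3"])
def test_constant_contrast_sum_and_unique_sign(exp):
    cfg = experiment_config(exp)
    cells = standard_cells(exp)
    count = 0
    for seed in range(0, 1000, len(cells)):
        for k, cell in enumerate(cells):
            trial = generate_trial(cfg, cell, seed=seed + k)
            count += 1
            assert np.unique(trial.C_sum).size == 1  # C_sum constant within trial
            if cell.condition == "baseline":
                assert trial.singleton_index is None
                assert np.unique(trial.O).size == 1
            else:
                unique = _unique_sign_index(trial.O)
                assert unique is not None
                expected = (
                    trial.target_index if cell.condition == "DC" else trial.singleton_index
                )
                assert unique == expected
    assert count >= 1000 // len(cells) * len(cells)


def test_single_strength_monocular_singleton():
    cfg = experiment_config("E1")
    cell = e1_session_cells("monocular_among_binocular_single")[1]
    assert cell.condition == "DC"
    trial = generate_trial(cfg, cell, seed=6)
    t = trial.target_index
    # the monocular bar's single-eye luminance matches the binocular bars' per-eye level
    assert max(trial.lum_L[t], trial.lum_R[t]) == pytest.approx(24.0)
    assert min(trial.lum_L[t], trial.lum_R[t]) == 0.0
    other = (t + 1) % trial.n_items
    assert trial.lum_L[other] == pytest.approx(24.0)


def test_double_strength_monocular_singleton():
    cfg = experiment_config("E1")
    cell = e1_session_cells("monocular_among_binocular")[1]
    trial = generate_trial(cfg, cell, seed=6)
    t = trial.target_index
    assert max(trial.lum_L[t], trial.lum_R[t]) == pytest.approx(48.0)
    assert trial.lum_L[t] + trial.lum_R[t] == pytest.approx(
        trial.lum_L[(t + 1) % trial.n_items] + trial.lum_R[(t + 1) % trial.n_items]
    )


def test_transient_monocular_item_becomes_binocular():
    cfg = experiment_config("E1")
    cell = e1_session_cells("monocular_among_binocular_transient")[1]
    assert cell.transient == TransientProfile("abrupt", dT=0.15)
    trial = generate_trial(cfg, cell, seed=2)
    t = trial.target_index
    lum_L, lum_R = trial.eye_luminances(t=0.2)
    assert lum_L[t] == pytest.approx(lum_R[t]) == pytest.approx(24.0)
    # binocular input sum unchanged through the transition
    assert lum_L[t] + lum_R[t] == pytest.approx(trial.lum_L[t] + trial.lum_R[t])


def test_scene_dict_serializable():
    cfg = experiment_config("E4")
    trial = generate_trial(cfg, ConditionCell("DC", 1 / 3, scheme="target_only"), seed=3)
    blob = json.dumps(trial.scene_dict())
    assert "disparity_sign" in blob


def test_unknown_experiment_lists_valid_ids():
    with pytest.raises(ConfigurationError, match="E1, E2, E3, E4"):
        experiment_config("E9")
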