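"""Synthetic-session generator: trajectories, templates, events, digs."""

import numpy as np
import pytest

from reorient.arena import ArenaSpec
from reorient.synth import (
    CellTemplate,
    SessionConfig,
    TrajectoryParams,
    generate_cell_population,
    generate_dig_outcomes,
    generate_session,
    generate_trajectory,
    generate_trial_events,
    read_session,
    write_session,
)


ARENA = ArenaSpec()


class TestArena:
    def test_square_rejected(self):
        with pytest.raises(ValueError):
            ArenaSpec(width_cm=20.0, height_cm=20.0)

    def test_corner_labels_bijective(self):
        for ctx in ("A", "B"):
            labels = ARENA.corner_labels(ctx)
            assert set(labels) == {"C", "G", "N", "F"}
            assert len({tuple(v) for v in labels.values()}) == 4
            assert all(tuple(v) in ARENA.corners() for v in labels.values())

    def test_g_is_180_image_of_c(self):
        labels = ARENA.corner_labels("A")
        assert labels["G"] == ARENA.rotate180(labels["C"])


class TestTrajectory:
    def test_zero_variance_is_stationary(self):
        traj = generate_trajectory(
            ARENA, 5.0, TrajectoryParams(speed_sd_cm_s=0.0), seed=0
        )
        assert np.allclose(np.diff(traj["x"]), 0.0)
        assert np.allclose(np.diff(traj["y"]), 0.0)

    def test_determinism(self):
        t1 = generate_trajectory(ARENA, 10.0, seed=42)
        t2 = generate_trajectory(ARENA, 10.0, seed=42)
        assert t1.equals(t2)

    def test_stays_in_arena(self):
        traj = generate_trajectory(ARENA, 30.0, seed=3)
        assert ARENA.contains(traj["x"].to_numpy(), traj["y"].to_numpy())

    def test_coverage_at_120s(self):
        """Brute-force occupancy count: >= 80% of the 600 bins visited."""
        traj = generate_trajectory(ARENA, 120.0, seed=5)
        visited = set()
        for x, y in zip(traj["x"], traj["y"]):  # brute-force bin count
            visited.add((int(min(x, 29.999)), int(min(y, 19.999))))
        assert len(visited) >= 0.8 * 600

    def test_speed_distribution_straddles_filter(self):
        traj = generate_trajectory(ARENA, 60.0, seed=6)
        speed = np.hypot(np.diff(traj["x"]), np.diff(traj["y"])) / np.diff(traj["t"])
        assert 0.0 < np.mean(speed < 2.0) < 0.5

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_trajectory(ARENA, 0.0, seed=0)


class TestCellPopulation:
    @pytest.mark.parametrize(
        "frac, n, expected", [(0.0, 50, 0), (1.0, 50, 50), (0.15, 200, 30)]
    )
    def test_fs_count_rounding(self, frac, n, expected):
        gt = generate_cell_population(
            SessionConfig(n_cells=n, fs_fraction=frac), seed=0
        )
        assert sum(1 for l in gt.labels if l == "FS") == expected

    def test_fi_templates_shared_across_contexts(self):
        gt = generate_cell_population(SessionConfig(n_cells=40), seed=1)
        fi = [i for i, l in enumerate(gt.labels) if l == "FI"]
        fs = [i for i, l in enumerate(gt.labels) if l == "FS"]
        assert np.array_equal(gt.centers_a[fi], gt.centers_b[fi])
        # FS templates relocated away from both the A field and its image
        for i in fs:
            a = gt.centers_a[i]
            a_rot = np.array(ARENA.rotate180(tuple(a)))
            d = min(
                np.linalg.norm(gt.centers_b[i] - a),
                np.linalg.norm(gt.centers_b[i] - a_rot),
            )
            assert d >= 8.0

    def test_centers_inside_arena(self):
        gt = generate_cell_population(SessionConfig(n_cells=100), seed=2)
        for centers in (gt.centers_a, gt.centers_b):
            assert np.all(centers[:, 0] >= 0) and np.all(centers[:, 0] <= 30)
            assert np.all(centers[:, 1] >= 0) and np.all(centers[:, 1] <= 20)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(fs_fraction=1.5)


class TestTrialEvents:
    TEMPLATE = CellTemplate(center=(8.0, 6.0), sigma_cm=4.0, peak_hz=15.0)

    def test_zero_gain_empty(self):
        traj = generate_trajectory(ARENA, 20.0, seed=0)
        ev = generate_trial_events(self.TEMPLATE, traj, 0, 0.0, ARENA, seed=1)
        assert len(ev) == 0

    def test_negative_gain_rejected(self):
        traj = generate_trajectory(ARENA, 5.0, seed=0)
        with pytest.raises(ValueError):
            generate_trial_events(self.TEMPLATE, traj, 0, -1.0, ARENA, seed=1)

    def test_events_within_trajectory_span(self):
        traj = generate_trajectory(ARENA, 30.0, seed=2)
        ev = generate_trial_events(self.TEMPLATE, traj, 0, 1.0, ARENA, seed=3)
        assert ev["t"].between(traj["t"].min(), traj["t"].max()).all()

    def test_rotated_template_moves_event_centroid(self):
        traj = generate_trajectory(ARENA, 120.0, seed=4)
        x = traj["x"].to_numpy()
        ev = generate_trial_events(self.TEMPLATE, traj, 1, 1.5, ARENA, seed=5)
        idx = np.searchsorted(traj["t"].to_numpy(), ev["t"].to_numpy()) - 1
        centroid = np.array([x[idx].mean(), traj["y"].to_numpy()[idx].mean()])
        rotated_center = np.array(ARENA.rotate180(self.TEMPLATE.center))
        original_center = np.array(self.TEMPLATE.center)
        assert np.linalg.norm(centroid - rotated_center) < np.linalg.norm(
            centroid - original_center
        )

    def test_doubling_gain_doubles_event_count(self):
        """Monte-Carlo mean over 100 repetitions within Poisson error."""
        traj = generate_trajectory(ARENA, 30.0, seed=6)
        rng = np.random.default_rng(7)
        n1 = [
            len(generate_trial_events(self.TEMPLATE, traj, 0, 1.0, ARENA, rng))
            for _ in range(100)
        ]
        n2 = [
            len(generate_trial_events(self.TEMPLATE, traj, 0, 2.0, ARENA, rng))
            for _ in range(100)
        ]
        se = np.sqrt(np.mean(n2) / 100 + 4 * np.mean(n1) / 100)
        assert abs(np.mean(n2) - 2 * np.mean(n1)) < 3 * se

    def test_rate_calibration_against_template_integral(self):
        """Empirical mean event count within 3 MC standard errors of the
        integral of the rate along the path (50 repetitions)."""
        traj = generate_trajectory(ARENA, 60.0, seed=8)
        dt = float(np.median(np.diff(traj["t"])))
        lam = self.TEMPLATE.rate_at(
            traj["x"].to_numpy(), traj["y"].to_numpy(), ARENA, 0
        )
        expected = lam.sum() * dt
        rng = np.random.default_rng(9)
        counts = [
            len(generate_trial_events(self.TEMPLATE, traj, 0, 1.0, ARENA, rng))
            for _ in range(50)
        ]
        se = np.sqrt(expected / 50)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_gamma_weights_positive(self):
        traj = generate_trajectory(ARENA, 30.0, seed=10)
        ev = generate_trial_events(
            self.TEMPLATE, traj, 0, 1.0, ARENA, seed=11, weight_mode="gamma"
        )
        assert (ev["weight"] > 0).all()
        assert not np.allclose(ev["weight"], 1.0)


class TestDigOutcomes:
    def test_degenerate_probs_all_correct(self):
        digs = generate_dig_outcomes(
            (1.0, 0.0, 0.0, 0.0), np.zeros(50, int), rho=0.0, seed=0
        )
        assert digs == ["C"] * 50

    def test_full_coupling_follows_orientation(self):
        orient = np.random.default_rng(1).integers(0, 2, 200)
        digs = generate_dig_outcomes((0.5, 0.5, 0.0, 0.0), orient, rho=1.0, seed=2)
        for o, d in zip(orient, digs):
            assert d == ("C" if o == 0 else "G")

    def test_match_rate_at_half_coupling(self):
        """With rho = 0.5 the match probability is (1 + rho)/2 = 0.75."""
        rng = np.random.default_rng(3)
        orient = rng.integers(0, 2, 10_000)
        digs = generate_dig_outcomes((0.5, 0.5, 0.0, 0.0), orient, rho=0.5, seed=rng)
        match = np.mean(
            [d == ("C" if o == 0 else "G") for o, d in zip(orient, digs)]
        )
        assert match == pytest.approx(0.75, abs=0.02)

    def test_no_coupling_matches_at_chance(self):
        rng = np.random.default_rng(4)
        orient = rng.integers(0, 2, 10_000)
        digs = generate_dig_outcomes((0.5, 0.5, 0.0, 0.0), orient, rho=0.0, seed=5)
        match = np.mean(
            [d == ("C" if o == 0 else "G") for o, d in zip(orient, digs)]
        )
        assert match == pytest.approx(0.5, abs=0.02)

    def test_bad_probs_rejected(self):
        with pytest.raises(ValueError):
            generate_dig_outcomes((0.5, 0.5, 0.5, 0.0), [0], rho=0.5, seed=0)


class TestSession:
    def test_trials_alternate_contexts(self):
        cfg = SessionConfig(
            n_days=1, trials_per_day=12, n_cells=2, trial_duration_s=10.0, seed=0
        )
        s = generate_session(cfg)
        ctx = [t.context for t in s.trials]
        assert ctx == ["A", "B"] * 6
        assert ctx.count("A") == 6 and ctx.count("B") == 6

    def test_odd_trials_per_day_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(trials_per_day=11)

    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = SessionConfig(
            n_days=1, trials_per_day=4, n_cells=3, trial_duration_s=10.0, seed=9
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_session(generate_session(cfg), d1)
        write_session(generate_session(cfg), d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_roundtrip(self, tmp_path):
        cfg = SessionConfig(
            n_days=1, trials_per_day=4, n_cells=3, trial_duration_s=10.0, seed=10
        )
        s = generate_session(cfg)
        write_session(s, tmp_path / "sess")
        s2 = read_session(tmp_path / "sess")
        assert s2.trials_frame().equals(s.trials_frame())
        assert s2.ground_truth.labels == s.ground_truth.labels
        assert np.allclose(s2.trials[1].trajectory["x"], s.trials[1].trajectory["x"])

    def test_ground_truth_structure_recovered(self, default_analysis):
        """FI cells correlate across contexts, FS cells do not, on
        full-scale generated data."""
        sa = default_analysis
        prof = sa.alignment.profiles
        gt = sa.session.ground_truth.labels
        sim_fi = prof[[gt[int(c)] == "FI" for c in prof["cell_id"]]][
            "context_similarity"
        ]
        sim_fs = prof[[gt[int(c)] == "FS" for c in prof["cell_id"]]][
            "context_similarity"
        ]
        assert sim_fi.mean() > 0.5
        assert (sim_fs < 0.3).mean() >= 0.9
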