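"""Step decomposition, movement-parameter fitting and path statistics."""

import numpy as np
import pandas as pd
import pytest

import wolftracks as wt
from wolftracks.params import DECEMBER
from wolftracks.telemetry import (
    StepSeries,
    paired_path_comparison,
    path_characteristics,
    stats_to_frame,
)


def series_from_xy(x, y, wolf_id="w", months=None):
    ts = 2.0 * np.arange(len(x))
    return wt.GPSFixSeries(wolf_id=wolf_id, timestamps=ts, x=x, y=y, months=months)


def make_steps(lengths, moving=None, month="December", angles=None):
    lengths = np.asarray(lengths, dtype=float)
    return StepSeries(
        pd.DataFrame(
            {
                "wolf_id": "w",
                "length": lengths,
                "turning_angle": angles if angles is not None else 0.0,
                "moving": moving if moving is not None else lengths > 150,
                "month": month,
            }
        )
    )


class TestComputeSteps:
    def test_single_step_length_is_euclidean(self):
        s = wt.compute_steps(series_from_xy([0, 3000], [0, 4000]))
        assert len(s) == 1
        assert s.lengths[0] == pytest.approx(5000.0)
        assert np.isnan(s.steps["turning_angle"].iloc[0])

    def test_collinear_fixes_turn_zero(self):
        s = wt.compute_steps(series_from_xy([0, 1000, 2000], [0, 0, 0]))
        assert s.steps["turning_angle"].iloc[1] == pytest.approx(0.0)

    def test_left_turn_is_positive_ninety(self):
        s = wt.compute_steps(series_from_xy([0, 1000, 1000], [0, 0, 1000]))
        assert s.steps["turning_angle"].iloc[1] == pytest.approx(90.0)

    def test_right_turn_is_negative(self):
        s = wt.compute_steps(series_from_xy([0, 1000, 1000], [0, 0, -1000]))
        assert s.steps["turning_angle"].iloc[1] == pytest.approx(-90.0)

    def test_too_few_fixes_give_empty_series(self):
        assert len(wt.compute_steps(series_from_xy([0], [0]))) == 0

    def test_state_threshold_is_strict(self):
        s = wt.compute_steps(series_from_xy([0, 150, 301], [0, 0, 0]))
        assert list(s.steps["moving"]) == [False, True]

    def test_gap_steps_excluded_and_break_turn_chain(self):
        ts = np.array([0.0, 2.0, 7.0, 9.0, 11.0])  # 5-h gap in the middle
        fixes = wt.GPSFixSeries(
            wolf_id="w", timestamps=ts,
            x=np.array([0.0, 1000.0, 5000.0, 6000.0, 7000.0]),
            y=np.zeros(5),
        )
        s = wt.compute_steps(fixes)
        assert len(s) == 3  # gap step dropped
        # first retained step after the gap has no defined turning angle
        assert np.isnan(s.steps["turning_angle"].iloc[1])
        assert s.steps["turning_angle"].iloc[2] == pytest.approx(0.0)

    def test_roundtrip_recovers_simulated_step_lengths_exactly(self, rng):
        path = wt.simulate_path(None, DECEMBER, None, 24, rng)
        fixes = series_from_xy(path.vertices[:, 0], path.vertices[:, 1])
        s = wt.compute_steps(fixes)
        np.testing.assert_allclose(s.lengths, path.step_lengths)
        np.testing.assert_array_equal(s.moving, path.moving)


class TestFitMovementParams:
    def test_degenerate_identical_steps(self):
        s = make_steps([2000.0] * 40)
        p = wt.fit_movement_params(s, "December")
        assert p.step_mean == pytest.approx(2000.0)
        assert p.step_sd == pytest.approx(0.0)
        assert p.p_move == pytest.approx(1.0)

    def test_p_move_is_moving_fraction(self):
        s = make_steps([500.0] * 40 + [100.0] * 60)
        p = wt.fit_movement_params(s, "December")
        assert p.p_move == pytest.approx(0.40)

    def test_refuses_too_few_moving_steps(self):
        s = make_steps([500.0] * 10)
        with pytest.raises(ValueError, match="moving steps"):
            wt.fit_movement_params(s, "December")

    def test_recovers_generating_december_parameters(self):
        series = wt.generate_synthetic_telemetry(DECEMBER, n_wolves=2, n_days=90, seed=42)
        steps = wt.concat_steps([wt.compute_steps(s) for s in series])
        fitted = wt.fit_movement_params(steps, "December")
        assert fitted.step_mean == pytest.approx(3013.0, rel=0.10)
        assert fitted.step_sd == pytest.approx(2657.0, rel=0.15)
        assert fitted.turn_sd == pytest.approx(103.85, rel=0.10)
        # binomial 3-sigma band around the generating moving probability
        n = len(steps)
        assert abs(fitted.p_move - 0.57) < 3 * np.sqrt(0.57 * 0.43 / n)


class TestMonthlyComparison:
    def test_identical_samples_not_significant(self):
        x = np.linspace(200, 4000, 50)
        out = wt.compare_monthly_steps({"December": x, "February": x.copy()})
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_means_detected(self, rng):
        a = rng.normal(3000, 500, 200)
        b = rng.normal(1500, 500, 200)
        out = wt.compare_monthly_steps({"December": a, "February": b})
        assert out["p"].iloc[0] < 0.05
        assert out["t"].iloc[0] > 0

    def test_swapping_months_negates_t(self, rng):
        a = rng.normal(3000, 500, 80)
        b = rng.normal(2000, 500, 80)
        t_ab = wt.compare_monthly_steps({"A": a, "B": b})
        t_ba = wt.compare_monthly_steps({"B": b, "A": a})
        assert t_ab["t"].iloc[0] == pytest.approx(-t_ba["t"].iloc[0])
        assert t_ab["p"].iloc[0] == pytest.approx(t_ba["p"].iloc[0])

    def test_single_month_yields_empty_table(self):
        out = wt.compare_monthly_steps({"December": np.ones(10) * 500})
        assert out.empty


class TestMcpAndCorrelation:
    def test_square_area(self):
        s = series_from_xy([0, 10_000, 10_000, 0], [0, 0, 10_000, 10_000])
        assert wt.compute_mcp_area(s) == pytest.approx(100.0)

    def test_interior_point_does_not_change_hull(self):
        s = series_from_xy([0, 10_000, 10_000, 0, 5000], [0, 0, 10_000, 10_000, 5000])
        assert wt.compute_mcp_area(s) == pytest.approx(100.0)

    def test_disc_sample_bounded_by_disc_area(self, rng):
        r = rng.uniform(0, 10_000, 100)
        th = rng.uniform(0, 2 * np.pi, 100)
        s = series_from_xy(r * np.cos(th), r * np.sin(th))
        assert wt.compute_mcp_area(s) <= np.pi * 100.0

    def test_collinear_fixes_warn_and_return_zero(self):
        s = series_from_xy([0, 1000, 2000], [0, 0, 0])
        with pytest.warns(UserWarning, match="collinear"):
            assert wt.compute_mcp_area(s) == 0.0

    def test_perfect_monotone_pairs(self):
        rho, _ = wt.movement_territory_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_reversal_negates_rho(self):
        rho, _ = wt.movement_territory_correlation([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_null_pairs_rarely_significant(self):
        hits = 0
        for s in range(40):
            r = np.random.default_rng(s)
            rho, p = wt.movement_territory_correlation(
                r.normal(size=11), r.normal(size=11)
            )
            hits += p <= 0.05
        assert hits <= 4  # ~5% nominal rate over 40 null replicates


class TestPathCharacteristics:
    def test_contained_path_touches_one_cell_of_every_grid(self, grids_all):
        verts = np.array([[7000.0, 7000.0], [7400.0, 7300.0], [7100.0, 7600.0]])
        path = wt.Path(owner="p", vertices=verts, moving=np.ones(2, bool))
        st = path_characteristics(path, grids_all)
        assert all(n == 1 for n in st.cells_intersected.values())

    def test_straight_path_along_grid_row(self, extent):
        grid = wt.build_grid(extent, 36.0)
        verts = np.array([[2000.0, 3000.0], [32_000.0, 3000.0]])  # 30 km run
        path = wt.Path(owner="p", vertices=verts, moving=np.ones(1, bool))
        st = path_characteristics(path, [grid])
        assert st.cells_intersected[36.0] in (5, 6)
        assert st.total_length_km == pytest.approx(30.0)

    def test_constructed_crossing_counts(self):
        road = wt.LineFeatureSet(
            features=[("road", np.array([[0.0, 5000.0], [50_000.0, 5000.0]]))]
        )
        verts = np.array([[10_000.0, 0.0], [10_000.0, 8000.0], [12_000.0, 0.0]])
        path = wt.Path(owner="p", vertices=verts, moving=np.ones(2, bool))
        st = path_characteristics(path, [], road)
        assert st.road_pipeline_crossings == 2
        assert st.river_crossings == 0

    def test_empty_feature_set_zero_crossings(self):
        verts = np.array([[0.0, 0.0], [1000.0, 1000.0]])
        path = wt.Path(owner="p", vertices=verts, moving=np.ones(1, bool))
        st = path_characteristics(path, [], wt.LineFeatureSet())
        assert st.river_crossings == 0 and st.road_pipeline_crossings == 0

    def test_length_bounded_below_by_displacement(self, rng):
        path = wt.simulate_path(None, DECEMBER, None, 24, rng)
        disp = np.hypot(*(path.vertices[-1] - path.vertices[0])) / 1000.0
        assert path.total_length_km >= disp


class TestPairedComparison:
    def _stats(self, lengths, cells, crossings):
        return [
            wt.PathStats(
                path_id=f"p{i}",
                total_length_km=ln,
                cells_intersected={36.0: c},
                river_crossings=x,
                road_pipeline_crossings=x,
            )
            for i, (ln, c, x) in enumerate(zip(lengths, cells, crossings))
        ]

    def test_identical_lists_are_all_nonsignificant(self):
        a = self._stats([10, 12, 14], [2, 3, 4], [1, 0, 2])
        out = paired_path_comparison(a, a)
        assert (out["p"] == 1.0).all()
        assert (out["t"] == 0.0).all()

    def test_large_shift_detected(self, rng):
        base = rng.uniform(10, 20, 22)
        a = self._stats(base, rng.integers(1, 5, 22), rng.integers(0, 3, 22))
        b = self._stats(base + 50.0, rng.integers(1, 5, 22), rng.integers(0, 3, 22))
        out = paired_path_comparison(a, b)
        row = out[out["characteristic"] == "path_length_km"].iloc[0]
        assert row["p"] < 0.01

    def test_length_mismatch_rejected(self):
        a = self._stats([10.0], [1], [0])
        with pytest.raises(ValueError, match="matched"):
            paired_path_comparison(a, a + a)

    def test_stats_frame_mirrors_table_layout(self, grids_all):
        """Output columns follow the observed-vs-simulated table layout:
        length, per-grid cells intersected, crossing counts."""
        path = wt.simulate_path(None, DECEMBER, None, 24, np.random.default_rng(0))
        st = path_characteristics(path, grids_all, wt.LineFeatureSet())
        cols = list(stats_to_frame([st]).columns)
        assert cols == [
            "path_id", "path_length_km", "river_crossings",
            "road_pipeline_crossings", "cells_36km2", "cells_144km2",
            "cells_400km2", "cells_576km2",
        ]


class TestValidationHarness:
    def test_per_characteristic_significance_rate_is_nominal(self, extent):
        """Identical generating parameters: each paired t-test rejects at
        roughly its nominal 5% level across harness repetitions."""
        grids = [wt.build_grid(extent, a) for a in (36.0, 576.0)]
        features = wt.generate_line_features(extent, {"road": 4, "river": 3}, seed=7)
        sig = []
        for i in range(15):
            tab = wt.path_validation_harness(
                wt.DECEMBER, grids, features,
                rng=wt.substream(55, "harness", i), n_paths=22,
            )
            sig.append((tab["p"] <= 0.05).to_numpy())
        rate = np.mean(sig)
        assert rate < 0.25  # far from systematic rejection; nominal is 0.05
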