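"""Field partition, interval scheme, possession matrices, Rényi entropy,
and the ΔH feature construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_event
from edran.core import (
    DEFAULT_ALPHAS,
    FieldPartition,
    accumulate_possession,
    build_interval_scheme,
    compute_edran_series,
    delta_features,
    normalize_distribution,
    region_of,
    renyi_entropy,
    shannon_entropy,
)
from edran.event_data import MatchRecord


class TestPartition:
    def test_corner_maps_to_first_region(self):
        assert region_of(0.0, 0.0) == (0, 0, 0)

    def test_upper_boundary_closed(self):
        assert region_of(120.0, 80.0) == (4, 5, 29)

    def test_dense_grid_covers_exactly_30_regions(self, partition):
        xs, ys = np.meshgrid(np.linspace(0, 120, 121), np.linspace(0, 80, 81))
        flat = partition.flat_region_of_array(xs.ravel(), ys.ravel())
        assert set(flat.tolist()) == set(range(30))

    @pytest.mark.parametrize("rows,cols", [(5, 6), (8, 12), (5, 3)])
    def test_equal_area_tiling(self, rows, cols):
        part = FieldPartition(n_rows=rows, n_cols=cols)
        assert part.n_regions == rows * cols
        assert part.cell_area * part.n_regions == pytest.approx(120 * 80, rel=1e-15)

    def test_out_of_range_rejected(self, partition):
        with pytest.raises(ValueError):
            partition.region_of(120.5, 10.0)

    def test_flat_index_row_major(self, partition):
        # x picks the column, y the row: x=25 -> col 1, y=17 -> row 1 -> flat 7
        assert partition.region_of(25.0, 17.0) == (1, 1, 7)


class TestIntervalScheme:
    def test_unequal_halves(self):
        rec = MatchRecord("m", [], 1, {1: 2820.0, 2: 2940.0})
        scheme = build_interval_scheme(rec)
        dts = scheme.dt_s
        assert np.allclose(dts[:5], 564.0) and np.allclose(dts[5:], 588.0)
        assert [iv.period for iv in scheme] == [1] * 5 + [2] * 5

    def test_equal_halves(self):
        rec = MatchRecord("m", [], 1, {1: 2700.0, 2: 2700.0})
        assert np.allclose(build_interval_scheme(rec).dt_s, 540.0)

    def test_intervals_contiguously_cover_each_half(self):
        rec = MatchRecord("m", [], 1, {1: 2820.0, 2: 2940.0})
        scheme = build_interval_scheme(rec)
        for period, end in ((1, 2820.0), (2, 2940.0)):
            ivs = [iv for iv in scheme if iv.period == period]
            assert ivs[0].start_s == 0.0 and ivs[-1].end_s == pytest.approx(end)
            for prev, nxt in zip(ivs, ivs[1:]):
                assert prev.end_s == pytest.approx(nxt.start_s)

    def test_period_end_event_lands_in_last_interval_of_half(self, scheme):
        idx = scheme.interval_index_of(np.array([2700.0, 2700.0]), np.array([1, 2]))
        assert idx.tolist() == [4, 9]

    def test_missing_period_is_an_error(self):
        rec = MatchRecord("m", [make_event(period=1)], 1)
        with pytest.raises(ValueError, match="period 2"):
            build_interval_scheme(rec)


class TestPossession:
    def test_durations_accumulate_by_region(self, partition):
        events = [
            make_event(time_s=1.0, duration_s=3.0, x=5.0, y=5.0),
            make_event(time_s=2.0, duration_s=1.0, x=15.0, y=10.0),  # same region (0,0)
            make_event(time_s=3.0, duration_s=4.0, x=25.0, y=5.0),  # region (0,1)
        ]
        rec = MatchRecord("m", events, 1, {1: 2700.0, 2: 2700.0})
        mats = accumulate_possession(rec, build_interval_scheme(rec), partition)
        m = mats[("A", 1)]
        assert m[0, 0] == 4.0 and m[0, 1] == 4.0 and m.sum() == 8.0

    def test_empty_interval_is_all_zero(self, toy_match, partition, scheme):
        mats = accumulate_possession(toy_match, scheme, partition)
        assert mats[("B", 7)].sum() == 0.0

    def test_conservation_on_simulated_matches(self, small_sim, partition):
        _, records, _ = small_sim
        for rec in records[:10]:
            mats = accumulate_possession(rec, build_interval_scheme(rec), partition)
            total = sum(m.sum() for m in mats.values())
            assert total == pytest.approx(rec.total_duration_s(), rel=1e-12)

    def test_normalize(self):
        m = np.zeros((5, 6))
        m[0, 0] = 4.0
        m[0, 1] = 4.0
        dist = normalize_distribution(m)
        assert not dist.empty_flag
        assert dist.p[0] == 0.5 and dist.p[1] == 0.5 and dist.p.sum() == pytest.approx(1, abs=1e-12)

    def test_normalize_empty(self):
        dist = normalize_distribution(np.zeros((5, 6)))
        assert dist.empty_flag and not dist.p.any()


def random_dists(n, rng, n_regions=30, allow_zeros=True):
    """Random probability vectors, a fraction with masked-out support."""
    out = []
    for _ in range(n):
        p = rng.dirichlet(np.full(n_regions, rng.uniform(0.2, 4.0)))
        if allow_zeros and rng.random() < 0.5:
            k = rng.integers(1, n_regions - 1)
            p[rng.choice(n_regions, size=k, replace=False)] = 0.0
            p = p / p.sum()
        out.append(p)
    return out


class TestRenyiEntropy:
    def test_uniform_gives_log_n_for_every_alpha(self):
        p = np.full(30, 1 / 30)
        for a in DEFAULT_ALPHAS:
            assert renyi_entropy(p, a) == pytest.approx(math.log(30), abs=1e-12)

    def test_max_entropy_counts_support(self):
        assert renyi_entropy([0.5, 0.5], 0.0) == pytest.approx(math.log(2))
        assert renyi_entropy([0.5, 0.5, 0.0], 0.0) == pytest.approx(math.log(2))

    def test_collision_and_shannon_hand_values(self):
        p = [0.75, 0.25]
        assert renyi_entropy(p, 2.0) == pytest.approx(-math.log(0.625), abs=1e-12)
        expected_shannon = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert renyi_entropy(p, 1.0) == pytest.approx(expected_shannon, abs=1e-12)
        assert renyi_entropy(p, 1.0) == pytest.approx(0.5623, abs=5e-5)

    def test_log_base_2(self):
        assert renyi_entropy([0.5, 0.5], 0.0, log_base="2") == pytest.approx(1.0)

    def test_degenerate_distribution_is_zero(self):
        p = np.zeros(30)
        p[3] = 1.0
        for a in DEFAULT_ALPHAS:
            assert renyi_entropy(p, a) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            renyi_entropy([0.5, 0.5], -0.5)
        with pytest.raises(ValueError):
            renyi_entropy([0.5, 0.4], 2.0)  # not normalized
        with pytest.raises(ValueError):
            renyi_entropy([1.2, -0.2], 2.0)

    def test_matches_direct_formula_on_random_dists(self, rng):
        # independent oracle: literal formula evaluation at alpha not in
        # any special-cased branch
        for p in random_dists(50, rng):
            for a in (0.3, 0.7, 1.5, 2.0, 3.0):
                nz = p[p > 0]
                expected = math.log(float((nz**a).sum())) / (1 - a)
                assert renyi_entropy(p, a) == pytest.approx(expected, rel=1e-12)

    def test_monotone_nonincreasing_in_alpha(self, rng):
        for p in random_dists(200, rng):
            values = [renyi_entropy(p, a) for a in DEFAULT_ALPHAS]
            assert all(h1 >= h2 - 1e-10 for h1, h2 in zip(values, values[1:]))

    def test_bounds(self, rng):
        for p in random_dists(100, rng):
            for a in DEFAULT_ALPHAS:
                h = renyi_entropy(p, a)
                assert -1e-12 <= h <= math.log(30) + 1e-12

    def test_continuity_at_one(self, rng):
        for p in random_dists(100, rng):
            h_shannon = shannon_entropy(p)
            for a in (1 - 1e-6, 1 + 1e-6):
                assert abs(renyi_entropy(p, a) - h_shannon) < 1e-4

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        weights=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=30),
        alpha=st.sampled_from([0.0, 0.1, 0.5, 1.0, 1.5, 2.0]),
    )
    def test_permutation_invariance(self, weights, alpha):
        p = np.array(weights) / np.sum(weights)
        h = renyi_entropy(p, alpha)
        assert renyi_entropy(p[::-1].copy(), alpha) == pytest.approx(h, rel=1e-10)
        perm = np.roll(p, 3)
        assert renyi_entropy(perm, alpha) == pytest.approx(h, rel=1e-10)


class TestSeriesAndFeatures:
    def test_series_cardinality(self, toy_match):
        series = compute_edran_series(toy_match, alphas=(0.0, 1.0, 2.0))
        assert len(series) == 2 * 10 * 3
        assert set(series.columns) == {
            "match_id", "team", "interval", "alpha", "H", "dt_s", "empty_flag"
        }

    def test_single_region_team_has_zero_entropy(self):
        events = [
            make_event(time_s=t, duration_s=1.0, x=5.0, y=5.0) for t in np.linspace(0, 2699, 40)
        ]
        rec = MatchRecord("m", events, 1, {1: 2700.0, 2: 2700.0})
        series = compute_edran_series(rec, alphas=DEFAULT_ALPHAS)
        assert (series.loc[series["team"] == "A", "H"] == 0.0).all()

    def test_empty_intervals_flagged(self, toy_match):
        series = compute_edran_series(toy_match, alphas=(0.0,))
        b_rows = series[(series["team"] == "B") & (series["interval"] == 7)]
        assert bool(b_rows["empty_flag"].iloc[0]) and b_rows["H"].iloc[0] == 0.0

    def test_equal_entropies_give_zero_features(self, small_sim):
        _, records, _ = small_sim
        series = compute_edran_series(records[:3], alphas=(0.0,))
        series = series.copy()
        series["H"] = 1.7  # force H_A == H_B everywhere
        table = delta_features(series, records[:3], alpha=0.0)
        feats = table.filter(like="dH_t").to_numpy()
        assert np.allclose(feats, 0.0)

    def test_swapping_teams_negates_features(self, small_sim):
        _, records, _ = small_sim
        series = compute_edran_series(records[:3], alphas=(0.0,))
        flipped = series.copy()
        flipped["team"] = flipped["team"].map({"A": "B", "B": "A"})
        t1 = delta_features(series, records[:3], alpha=0.0).filter(like="dH_t").to_numpy()
        t2 = delta_features(flipped, records[:3], alpha=0.0).filter(like="dH_t").to_numpy()
        assert np.allclose(t1, -t2)

    def test_delta_feature_arithmetic(self):
        import pandas as pd

        rows = []
        for iv in range(1, 11):
            for team, h in (("A", 3.0), ("B", 2.5)):
                rows.append(
                    {"match_id": "m", "team": team, "interval": iv, "alpha": 0.0,
                     "H": h, "dt_s": 9.4 * 60, "empty_flag": False}
                )
        table = delta_features(pd.DataFrame(rows), {"m": 1}, alpha=0.0, dt_unit="min")
        assert table["dH_t1"].iloc[0] == pytest.approx(0.5 / 9.4, rel=1e-12)
        assert table["dH_t1"].iloc[0] == pytest.approx(0.0532, abs=5e-5)

    def test_missing_interval_is_an_error(self, toy_match):
        series = compute_edran_series(toy_match, alphas=(0.0,))
        broken = series[series["interval"] != 4]
        with pytest.raises(ValueError, match="missing interval"):
            delta_features(broken, {"m1": 1}, alpha=0.0)
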