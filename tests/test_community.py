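"""Hellinger/Bray-Curtis transforms, environment overlap, rarefaction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sedavirome.community import (
    CommunityError,
    OverlapResult,
    bray_curtis,
    environment_overlap,
    hellinger_distance,
    hellinger_transform,
    rarefaction_overlap_curve,
    rarefy,
    round_half_away,
)
from sedavirome.tables import CountMatrix, aggregate_cumulative
from sedavirome.taxonomy import parse_taxonomy

positive_rows = st.lists(
    st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=20
).filter(lambda xs: sum(xs) > 0)


class TestTransforms:
    def test_hellinger_examples(self):
        np.testing.assert_allclose(hellinger_transform([1, 0, 0]), [1, 0, 0])
        np.testing.assert_allclose(
            hellinger_transform([1, 3]), [0.5, np.sqrt(3) / 2]
        )
        np.testing.assert_allclose(hellinger_transform([2, 2, 2, 2]), [0.5] * 4)

    def test_hellinger_all_zero_is_error(self):
        with pytest.raises(CommunityError):
            hellinger_transform([0.0, 0.0])

    @given(positive_rows)
    def test_hellinger_unit_norm(self, row):
        h = hellinger_transform(row)
        assert np.sum(h**2) == pytest.approx(1.0, abs=1e-9)

    def test_bray_curtis_examples(self):
        assert bray_curtis([2, 1, 0], [2, 1, 0]) == 0.0
        assert bray_curtis([1, 0], [0, 1]) == 1.0
        assert bray_curtis([2, 1, 0], [1, 1, 1]) == pytest.approx(1 / 3)

    def test_bray_curtis_both_zero_is_error(self):
        with pytest.raises(CommunityError):
            bray_curtis([0, 0], [0, 0])

    @given(positive_rows, positive_rows)
    def test_bray_curtis_bounded_and_symmetric(self, u, v):
        m = min(len(u), len(v))
        u, v = u[:m], v[:m]
        if sum(u) + sum(v) == 0:
            return
        d = bray_curtis(u, v)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(v, u))

    @given(positive_rows, positive_rows)
    def test_hellinger_distance_bounded_by_sqrt2(self, u, v):
        m = min(len(u), len(v))
        u, v = u[:m], v[:m]
        if sum(u) == 0 or sum(v) == 0:
            return
        assert 0.0 <= hellinger_distance(u, v) <= np.sqrt(2) + 1e-9


class TestOverlap:
    def test_published_scale_percentages(self):
        res = OverlapResult.from_counts(758, 697, 323)
        assert (res.pct_unique_a, res.pct_unique_b, res.pct_shared) == (43, 39, 18)

    def test_complete_overlap(self):
        res = OverlapResult.from_sets({1, 2, 3}, {1, 2, 3})
        assert (res.pct_unique_a, res.pct_unique_b, res.pct_shared) == (0, 0, 100)

    def _toy(self, lake_rows, marine_rows, n_species=6):
        nodes = [(1, 1, "no-rank"), (2, 1, "superkingdom")]
        names = [(1, "root"), (2, "Viruses")]
        for i in range(n_species):
            nodes.append((10 + i, 2, "species"))
            names.append((10 + i, f"v{i}"))
        tree = parse_taxonomy(nodes, names)
        data = pd.DataFrame(
            np.column_stack([lake_rows, marine_rows]),
            index=pd.Index(range(10, 10 + n_species), name="taxid"),
            columns=["L1", "M1"],
        )
        cm = aggregate_cumulative(CountMatrix(data, "assigned"), tree)
        meta = pd.DataFrame(
            [
                {"sample_id": "L1", "site": "L", "environment": "lake",
                 "age_cal_ka_bp": 1.0},
                {"sample_id": "M1", "site": "M", "environment": "marine",
                 "age_cal_ka_bp": 1.0},
            ]
        )
        return tree, cm, meta

    def test_matches_brute_force_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(3, 100))
            lake = rng.integers(0, 3, n)
            marine = rng.integers(0, 3, n)
            if not lake.any() or not marine.any():
                continue
            tree, cm, meta = self._toy(lake, marine, n)
            res = environment_overlap(cm, meta, tree, within=2)
            a = {10 + i for i in range(n) if lake[i] > 0}
            b = {10 + i for i in range(n) if marine[i] > 0}
            assert res.unique_a == len(a - b)
            assert res.unique_b == len(b - a)
            assert res.shared == len(a & b)
            assert res.unique_a + res.unique_b + res.shared == len(a | b)

    def test_read_fractions(self):
        tree, cm, meta = self._toy([5, 5, 0], [0, 5, 5], 3)
        res = environment_overlap(cm, meta, tree, within=2)
        assert res.shared_reads == 10
        assert res.unique_reads == 10
        assert res.shared_read_fraction == pytest.approx(0.5)

    def test_missing_environment_is_error(self):
        tree, cm, meta = self._toy([1, 1, 1], [1, 1, 1], 3)
        meta = meta[meta["environment"] == "lake"]
        with pytest.raises(CommunityError, match="marine"):
            environment_overlap(cm, meta, tree, within=2)


class TestRarefy:
    def test_saturation_identity(self):
        v = np.array([100, 0, 50])
        np.testing.assert_array_equal(rarefy(v, 150, seed=0), v)
        np.testing.assert_array_equal(rarefy(v, 10**8, seed=0), v)

    def test_depth_zero(self):
        np.testing.assert_array_equal(rarefy([5, 5], 0, seed=0), [0, 0])

    def test_negative_depth_is_error(self):
        with pytest.raises(CommunityError):
            rarefy([1, 2], -1)

    def test_support_conservation_and_hypergeometric_mean(self):
        v = np.array([100, 0, 50])
        draws = np.array([rarefy(v, 30, seed=s) for s in range(1000)])
        assert (draws.sum(axis=1) == 30).all()
        assert (draws[:, 1] == 0).all()
        # hypergeometric mean 30*100/150 = 20, sd ~ 2.3 -> mean of 1000
        # draws within +-4 sd/sqrt(1000)
        se = np.sqrt(30 * (100 / 150) * (50 / 150) * (120 / 149)) / np.sqrt(1000)
        assert abs(draws[:, 0].mean() - 20.0) < 4 * se

    def test_reproducible_under_seed(self):
        v = [40, 30, 20, 10]
        np.testing.assert_array_equal(
            rarefy(v, 37, seed=99), rarefy(v, 37, seed=99)
        )


class TestRarefactionCurve:
    def test_saturated_depth_equals_unrarefied_and_deterministic(
        self, default_sim
    ):
        res, cum, tree = default_sim["res"], default_sim["cum"], default_sim["res"].tree
        vr = default_sim["viral_root"]
        curve = rarefaction_overlap_curve(
            cum, res.meta, tree, depths=(10**9,), reps=1, seed=4, within=vr
        )
        full = environment_overlap(cum, res.meta, tree, within=vr)
        row = curve.table.iloc[0]
        assert row["distinct_species"] == full.total
        assert row["pct_shared"] == pytest.approx(100 * full.frac_shared)
        again = rarefaction_overlap_curve(
            cum, res.meta, tree, depths=(10**9,), reps=1, seed=4, within=vr
        )
        pd.testing.assert_frame_equal(curve.table, again.table)

    def test_shared_proportion_stable_across_top_depths(self, default_sim):
        """Overlap proportions broadly consistent over depth decades."""
        res, cum, tree = default_sim["res"], default_sim["cum"], default_sim["res"].tree
        curve = rarefaction_overlap_curve(
            cum, res.meta, tree, depths=(10**4, 10**5, 10**6), reps=2,
            seed=11, within=default_sim["viral_root"],
        )
        shared = curve.table["pct_shared"].to_numpy()
        assert shared.max() - shared.min() < 10.0


def test_round_half_away():
    assert round_half_away(42.5) == 43
    assert round_half_away(39.2) == 39
    assert round_half_away(-2.5) == -3
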