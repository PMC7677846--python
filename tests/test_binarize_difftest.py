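import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from switchmodal import (
    CellAnnotation,
    adjust_pvalues,
    binarization_threshold,
    binarize,
    differential_switching,
    fractional_windows,
    geneset_overlap,
    read_gmt,
    switch_test,
)
from switchmodal.bimodality import MixtureFit


def _bimodal_fit(mu1, mu2, sd=0.3, w1=0.5):
    fit = MixtureFit(
        gene_id="g", dip=0.1, dip_p=0.001, n_components=2,
        means=np.array([mu1, mu2]), sds=np.array([sd, sd]),
        weights=np.array([w1, 1 - w1]), epsilon=1e-5,
    )
    fit.is_bimodal = True
    return fit


class TestThreshold:
    def test_symmetric_valley_near_midpoint(self, rng):
        sd = 0.3
        x = np.concatenate([rng.normal(0, sd, 2000), rng.normal(2, sd, 2000)])
        th = binarization_threshold(x, _bimodal_fit(0.0, 2.0, sd))
        assert abs(th - 1.0) < sd / 10

    def test_tight_modes_threshold_lands_in_the_valley(self, rng):
        x = np.concatenate([rng.normal(0, 0.2, 1500), rng.normal(3, 0.2, 500)])
        th = binarization_threshold(x, _bimodal_fit(0.0, 3.0, 0.2, w1=0.75))
        assert 0.6 < th < 2.4

    def test_valley_matches_brute_force_density_scan(self, rng):
        # overlapping modes give a unique interior valley both estimators see
        x = np.concatenate([rng.normal(0, 0.45, 1500), rng.normal(2, 0.45, 500)])
        th = binarization_threshold(x, _bimodal_fit(0.0, 2.0, 0.45, w1=0.75))
        hist, edges = np.histogram(x, bins=100, range=(0.0, 2.0), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        smoothed = np.convolve(hist, np.ones(9) / 9, mode="same")
        inner = (centers > 0.3) & (centers < 1.7)
        brute = centers[inner][np.argmin(smoothed[inner])]
        assert abs(th - brute) < 0.25

    def test_monotone_density_falls_back_to_midpoint(self, rng):
        # overlapping components: no interior valley between the means
        x = rng.normal(1.0, 1.0, 1000)
        th = binarization_threshold(x, _bimodal_fit(0.9, 1.1, 1.0))
        assert th == pytest.approx(1.0, abs=0.02)

    def test_non_bimodal_fit_rejected(self, rng):
        fit = _bimodal_fit(0, 2)
        fit.is_bimodal = False
        with pytest.raises(ValueError):
            binarization_threshold(rng.normal(size=100), fit)


class TestBinarize:
    def test_boundary_value_is_on(self):
        df = pd.DataFrame([[0.5, 0.49, 0.51]], index=["g"], columns=list("abc"))
        bits = binarize(df, pd.Series({"g": 0.5}))
        assert list(bits.loc["g"]) == [1, 0, 1]

    def test_extreme_thresholds(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        assert binarize(df, pd.Series({"g": -np.inf})).to_numpy().all()
        assert not binarize(df, pd.Series({"g": 10.0})).to_numpy().any()

    def test_missing_threshold_errors(self):
        df = pd.DataFrame([[1.0]], index=["g"], columns=["a"])
        with pytest.raises(ValueError, match="g"):
            binarize(df, pd.Series(dtype=float))


class TestFractionalWindows:
    def test_750_cells_30_windows_of_25(self):
        cells = [f"c{i}" for i in range(750)]
        bits = pd.DataFrame(np.ones((2, 750), dtype=int),
                            index=["g1", "g2"], columns=cells)
        ann = CellAnnotation(pd.Series(["grp"] * 750, index=cells))
        prof = fractional_windows(bits, ann, n_windows=30, seed=0)
        assert prof.fractions.shape == (2, 30)
        assert all(len(c) == 25 for c in prof.window_cells.values())
        assert (prof.fractions.to_numpy() == 1.0).all()

    def test_windows_never_span_groups_and_scale_with_size(self):
        cells = [f"c{i}" for i in range(90)]
        groups = ["A"] * 60 + ["B"] * 30
        bits = pd.DataFrame(np.zeros((1, 90), dtype=int), index=["g"], columns=cells)
        ann = CellAnnotation(pd.Series(groups, index=cells), group_order=["A", "B"])
        prof = fractional_windows(bits, ann, n_windows=9, seed=1)
        per_group = prof.window_groups.value_counts()
        assert per_group["A"] == 6 and per_group["B"] == 3
        for label, wcells in prof.window_cells.items():
            expected = prof.window_groups[label]
            assert {ann.groups[c] for c in wcells} == {expected}

    def test_fraction_arithmetic(self):
        cells = list("abcde")
        bits = pd.DataFrame([[1, 1, 1, 0, 0]], index=["g"], columns=cells)
        ann = CellAnnotation(pd.Series(["x"] * 5, index=cells))
        prof = fractional_windows(bits, ann, n_windows=1, seed=0)
        assert prof.fractions.iat[0, 0] == pytest.approx(0.6)

    def test_more_windows_than_cells_errors(self):
        bits = pd.DataFrame([[1, 0]], index=["g"], columns=["a", "b"])
        ann = CellAnnotation(pd.Series(["x", "x"], index=["a", "b"]))
        with pytest.raises(ValueError):
            fractional_windows(bits, ann, n_windows=3)


def _fisher_p_oracle(on_a, off_a, on_b, off_b):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n = on_a + off_a + on_b + off_b
    row_a = on_a + off_a
    col_on = on_a + on_b
    probs = {
        k: hypergeom.pmf(k, n, col_on, row_a)
        for k in range(max(0, col_on - (n - row_a)), min(row_a, col_on) + 1)
    }
    p_obs = probs[on_a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestSwitchTest:
    def test_closed_form_strong_switch(self):
        a = np.array([1] * 10 + [0] * 90)   # 10% ON in baseline
        b = np.array([1] * 90 + [0] * 10)   # 90% ON after differentiation
        res = switch_test(a, b)
        assert res.odds_ratio == pytest.approx(81.0)
        assert res.p == pytest.approx(_fisher_p_oracle(10, 90, 90, 10), rel=1e-9)
        assert res.p < 1e-25

    def test_no_association(self):
        a = np.array([1] * 50 + [0] * 50)
        res = switch_test(a, a)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cells(self):
        res = switch_test(np.ones(100), np.zeros(100))
        assert np.isfinite(res.odds_ratio) and res.odds_ratio < 1
        assert res.p == pytest.approx(_fisher_p_oracle(100, 0, 0, 100), rel=1e-9)

    def test_label_swap_symmetry(self, rng):
        a = (rng.random(80) < 0.3).astype(int)
        b = (rng.random(60) < 0.7).astype(int)
        r1, r2 = switch_test(a, b), switch_test(b, a)
        assert r1.p == pytest.approx(r2.p, rel=1e-9)
        assert r1.odds_ratio == pytest.approx(1 / r2.odds_ratio, rel=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            switch_test(np.array([]), np.array([1, 0]))


class TestAdjustPvalues:
    def test_hand_computed_step_up(self):
        out = adjust_pvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_vectors(self, rng):
        ps = rng.random(500)
        out = adjust_pvalues(ps)
        # brute-force BH: p_(i) * n / i with a running minimum from the top
        order = np.argsort(ps)
        n = len(ps)
        raw = ps[order] * n / np.arange(1, n + 1)
        brute = np.minimum.accumulate(raw[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(brute, 1.0)
        np.testing.assert_allclose(out, expected)

    def test_single_and_equal_values(self):
        assert adjust_pvalues(np.array([0.42]))[0] == pytest.approx(0.42)
        out = adjust_pvalues(np.full(5, 0.2))
        assert np.unique(out).size == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(np.array([0.5, 1.5]))


class TestDifferentialSwitching:
    def test_direction_calls(self):
        cells_a = [f"a{i}" for i in range(60)]
        cells_b = [f"b{i}" for i in range(60)]
        bits = pd.DataFrame(
            [[1] * 5 + [0] * 55 + [1] * 55 + [0] * 5,     # up
             [1] * 55 + [0] * 5 + [1] * 5 + [0] * 55,     # down
             [1] * 30 + [0] * 30 + [1] * 30 + [0] * 30],  # flat
            index=["up", "down", "flat"], columns=cells_a + cells_b,
        )
        res = differential_switching(bits, cells_a, cells_b, alpha=0.05)
        assert res.loc["up", "direction"] == "up"
        assert res.loc["down", "direction"] == "down"
        assert res.loc["flat", "direction"] == "none"
        assert (res["p_adj"] >= res["p"] - 1e-12).all()


class TestGenesetOverlap:
    def test_full_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}
        res = geneset_overlap(query, {"s": set(query)}, universe)
        from math import comb
        assert res.loc["s", "p"] == pytest.approx(1 / comb(20, 5))

    def test_disjoint_set_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = geneset_overlap({"g0"}, {"s": {"g5", "g6"}}, universe)
        assert res.loc["s", "p"] == pytest.approx(1.0)

    def test_degenerate_everything_equal(self):
        u = {"a", "b", "c"}
        res = geneset_overlap(u, {"s": set(u)}, u)
        assert res.loc["s", "overlap"] == 3
        assert res.loc["s", "p"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            geneset_overlap({"x"}, {"s": {"a"}}, {"a", "b"})


def test_gmt_round_trip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("s1\tdesc\tg1\tg2\ns2\tdesc\tg3\n")
    assert read_gmt(path) == {"s1": {"g1", "g2"}, "s2": {"g3"}}
    bad = tmp_path / "bad.gmt"
    bad.write_text("x\ty\n")
    with pytest.raises(ValueError, match="malformed"):
        read_gmt(bad)
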