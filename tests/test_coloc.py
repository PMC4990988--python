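"""Costes thresholding, Pearson correlation and group-statistics tests."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from lirquant.coloc import (
    ImageStack,
    PCCResult,
    analyze_cell,
    compare_groups,
    costes_thresholds,
    pearson,
    two_way_anova,
)


def exhaustive_costes(ch1, ch2):
    """Independent oracle: orthogonal regression by explicit eigen-decomposition,
    then a full scan over all unique ch1 intensities keeping the largest
    threshold whose sub-threshold correlation is <= 0."""
    x, y = np.asarray(ch1, float).ravel(), np.asarray(ch2, float).ravel()
    cov = np.cov(np.vstack([x, y]))
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(vals)]
    a = v[1] / v[0]
    b = y.mean() - a * x.mean()
    best = None
    for t1 in np.unique(x)[::-1]:
        t2 = a * t1 + b
        sel = (x < t1) & (y < t2)
        if sel.sum() < 2:
            continue
        sub = np.corrcoef(x[sel], y[sel])
        r = sub[0, 1]
        if np.isnan(r) or r <= 0:
            best = (t1, t2)
            break
    return best


class TestPearson:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 500)
        assert pearson(x, 2 * x + 5) == pytest.approx(1.0, abs=1e-12)
        assert pearson(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 1, 100_000)
        y = rng.uniform(0, 1, 100_000)
        assert abs(pearson(x, y)) < 0.02

    def test_zero_variance_is_nan_marker(self):
        assert math.isnan(pearson(np.ones(10), np.arange(10.0)))

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(0, 50, 1000), rng.uniform(0, 50, 1000)
        assert pearson(3.2 * x + 7, 0.5 * y + 1) == pytest.approx(pearson(x, y), abs=1e-12)


class TestCostes:
    def test_identical_channels_recover_unit_regression(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 200, (8, 8, 4)).astype(float)
        from lirquant.coloc import _orthogonal_regression
        a, b = _orthogonal_regression(x.ravel(), x.ravel())
        assert a == pytest.approx(1.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_matches_exhaustive_scan_on_small_fixtures(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            base = rng.integers(0, 50, (8, 8, 8)).astype(float)
            ch1 = base + rng.integers(0, 10, base.shape)
            ch2 = 0.8 * base + rng.integers(0, 10, base.shape)
            got = costes_thresholds(ch1, ch2)
            want = exhaustive_costes(ch1, ch2)
            assert want is not None
            assert got[2]
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_independent_noise_thresholds_near_maximum(self):
        # with genuinely independent channels almost the whole image is
        # uncorrelated, so the scan stops within a few steps of the top
        rng = np.random.default_rng(4)
        ch1 = rng.integers(0, 100, (20, 20, 20)).astype(float)
        ch2 = rng.integers(0, 100, (20, 20, 20)).astype(float)
        t1, t2, found = costes_thresholds(ch1, ch2)
        assert found
        assert t1 > np.quantile(ch1, 0.85)
        # and it agrees with the exhaustive oracle
        want = exhaustive_costes(ch1, ch2)
        assert t1 == pytest.approx(want[0], abs=1e-12)

    def test_puncta_on_background_separated(self):
        # correlated puncta above zero background: thresholds must sit below
        # every punctum voxel
        img1 = np.zeros((4, 16, 16))
        img2 = np.zeros((4, 16, 16))
        rng = np.random.default_rng(5)
        pos = [(z, y, x) for z in range(4) for y in (3, 8, 13) for x in (3, 8, 13)]
        for z, y, x in pos:
            amp = rng.uniform(80, 120)
            img1[z, y, x] = amp
            img2[z, y, x] = 0.9 * amp
        img1 += rng.integers(0, 6, img1.shape)
        img2 += rng.integers(0, 6, img2.shape)
        t1, t2, found = costes_thresholds(img1, img2)
        assert found
        # thresholds sit above the background ...
        assert t1 > img1[img1 < 50].max()
        assert t2 > img2[img2 < 50].max()
        # ... and the bulk of the puncta survives them; the scan halts inside
        # the dim tail of the punctum amplitude distribution, so the dimmest
        # few may straddle the threshold pair
        above = sum(img1[p] > t1 and img2[p] > t2 for p in pos)
        assert above >= 0.85 * len(pos)

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="constant channel"):
            costes_thresholds(np.ones((2, 2, 2)), np.random.default_rng(0).uniform(size=(2, 2, 2)))


class TestAnalyzeCell:
    def _stack(self, g, r):
        return ImageStack(channel_green=g, channel_red=r)

    def test_identical_channels_give_unit_pcc(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 300, (4, 16, 16)).astype(float)
        res = analyze_cell(self._stack(img, img), np.ones(img.shape, bool))
        assert res.pcc == pytest.approx(1.0, abs=1e-9)
        assert res.pcc_global == pytest.approx(1.0, abs=1e-9)

    def test_empty_mask_is_undefined_marker(self):
        img = np.ones((4, 8, 8))
        res = analyze_cell(self._stack(img, img), np.zeros(img.shape, bool))
        assert res.undefined and math.isnan(res.pcc)

    def test_red_only_puncta_lower_thresholded_pcc(self):
        from lirquant.synth import ConditionPreset, gen_cell_stack
        full = ConditionPreset("all-dual", f_acidic=0.0)
        half = ConditionPreset("half-red", f_acidic=0.5)
        s1, m1, _ = gen_cell_stack(full, seed=77)
        s2, m2, _ = gen_cell_stack(half, seed=77)
        r1 = analyze_cell(s1, m1)
        r2 = analyze_cell(s2, m2)
        assert r2.pcc < r1.pcc


class TestCompareGroups:
    def _results(self, groups):
        out = []
        for cond, vals in groups.items():
            out += [PCCResult(f"{cond}-{i}", cond, v, v, 0, 0, 100)
                    for i, v in enumerate(vals)]
        return out

    def test_identical_groups_give_f_zero_p_one(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gs = compare_groups(self._results({"a": [0.5, 0.5], "b": [0.5, 0.5]}))
        assert gs.f_statistic == 0.0 or math.isnan(gs.f_statistic)
        assert all(p == 1.0 for *_, p in gs.pairwise)

    def test_disjoint_constant_groups_give_infinite_f(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gs = compare_groups(self._results({"a": [0, 0, 0, 0], "b": [1, 1, 1, 1]}))
        assert math.isinf(gs.f_statistic) and gs.p_value == 0.0
        assert gs.pairwise[0][2] == pytest.approx(-1.0)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(7)
        groups = {c: list(rng.normal(0.5 + d, 0.1, 60))
                  for c, d in (("a", 0.0), ("b", 0.05), ("c", 0.1))}
        gs = compare_groups(self._results(groups))
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert gs.f_statistic == pytest.approx(f_ref, rel=1e-9)
        assert gs.p_value == pytest.approx(p_ref, rel=1e-6)

    def test_single_cell_condition_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(self._results({"a": [0.5], "b": [0.4, 0.6]}))

    def test_small_groups_warn(self):
        with pytest.warns(UserWarning, match="fewer than the 50"):
            compare_groups(self._results({"a": [0.4, 0.5], "b": [0.6, 0.7]}))


class TestTwoWayAnova:
    def test_matches_known_main_effect(self):
        # constructed balanced design with a pure factor-A effect
        values, fa, fb = [], [], []
        rng = np.random.default_rng(8)
        for a, mu in (("WT", 1.0), ("mut", 0.5)):
            for b in ("LC3B", "Ub"):
                for _ in range(4):
                    values.append(mu + rng.normal(0, 0.01))
                    fa.append(a)
                    fb.append(b)
        out = two_way_anova(np.array(values), np.array(fa), np.array(fb))
        assert out["A"]["p"] < 1e-6
        assert out["B"]["p"] > 0.05
        assert out["AB"]["p"] > 0.05

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            two_way_anova(np.arange(5.0),
                          np.array(["a", "a", "a", "b", "b"]),
                          np.array(["x", "y", "x", "x", "y"]))
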