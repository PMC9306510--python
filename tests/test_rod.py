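"""Relative optical density: conversion, hierarchical averaging, t-test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from psckit.rod import (SaturationError, compare_regions, group_t_test,
                        hierarchical_mean, relative_percent, rod_from_grey)
from psckit.simulate import generate_grey_values


class TestRodFromGrey:
    def test_printed_formula_at_zero(self):
        assert rod_from_grey(0.0) == pytest.approx(math.log10(256 / 255),
                                                   abs=1e-6)

    def test_printed_formula_mid_scale(self):
        # grey 155, no background: log10(256/100) = 0.4082
        assert rod_from_grey(155.0) == pytest.approx(0.4082, abs=1e-4)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            rod_from_grey(255.0)

    def test_background_deducted_before_conversion(self):
        assert rod_from_grey(155.0, 55.0) == pytest.approx(
            rod_from_grey(100.0), abs=1e-12)

    def test_negative_corrected_value_needs_clamp(self):
        with pytest.raises(ValueError):
            rod_from_grey(10.0, 50.0)
        assert rod_from_grey(10.0, 50.0, clamp_negative=True) == \
            pytest.approx(rod_from_grey(0.0))

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0.0, 250.0))
    def test_monotone_and_invertible(self, grey):
        rod = rod_from_grey(grey)
        back = 255.0 - 256.0 * 10 ** (-rod)
        assert back == pytest.approx(grey, abs=1e-9)
        assert rod_from_grey(min(grey + 1.0, 254.0)) >= rod


def _measurements(values_by_mouse, region="CA1-so", condition="a"):
    """values_by_mouse: {mouse: {vib: [cryo values]}}."""
    rows = []
    for mouse, vibs in values_by_mouse.items():
        for vib, cryos in vibs.items():
            for i, grey in enumerate(cryos):
                rows.append({"region": region, "condition": condition,
                             "mouse_id": mouse, "vibratome_id": f"{mouse}{vib}",
                             "cryotome_id": f"{mouse}{vib}c{i}",
                             "grey": grey, "background": 0.0})
    return pd.DataFrame(rows)


class TestHierarchicalMean:
    def test_equal_measurements_give_zero_sem(self):
        df = _measurements({m: {v: [100.0, 100.0] for v in "xyz"}
                            for m in "abcd"})
        res = hierarchical_mean(df)
        assert res["mean"] == pytest.approx(rod_from_grey(100.0))
        assert res["sem"] == 0.0
        assert res["n_mice"] == 4

    def test_four_mouse_example(self):
        # per-mouse RODs 0.18/0.20/0.21/0.21 -> mean 0.200, SEM 0.0071
        greys = [255.0 - 256.0 * 10 ** (-rod)
                 for rod in (0.18, 0.20, 0.21, 0.21)]
        df = _measurements({f"m{i}": {"v": [g]}
                            for i, g in enumerate(greys)})
        res = hierarchical_mean(df)
        assert res["mean"] == pytest.approx(0.200, abs=1e-6)
        assert res["sem"] == pytest.approx(0.00707, abs=1e-4)

    def test_balanced_design_equals_grand_mean(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(50, 150, (3, 2, 2))  # 3 mice x 2 vib x 2 cryo
        df = _measurements({f"m{i}": {f"v{j}": list(vals[i, j])
                                      for j in range(2)} for i in range(3)})
        res = hierarchical_mean(df)
        rods = rod_from_grey(vals.ravel())
        assert res["mean"] == pytest.approx(rods.mean(), abs=1e-12)

    def test_unbalanced_design_differs_from_pooled_mean(self):
        # one vibratome slice contributes a single cryotome section: it is
        # its own slice mean, so the hierarchy no longer equals the pooled
        # leaf average
        df = _measurements({"m1": {"v1": [100.0, 100.0], "v2": [140.0]},
                            "m2": {"v1": [100.0, 120.0]}})
        res = hierarchical_mean(df)
        m1 = (rod_from_grey(100.0) + rod_from_grey(140.0)) / 2
        m2 = (rod_from_grey(100.0) + rod_from_grey(120.0)) / 2
        assert res["mean"] == pytest.approx((m1 + m2) / 2, abs=1e-12)
        pooled = rod_from_grey(
            np.array([100.0, 100.0, 140.0, 100.0, 120.0])).mean()
        assert res["mean"] != pytest.approx(pooled, abs=1e-6)

    def test_orphan_measurement_rejected(self):
        df = _measurements({"m1": {"v1": [100.0]}})
        df.loc[0, "vibratome_id"] = None
        with pytest.raises(ValueError):
            hierarchical_mean(df)


class TestRelativePercent:
    def test_printed_table_value(self):
        # CA3 stratum oriens: 0.125 vs 0.164 prints as 76%
        assert relative_percent(0.125, 0.164) == 76

    def test_equal_means_give_100(self):
        assert relative_percent(0.2, 0.2) == 100

    def test_rounding_is_half_up(self):
        assert relative_percent(0.215, 0.213) == 101  # 100.94 -> 101
        assert relative_percent(201.0, 200.0) == 101  # exactly 100.5 rounds up

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            relative_percent(0.1, 0.0)


class TestGroupTTest:
    def test_identical_groups_give_p_one(self):
        assert group_t_test([0.2, 0.2], [0.2, 0.2]) == 1.0

    def test_perfect_separation_of_constants_gives_p_zero(self):
        assert group_t_test([0.0, 0.0], [1.0, 1.0]) == 0.0

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(0.2, 0.03, 4)
        b = rng.normal(0.25, 0.03, 4)
        p = group_t_test(a, b)
        # closed-form equal-variance t with n1 + n2 - 2 df
        sp2 = ((a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        expected = 2 * sps.t.sf(abs(t), 6)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            group_t_test([0.1], [0.2, 0.3])


class TestRegionComparison:
    def test_generated_dataset_round_trip(self):
        regions = {r: g for r, g in zip(
            ("DG-ML", "CA1-so", "CA1-sr", "CA1-slm", "CA3-so", "CA3-sr"),
            (120.0, 130.0, 145.0, 128.0, 105.0, 103.0))}
        frames = [generate_grey_values(regions, 10.0, 3.0, condition=c,
                                       seed=s, mouse_sd=5.0)
                  for c, s in (("aCSF", 1), ("treated", 2))]
        df = pd.concat(frames, ignore_index=True)
        out = compare_regions(df, "aCSF", "treated")
        assert len(out) == 6
        assert out["p_value"].between(0, 1).all()
        assert (out["percent"] > 0).all()
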