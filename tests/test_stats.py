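"""Group statistics: equalization, K-S, Mann-Whitney, Fisher, summaries.

The nonparametric tests are checked against independent oracles written
here: a pooled-support ECDF sweep for the K-S statistic, full rank
assignment enumeration for the exact Mann-Whitney p, and hypergeometric
enumeration (via binomial coefficients) for Fisher's exact p.
"""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from psckit.events import EventTable, PSCEvent, filter_events
from psckit.stats import (ComparisonConfig, equalize_event_counts,
                          fisher_exact, ks_two_sample, mann_whitney,
                          run_comparison, summarize_cells)


# ---------------------------------------------------------------- oracles
def ks_D_brute_force(x, y):
    """sup |ECDF_x - ECDF_y| over the pooled support."""
    x, y = np.sort(x), np.sort(y)
    support = np.concatenate([x, y])
    best = 0.0
    for v in support:
        d = abs(np.searchsorted(x, v, side="right") / x.size
                - np.searchsorted(y, v, side="right") / y.size)
        best = max(best, d)
    return best


def mw_p_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating rank assignments."""
    x, y = np.asarray(x), np.asarray(y)
    nx = x.size
    pooled = np.concatenate([x, y])

    def u_of(first_idx):
        xs = pooled[list(first_idx)]
        ys = np.delete(pooled, list(first_idx))
        return sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)

    u_obs = u_of(range(nx))
    mu = nx * (pooled.size - nx) / 2.0
    stat_obs = abs(u_obs - mu)
    total = hits = 0
    for idx in itertools.combinations(range(pooled.size), nx):
        total += 1
        if abs(u_of(idx) - mu) >= stat_obs - 1e-12:
            hits += 1
    return hits / total


def fisher_p_enumeration(table):
    """Two-sided Fisher p: sum of hypergeometric masses <= the observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    return sum(p for k in range(0, c1 + 1)
               if (p := prob(k)) <= p_obs * (1 + 1e-9))


# ----------------------------------------------------------- equalization
def _table(cells):
    """cells: {cell_id: n_accepted_events} at 10 Hz spacing."""
    events = []
    for cell, n in cells.items():
        events.extend(
            PSCEvent(0.1 * i, 0.1 * i + 0.003, 10.0, 1.0, 5.0, 0.9,
                     cell_id=cell, condition="vehicle")
            for i in range(n))
    return filter_events(events)


class TestEqualizeEventCounts:
    def test_cell_with_exactly_n_events_fully_retained(self):
        eq = equalize_event_counts(_table({"a": 50, "b": 80}), 50)
        assert (eq.accepted().groupby("cell_id").size() == 50).all()

    def test_pooled_size_for_nine_cells_of_545(self):
        eq = equalize_event_counts(_table({f"c{i}": 600 for i in range(9)}), 545)
        assert len(eq.accepted()) == 4905

    def test_short_cells_excluded(self):
        eq = equalize_event_counts(_table({"a": 100, "b": 10}), 50)
        assert eq.cells() == ["a"]

    def test_deterministic_for_both_methods(self):
        table = _table({"a": 100, "b": 100})
        for method in ("prefix", "random"):
            one = equalize_event_counts(table, 60, seed=3, method=method)
            two = equalize_event_counts(table, 60, seed=3, method=method)
            assert one.frame.equals(two.frame)

    def test_prefix_keeps_earliest_events(self):
        eq = equalize_event_counts(_table({"a": 100}), 10)
        assert np.allclose(eq.accepted()["onset_s"], 0.1 * np.arange(10))

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            equalize_event_counts(_table({"a": 10}), 1)


# -------------------------------------------------------------------- K-S
class TestKolmogorovSmirnov:
    def test_identical_samples_have_zero_distance(self):
        x = np.array([1.0, 2.0, 3.0])
        D, p = ks_two_sample(x, x)
        assert D == 0.0

    def test_separated_samples_have_distance_one(self):
        D, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert D == 1.0

    def test_matches_pooled_support_sweep_exactly(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 50)
            y = rng.normal(0.3, 1.2, 50)
            D, _ = ks_two_sample(x, y)
            assert D == pytest.approx(ks_D_brute_force(x, y), abs=1e-14)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


# ----------------------------------------------------------- Mann-Whitney
class TestMannWhitney:
    def test_fully_separated_three_vs_three(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)  # 2/20 rank assignments as extreme

    def test_tied_singletons_give_p_one(self):
        _, p = mann_whitney([5.0], [5.0])
        assert p == 1.0

    @pytest.mark.parametrize("nx,ny", [(3, 3), (4, 4), (5, 6), (6, 6)])
    def test_exact_p_equals_full_enumeration(self, nx, ny, rng):
        x = rng.normal(size=nx)
        y = rng.normal(0.5, 1.0, size=ny)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(mw_p_enumeration(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [])


# ------------------------------------------------------------------ Fisher
class TestFisherExact:
    def test_minimal_balanced_table(self):
        assert fisher_exact([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_invariant_to_transposition_and_row_swap(self, rng):
        for _ in range(10):
            t = rng.integers(0, 30, size=(2, 2))
            p = fisher_exact(t)
            assert fisher_exact(t.T) == pytest.approx(p, abs=1e-12)
            assert fisher_exact(t[::-1]) == pytest.approx(p, abs=1e-12)

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(10):
            t = rng.integers(0, 25, size=(2, 2))
            assert fisher_exact(t) == pytest.approx(
                fisher_p_enumeration(t.tolist()), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])


# ------------------------------------------------------------- summaries
class TestSummarizeCells:
    def test_frequency_is_count_over_duration(self):
        table = _table({"a": 446})
        _, groups = summarize_cells(table, {"a": 120.0})
        assert groups["frequency_mean"].iloc[0] == pytest.approx(3.717, abs=1e-3)

    def test_single_cell_has_no_sem(self):
        _, groups = summarize_cells(_table({"a": 10}), {"a": 10.0})
        assert np.isnan(groups["frequency_sem"].iloc[0])

    def test_identical_cells_have_zero_sem(self):
        _, groups = summarize_cells(_table({"a": 50, "b": 50}),
                                    {"a": 10.0, "b": 10.0})
        assert groups["frequency_sem"].iloc[0] == 0.0

    def test_missing_duration_rejected(self):
        with pytest.raises(KeyError):
            summarize_cells(_table({"a": 10}), {})


# -------------------------------------------------------- full comparison
class TestRunComparison:
    def _arm(self, cells, rate, seed, condition):
        rng = np.random.default_rng(seed)
        events = []
        for c in range(cells):
            onsets = np.cumsum(rng.exponential(1.0 / rate, 300))
            for o in onsets:
                events.append(PSCEvent(
                    o, o + 0.003, float(rng.lognormal(2.3, 0.4)),
                    float(rng.choice([1.0, 3.0])), 6.0, 0.9,
                    cell_id=f"{condition}{c}", condition=condition))
        return filter_events(events)

    def test_report_structure_and_flags(self):
        v = self._arm(3, 4.0, 0, "v")
        t = self._arm(3, 6.0, 1, "t")
        durations = {c: 80.0 for c in v.cells() + t.cells()}
        rep = run_comparison(v, t, ComparisonConfig(n_per_cell=200,
                                                    cutoff_ms=1.4),
                             recording_durations=durations)
        assert set(rep.ks) == {"iei", "amplitude", "rise_time"}
        assert set(rep.mann_whitney) == {"frequency", "amplitude", "rise_time"}
        for v_ in rep.ks.values():
            assert 0.0 <= v_["D"] <= 1.0 and 0.0 <= v_["p"] <= 1.0
            assert v_["flag"] == (v_["p"] < 0.01 and v_["D"] > 0.05)
        assert rep.fisher["cutoff_ms"] == 1.4

    def test_empty_arm_rejected(self):
        v = self._arm(2, 4.0, 0, "v")
        empty = EventTable(v.frame.iloc[0:0])
        with pytest.raises(ValueError):
            run_comparison(v, empty, ComparisonConfig(n_per_cell=10))
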