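"""Group statistics for two-arm PSC comparisons.

The battery mirrors standard practice for spontaneous/miniature synaptic
currents: event counts are equalized across cells before pooling (so no
cell dominates the pooled distributions), pooled interevent-interval /
amplitude / rise-time distributions are compared with the two-sample
Kolmogorov-Smirnov test under a dual significance criterion (p < .01 AND
D > .05), cell-averaged metrics with the Mann-Whitney U test, and
fast:slow proportion changes with Fisher's exact test.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import (FastSlowCounts, NoCutoffError, classify_and_count,
                       ratio_curve, select_cutoff)
from .events import EventTable

__all__ = [
    "CellSummary",
    "ComparisonConfig",
    "ComparisonReport",
    "equalize_event_counts",
    "ks_two_sample",
    "mann_whitney",
    "fisher_exact",
    "summarize_cells",
    "run_comparison",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellSummary:
    cell_id: str
    condition: str
    n_events_used: int
    frequency: float       # accepted events / s of recording
    mean_amplitude: float  # pA
    mean_rise: float       # ms


def equalize_event_counts(table: EventTable, n_per_cell: int,
                          seed: int = 0, method: str = "prefix") -> EventTable:
    """Retain exactly ``n_per_cell`` accepted events per cell.

    With ``method="prefix"`` (default) each cell contributes its first
    ``n_per_cell`` accepted events in recording order — a contiguous
    epoch, which preserves the interevent-interval scale of the cell.  A
    seeded uniform subsample without replacement (``method="random"``) is
    also available, but note it stretches every cell's intervals to the
    same mean, erasing rate differences from the pooled IEI distribution.
    Cells with fewer accepted events are excluded with a logged notice.
    Both methods are deterministic given the seed.
    """
    if n_per_cell <= 1:
        raise ValueError("n_per_cell must be greater than 1")
    if method not in ("prefix", "random"):
        raise ValueError("method must be 'prefix' or 'random'")
    acc = table.accepted()
    kept = []
    for cell, group in sorted(acc.groupby("cell_id")):
        if len(group) < n_per_cell:
            log.info("cell %s excluded from equalization: %d < %d accepted events",
                     cell, len(group), n_per_cell)
            continue
        group = group.sort_values("onset_s")
        if method == "prefix":
            kept.append(group.iloc[:n_per_cell])
        else:
            rng = np.random.default_rng(np.random.SeedSequence(
                [int(seed) & 0x7FFFFFFF, zlib.crc32(str(cell).encode())]))
            idx = np.sort(rng.choice(len(group), size=n_per_cell, replace=False))
            kept.append(group.iloc[idx])
    if not kept:
        raise ValueError(
            f"no cell has {n_per_cell} accepted events; equalization impossible")
    return EventTable(pd.concat(kept, ignore_index=True))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: (D, asymptotic p).

    D is the supremum distance between the two empirical CDFs, evaluated
    exactly over the pooled support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: (U of the first sample, p).

    Exact enumeration for combined sample sizes up to 12 without ties;
    normal approximation with tie correction (and continuity correction)
    otherwise.  A fully tied pooled sample returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(counts) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Two-sidedness by the classical rule: sum hypergeometric probabilities
    of all tables (at fixed margins) no more probable than the observed
    one.  Accepts a FastSlowCounts or any 2x2 array-like.
    """
    table = counts.as_array() if isinstance(counts, FastSlowCounts) else \
        np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    return float(sps.fisher_exact(np.round(table).astype(np.int64))[1])


def summarize_cells(table: EventTable, recording_durations: dict,
                    n_animals: dict | None = None
                    ) -> tuple[list[CellSummary], pd.DataFrame]:
    """Cell-level summaries plus a mean +/- SEM group table.

    ``recording_durations`` maps cell_id to seconds of recording; the
    frequency is the accepted-event count over that duration.  The group
    table reports mean, SEM (absent for a single cell) and n per
    condition, the standard layout for cell-averaged comparisons.
    """
    acc = table.accepted()
    summaries = []
    for cell, group in sorted(acc.groupby("cell_id")):
        if cell not in recording_durations:
            raise KeyError(f"no recording duration for cell {cell}")
        dur = float(recording_durations[cell])
        summaries.append(CellSummary(
            cell_id=str(cell),
            condition=str(group["condition"].iloc[0]),
            n_events_used=int(len(group)),
            frequency=len(group) / dur,
            mean_amplitude=float(group["amplitude_pA"].mean()),
            mean_rise=float(group["rise_ms"].mean()),
        ))
    cell_df = pd.DataFrame([s.__dict__ for s in summaries])
    rows = []
    for condition, grp in cell_df.groupby("condition"):
        row = {"condition": condition, "n_cells": len(grp)}
        if n_animals:
            row["n_animals"] = n_animals.get(condition)
        for metric in ("frequency", "mean_amplitude", "mean_rise"):
            vals = grp[metric].to_numpy()
            row[f"{metric}_mean"] = float(vals.mean())
            row[f"{metric}_sem"] = (float(vals.std(ddof=1) / np.sqrt(vals.size))
                                    if vals.size > 1 else np.nan)
        rows.append(row)
    return summaries, pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonConfig:
    """Settings for the full two-arm comparison."""

    n_per_cell: int = 545
    seed: int = 0
    cutoff_ms: float | None = None   # None: select from the data
    fallback_cutoff_ms: float = 1.4  # used when selection is low-confidence
    cutoff_tolerance: float = 0.10
    ks_alpha: float = 0.01
    ks_min_D: float = 0.05
    mw_alpha: float = 0.05
    fisher_alpha: float = 0.05


@dataclass
class ComparisonReport:
    """All test results of one vehicle-vs-treated comparison."""

    ks: dict = field(default_factory=dict)        # metric -> {"D", "p", "flag"}
    mann_whitney: dict = field(default_factory=dict)  # metric -> {"U", "p", "flag"}
    fisher: dict = field(default_factory=dict)    # {"p", "flag", "cutoff_ms", counts}
    cell_summary: pd.DataFrame | None = None
    n_per_cell: int = 0
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "n_per_cell": self.n_per_cell,
            "ks": self.ks,
            "mann_whitney": self.mann_whitney,
            "fisher": self.fisher,
            "notes": list(self.notes),
        }
        if self.cell_summary is not None:
            out["cell_summary"] = self.cell_summary.to_dict(orient="records")
        return out


def _pooled_ieis(table: EventTable) -> np.ndarray:
    out = []
    for cell, grp in table.accepted().groupby("cell_id"):
        onsets = np.sort(grp["onset_s"].to_numpy())
        if onsets.size >= 2:
            out.append(np.diff(onsets))
    return np.concatenate(out) if out else np.empty(0)


def run_comparison(vehicle: EventTable, treated: EventTable,
                   config: ComparisonConfig = ComparisonConfig(),
                   recording_durations: dict | None = None) -> ComparisonReport:
    """Equalize counts, then run the full K-S / Mann-Whitney / Fisher battery.

    Pooled-event ECDFs (IEI, amplitude, rise time) are compared by K-S
    with the dual flag p < ks_alpha AND D > ks_min_D; cell averages by
    Mann-Whitney; the fast:slow split (at the configured or data-selected
    cutoff) by Fisher's exact test.  Frequencies need recording durations
    and are computed from all accepted events before equalization.
    """
    if len(vehicle.accepted()) == 0 or len(treated.accepted()) == 0:
        raise ValueError("both arms need accepted events")
    report = ComparisonReport(n_per_cell=config.n_per_cell)

    eq_v = equalize_event_counts(vehicle, config.n_per_cell, config.seed)
    eq_t = equalize_event_counts(treated, config.n_per_cell, config.seed + 1)

    pooled = {
        "iei": (_pooled_ieis(eq_v), _pooled_ieis(eq_t)),
        "amplitude": (eq_v.accepted()["amplitude_pA"].to_numpy(),
                      eq_t.accepted()["amplitude_pA"].to_numpy()),
        "rise_time": (eq_v.accepted()["rise_ms"].to_numpy(),
                      eq_t.accepted()["rise_ms"].to_numpy()),
    }
    for metric, (xv, xt) in pooled.items():
        D, p = ks_two_sample(xv, xt)
        report.ks[metric] = {"D": D, "p": p,
                             "flag": bool(p < config.ks_alpha and D > config.ks_min_D)}

    # cell-average comparisons; frequency uses the full accepted tables
    def _cell_means(tab: EventTable, col: str) -> np.ndarray:
        return tab.accepted().groupby("cell_id")[col].mean().to_numpy()

    mw_inputs = {
        "amplitude": (_cell_means(eq_v, "amplitude_pA"), _cell_means(eq_t, "amplitude_pA")),
        "rise_time": (_cell_means(eq_v, "rise_ms"), _cell_means(eq_t, "rise_ms")),
    }
    if recording_durations is not None:
        freqs = {}
        for name, tab in (("vehicle", vehicle), ("treated", treated)):
            counts = tab.accepted().groupby("cell_id").size()
            freqs[name] = np.array([
                counts[c] / recording_durations[c] for c in counts.index])
        mw_inputs["frequency"] = (freqs["vehicle"], freqs["treated"])
    for metric, (xv, xt) in mw_inputs.items():
        U, p = mann_whitney(xv, xt)
        report.mann_whitney[metric] = {"U": U, "p": p,
                                       "flag": bool(p < config.mw_alpha)}

    # fast:slow contingency at the configured or data-selected cutoff
    rise_v = eq_v.accepted()["rise_ms"].to_numpy()
    rise_t = eq_t.accepted()["rise_ms"].to_numpy()
    tau = config.cutoff_ms
    if tau is None:
        tau_max = float(max(rise_v.max(), rise_t.max())) + 0.1
        try:
            sel = select_cutoff(
                ratio_curve(rise_v, tau_max=tau_max, group="vehicle"),
                ratio_curve(rise_t, tau_max=tau_max, group="treated"),
                tolerance=config.cutoff_tolerance)
            tau = sel.tau_ms
            if sel.low_confidence:
                # a low-confidence selection would split a mode, not the
                # valley; fall back to the configured fixed cutoff
                tau = config.fallback_cutoff_ms
                report.notes.append(
                    f"data-driven cutoff low confidence ({sel.note}); "
                    f"using fallback {tau} ms")
        except NoCutoffError as exc:
            tau = config.fallback_cutoff_ms
            report.notes.append(
                f"no fast/slow cutoff found ({exc}); using fallback {tau} ms")
    if tau is not None:
        counts = classify_and_count({"vehicle": eq_v, "treated": eq_t}, tau)
        p = fisher_exact(counts)
        report.fisher = {
            "p": p, "flag": bool(p < config.fisher_alpha), "cutoff_ms": tau,
            "counts": {c: counts.table.loc[c].to_dict() for c in counts.table.index},
        }

    if recording_durations is not None:
        merged = EventTable(pd.concat([vehicle.frame, treated.frame],
                                      ignore_index=True))
        _, group_table = summarize_cells(merged, recording_durations)
        report.cell_summary = group_table
    return report
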