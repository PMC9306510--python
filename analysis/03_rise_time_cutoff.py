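"""Fast/slow cutoff selection: curves, derivatives and the chosen value.

Builds the slow:fast ratio curves r_sf(tau_c) = (n(rise > tau_c) + 1) /
(n(rise <= tau_c) + 1) on the 0.1 ms grid for both arms, their log-scale
derivatives, and runs the cutoff search twice: on the generator's true
rise times (clean bimodality, modes at 1 and 3 ms) and on the measured
rise times from the pipeline run.  Dumps the curves as CSV for plotting.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from psckit.calibrate import bimodal_rise_samples
from psckit.classify import (NoCutoffError, log_derivative, ratio_curve,
                             select_cutoff)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def report_selection(label, rise_a, rise_b):
    tau_max = float(max(np.max(rise_a), np.max(rise_b))) + 0.1
    curve_a = ratio_curve(rise_a, tau_max=tau_max, group="vehicle")
    curve_b = ratio_curve(rise_b, tau_max=tau_max, group="treated")
    try:
        sel = select_cutoff(curve_a, curve_b)
        flag = " (low confidence)" if sel.low_confidence else ""
        print(f"{label}: cutoff {sel.tau_ms:.1f} ms{flag}")
    except NoCutoffError as exc:
        print(f"{label}: no cutoff ({exc})")
        sel = None
    n = min(curve_a.tau_grid.size, curve_b.tau_grid.size)
    return pd.DataFrame({
        "tau_ms": curve_a.tau_grid[:n],
        "ratio_vehicle": curve_a.ratio[:n],
        "ratio_treated": curve_b.ratio[:n],
        "deriv_vehicle": log_derivative(curve_a)[:n],
        "deriv_treated": log_derivative(curve_b)[:n],
    }), sel


def main() -> None:
    rng = np.random.default_rng(11)
    truth, _ = report_selection(
        "generator rise times (n=2000/arm)",
        bimodal_rise_samples(rng, 2000, fast_fraction=0.60),
        bimodal_rise_samples(rng, 2000, fast_fraction=0.70))
    truth.to_csv(RESULTS / "cutoff_curves_ground_truth.csv", index=False)

    events_dir = RESULTS / "pipeline"
    if (events_dir / "events_vehicle.csv").exists():
        rises = {}
        for arm in ("vehicle", "treated"):
            df = pd.read_csv(events_dir / f"events_{arm}.csv")
            rises[arm] = df.loc[df["accepted"], "rise_ms"].to_numpy()
        measured, _ = report_selection(
            f"measured rise times ({len(rises['vehicle'])}/"
            f"{len(rises['treated'])} accepted events)",
            rises["vehicle"], rises["treated"])
        measured.to_csv(RESULTS / "cutoff_curves_measured.csv", index=False)
    else:
        print("no pipeline events found; run 02_run_pipeline.py first")


if __name__ == "__main__":
    main()
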