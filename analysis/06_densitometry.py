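"""Densitometry workflow on synthetic grey values, plus the published checks.

Generates grey-value measurements for the six hippocampal subfields on
the 4 mice x 3 vibratome x 2 cryotome hierarchy (region means chosen to
produce ROD values at the scale of the published group table), runs the
hierarchical averaging and per-region Student's t comparisons, and then
reproduces the two published-number checks that need no simulation: the
CA3 stratum-oriens relative percentage (0.125/0.164 -> 76%) and the
fast/slow contingency Fisher tests.
"""

import argparse
from pathlib import Path

import pandas as pd

from psckit.rod import compare_regions, relative_percent
from psckit.simulate import generate_grey_values
from psckit.stats import fisher_exact

RESULTS = Path(__file__).resolve().parent.parent / "results"

# grey values whose RODs sit at the scale of the published group means
CONTROL_MEANS = {"DG-ML": 92.0, "CA1-so": 98.0, "CA1-sr": 108.0,
                 "CA1-slm": 97.0, "CA3-so": 79.0, "CA3-sr": 78.0}
TREATED_MEANS = {"DG-ML": 102.0, "CA1-so": 106.0, "CA1-sr": 117.0,
                 "CA1-slm": 97.0, "CA3-so": 64.0, "CA3-sr": 80.0}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    frames = [
        generate_grey_values(CONTROL_MEANS, background_mean=8.0, noise_sd=4.0,
                             condition="aCSF", seed=args.seed, mouse_sd=6.0),
        generate_grey_values(TREATED_MEANS, background_mean=8.0, noise_sd=4.0,
                             condition="treated", seed=args.seed + 1,
                             mouse_sd=6.0),
    ]
    table = compare_regions(pd.concat(frames, ignore_index=True),
                            control="aCSF", treated="treated")
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "densitometry.csv", index=False)
    print(table.round(3).to_string(index=False))

    print("\npublished-number checks:")
    print(f"  CA3-so percent from printed means 0.125/0.164: "
          f"{relative_percent(0.125, 0.164)}%")
    print(f"  Fisher p, spontaneous IPSC fast/slow counts: "
          f"{fisher_exact([[2734, 1619], [3110, 1787]]):.3f}")
    print(f"  Fisher p, miniature IPSC fast/slow counts:   "
          f"{fisher_exact([[2777, 1864], [5190, 2235]]):.2e}")


if __name__ == "__main__":
    main()
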