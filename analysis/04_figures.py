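#!/usr/bin/env python
"""Render the report figures from the validation run.

Produces, under results/figures/: the histogram of per-cycle
(temperature-estimate minus surge-day) differences, a sample of
per-cycle temperature plots with the surge day marked by a vertical
line and the estimated ovulation day by a dot, and luteal-profile
galleries grouped by amplitude, rise and fluctuation class.
"""

import argparse
from pathlib import Path

from bbtval.cycle_model import read_cycles
from bbtval.report import render_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--validation-dir", type=Path, default=Path("results/validation"))
    parser.add_argument("--cycles", type=Path, default=Path("results/cohort/cycles.csv"))
    parser.add_argument("--outdir", type=Path, default=Path("results/figures"))
    parser.add_argument("--max-cycle-plots", type=int, default=12)
    args = parser.parse_args()

    cycles = read_cycles(args.cycles)
    written = render_report(args.validation_dir, cycles, args.outdir, args.max_cycle_plots)
    print(f"wrote {len(written)} figures to {args.outdir}")


if __name__ == "__main__":
    main()
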