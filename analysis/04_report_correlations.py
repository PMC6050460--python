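#!/usr/bin/env python
"""Percent-change and PET-to-histology correlation report.

From results/suvr.csv and results/histology.csv, computes each method's mean
percent SUVR change versus no correction and the Pearson correlation of each
method's SUVR with both simulated histology measures (plus the
histology-histology pair), flagging significance at two-sided p < 0.01.
Writes results/percent_change.csv, results/correlations.csv and
results/summary.txt.
"""

from pathlib import Path

from pvcsim.pipeline import stage_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    pct, corr = stage_report(
        results / "suvr.csv", results / "histology.csv", results
    )
    print((results / "summary.txt").read_text())


if __name__ == "__main__":
    main()
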