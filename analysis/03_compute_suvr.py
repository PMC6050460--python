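#!/usr/bin/env python
"""Sample GM-only VOI and cerebellar-GM SUVRs from the corrected images.

The target VOI is intersected with the GM mask before sampling (mimicking a
pathology analysis confined to grey matter) and each method's SUVR uses the
equivalently corrected cerebellar-GM reference.  Writes results/suvr.csv.
"""

from pathlib import Path

from pvcsim.pipeline import RunConfig, stage_suvr

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = RunConfig.from_yaml(ROOT / "results" / "config.yaml")
    table = stage_suvr(
        ROOT / "scratch" / "cohort",
        ROOT / "scratch" / "corrected",
        ROOT / "results" / "suvr.csv",
        config,
    )
    wide = table.pivot(index="subject_id", columns="method", values="suvr")
    print(wide.round(3).to_string())
    print(f"\n{len(table)} SUVR records -> results/suvr.csv")


if __name__ == "__main__":
    main()
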