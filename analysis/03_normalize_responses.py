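"""Normalize the raw screen against in-plate vehicle controls.

Writes the long-format normalized table and compares the realized control
SD of each continuous endpoint with its configured value — the simulator's
noise calibration should land within sampling error.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, panel_config

from planartox import schema as sc
from planartox.normalization import normalize_continuous
from planartox.pipeline import stage_normalize


def main() -> None:
    cfg = panel_config()
    raw = pd.read_csv(RESULTS / "raw_screen.csv")
    normalized = stage_normalize(cfg, raw)
    normalized.to_csv(RESULTS / "normalized.csv", index=False)
    print(f"normalized table: {len(normalized)} per-worm values")

    by_name = sc.schema_by_name(cfg.schema())
    print("\ncontrol SD calibration (adult, day 7):")
    print(f"{'endpoint':28s} {'configured':>10s} {'realized':>9s}")
    cont = raw[(raw["kind"] == "continuous") & (raw["worm_type"] == "adult")
               & (raw["day"] == 7) & (raw["concentration_uM"] == 0.0)]
    for endpoint, grp in cont.groupby("endpoint"):
        spec = by_name[endpoint]
        vals = []
        for plate, g in grp.groupby("plate"):
            m = g["value"].median()
            vals += [normalize_continuous(v, m, spec.rule) for v in g["value"]]
        print(f"{endpoint:28s} {spec.control_sd[('adult', 7)]:10.1f} "
              f"{np.std(vals):9.1f}")


if __name__ == "__main__":
    main()
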