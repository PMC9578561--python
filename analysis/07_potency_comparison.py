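"""Compare behavioral potency with enzymatic potency.

Ranks the inhibitor chemicals by their most sensitive adult BMC and by
their IC80 and reports Spearman's correlation with an exact permutation
p-value — the same comparison used to ask whether AChE inhibition predicts
behavioral toxicity.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from planartox.barcode_cluster import rank_and_correlate
from planartox.pipeline import most_sensitive_table


def main() -> None:
    bmc_table = pd.read_csv(RESULTS / "bmc_table.csv")
    ic_table = pd.read_csv(RESULTS / "ic_table.csv").set_index("chemical")
    bmc_adult = most_sensitive_table(bmc_table, "adult")
    shared = sorted(set(bmc_adult) & set(ic_table.index))
    if len(shared) < 3:
        print(f"only {len(shared)} chemicals with both measures; "
              "rank comparison needs at least 3")
        return
    potency_bmc = {c: bmc_adult[c] for c in shared}
    potency_ic80 = {c: float(ic_table.loc[c, "IC80_uM"]) for c in shared}
    out = rank_and_correlate(potency_bmc, potency_ic80)
    print("chemical        BMC_adult   IC80   rank_BMC rank_IC80")
    for c, ra, rb in zip(out["chemicals"], out["ranks_a"], out["ranks_b"]):
        print(f"{c:14s} {potency_bmc[c]:9.3f} {potency_ic80[c]:7.3f} "
              f"{ra:8.1f} {rb:9.1f}")
    print(f"Spearman rho {out['spearman_rho']:.3f}, "
          f"exact p {out['p_value']:.3f} (n={len(shared)})")


if __name__ == "__main__":
    main()
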