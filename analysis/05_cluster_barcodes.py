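"""Phenotypic barcoding, filtering, and Ward/Jaccard clustering.

Binarizes every chemical concentration against the battery's benchmark
responses, filters to rows/columns with activity (dropping fully lethal
concentrations), clusters with binary distance and the ward.D2 criterion,
and writes barcode matrices, cluster assignments, and endpoint-class links.
Concentrations of the same chemical should co-cluster.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, panel_config

from planartox.barcode_cluster import ward_cluster
from planartox.pipeline import stage_barcode, stage_class_links


def main() -> None:
    cfg = panel_config()
    raw = pd.read_csv(RESULTS / "raw_screen.csv")
    normalized = pd.read_csv(RESULTS / "normalized.csv")
    bmc_table = pd.read_csv(RESULTS / "bmc_table.csv")

    for wt in cfg.design.worm_types:
        bc = stage_barcode(cfg, raw, normalized, wt)
        bc.matrix.astype(int).to_csv(RESULTS / f"barcode_{wt}.csv")
        print(f"{wt}: barcode {bc.matrix.shape[0]} rows x "
              f"{bc.matrix.shape[1]} measures "
              f"({len(bc.lethal_rows)} fully lethal rows removed)")
        if len(bc.matrix) >= cfg.k_clusters:
            res = ward_cluster(bc, cfg.k_clusters)
            res.assignments().to_csv(RESULTS / f"clusters_{wt}.csv")
            comp = res.assignments().groupby(
                res.assignments().index.str.split("@").str[0])
            print("  cluster spread per chemical:",
                  {c: sorted(set(v)) for c, v in comp})
        links = stage_class_links(bmc_table, wt)
        links.to_csv(RESULTS / f"class_links_{wt}.csv", index=False)
        print("  class links:", {c: list(g["endpoint_class"])
                                 for c, g in links.groupby("chemical")})


if __name__ == "__main__":
    main()
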