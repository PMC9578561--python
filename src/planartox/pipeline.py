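"""End-to-end stages: simulate -> normalize -> BMC -> barcode -> cluster.

Each stage is a plain function over DataFrames so the command-line interface,
the analysis drivers and the tests all share one code path.  Seeds for the
per-measure bootstraps are derived deterministically from the master seed and
the (chemical, measure) identity, so adding a chemical never perturbs the
results of another.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import schema as sc
from .bmc import (BMCResult, BMRScan, ConcentrationResponse, child_seed,
                  estimate_bmc, estimate_bmcs, most_sensitive_bmc)
from .barcode_cluster import (PhenotypicBarcode, binarize, filter_barcode,
                              ward_cluster, endpoint_class_links)
from .config import RunConfig, manual_bmr_for
from .normalization import build_concentration_responses, normalize_screen
from .synthetic_screen import simulate_screen

log = logging.getLogger("planartox")

BMC_COLUMNS = ["chemical", "worm_type", "day", "endpoint", "direction",
               "outcome_measure", "bmr", "bmc_median_uM", "bmc_p5_uM",
               "bmc_p95_uM", "status", "censored_fraction"]


def stage_simulate(cfg: RunConfig) -> pd.DataFrame:
    raw = simulate_screen(cfg.design, cfg.truth, cfg.seed,
                          chemicals=cfg.chemicals or None)
    log.info("simulate: %d raw observations, config %s", len(raw),
             cfg.config_hash())
    return raw


def stage_normalize(cfg: RunConfig, raw: pd.DataFrame) -> pd.DataFrame:
    normalized = normalize_screen(raw, cfg.schema())
    log.info("normalize: %d normalized continuous observations", len(normalized))
    return normalized


def concentration_responses(cfg: RunConfig, raw: pd.DataFrame,
                            normalized: pd.DataFrame, chemical: str,
                            worm_type: str) -> dict[sc.OutcomeMeasure, ConcentrationResponse]:
    return build_concentration_responses(raw, normalized, cfg.schema(),
                                         chemical, worm_type, cfg.masks)


def stage_bmc(cfg: RunConfig, raw: pd.DataFrame,
              normalized: pd.DataFrame) -> pd.DataFrame:
    """BMC table over every chemical x worm type x outcome measure.

    One BMR is selected per outcome measure from all chemicals' responses;
    each chemical then gets its own final bootstrap BMC at that BMR.
    """
    by_name = sc.schema_by_name(cfg.schema())
    chemicals = cfg.chemicals or sorted(raw["chemical"].unique())
    rows = []
    for worm_type in cfg.design.worm_types:
        per_chem = {chemical: concentration_responses(cfg, raw, normalized,
                                                      chemical, worm_type)
                    for chemical in chemicals}
        measures = sorted({m for resp in per_chem.values() for m in resp},
                          key=lambda m: (m.endpoint, m.day, m.direction))
        for measure in measures:
            chems = [c for c in chemicals if measure in per_chem[c]]
            crs = [per_chem[c][measure] for c in chems]
            spec = by_name[measure.endpoint]
            scan = BMRScan.for_class(spec.scan, B_select=cfg.B_select,
                                     B_final=cfg.B_final,
                                     plateau_tol=cfg.plateau_tol)
            seed = child_seed(cfg.seed, worm_type, measure.label)
            manual = manual_bmr_for(measure, cfg.manual_bmrs)
            results, _sel = estimate_bmcs(crs, scan, seed, manual_bmr=manual)
            for chemical, result in zip(chems, results):
                rows.append((chemical, worm_type, measure.day,
                             measure.endpoint, measure.direction,
                             measure.label, result.bmr, result.median_uM,
                             result.p5_uM, result.p95_uM, result.status,
                             result.censored_fraction))
    table = pd.DataFrame(rows, columns=BMC_COLUMNS)
    log.info("bmc: %d measure estimates (%d active)", len(table),
             int((table["status"] == "active").sum()))
    return table


def stage_barcode(cfg: RunConfig, raw: pd.DataFrame, normalized: pd.DataFrame,
                  worm_type: str) -> PhenotypicBarcode:
    """Filtered phenotypic barcode for one worm type, all chemicals pooled."""
    measures = sc.enumerate_measures(cfg.schema(), worm_type)
    bmr_table = {}
    for m in measures:
        manual = manual_bmr_for(m, cfg.manual_bmrs)
        spec = sc.schema_by_name(cfg.schema())[m.endpoint]
        bmr_table[m] = manual if manual is not None else spec.bmr[
            (m.worm_type, m.day, m.direction)]
    chemicals = cfg.chemicals or sorted(raw["chemical"].unique())
    mats, lethal = [], []
    for chemical in chemicals:
        responses = concentration_responses(cfg, raw, normalized, chemical,
                                            worm_type)
        bc = binarize(responses, bmr_table, chemical)
        mats.append(bc.matrix)
        lethal.extend(bc.lethal_rows)
    matrix = pd.concat(mats).fillna(False).astype(bool) if mats else pd.DataFrame()
    barcode = filter_barcode(PhenotypicBarcode(matrix, lethal))
    log.info("barcode[%s]: %d rows x %d measures retained", worm_type,
             *barcode.matrix.shape)
    return barcode


def bmc_results_for(table: pd.DataFrame, chemical: str, worm_type: str
                    ) -> tuple[list[BMCResult], list[sc.OutcomeMeasure]]:
    sel = table[(table["chemical"] == chemical)
                & (table["worm_type"] == worm_type)]
    results, measures = [], []
    for _, r in sel.iterrows():
        results.append(BMCResult(r["outcome_measure"], r["direction"],
                                 r["bmr"], r["bmc_median_uM"], r["bmc_p5_uM"],
                                 r["bmc_p95_uM"], r["status"],
                                 r["censored_fraction"]))
        measures.append(sc.OutcomeMeasure(r["endpoint"], worm_type,
                                          int(r["day"]), r["direction"]))
    return results, measures


def stage_class_links(table: pd.DataFrame, worm_type: str) -> pd.DataFrame:
    frames = []
    for chemical in sorted(table["chemical"].unique()):
        results, measures = bmc_results_for(table, chemical, worm_type)
        frames.append(endpoint_class_links(results, measures, chemical))
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["chemical", "endpoint_class"]))


def most_sensitive_table(table: pd.DataFrame, worm_type: str) -> dict[str, float]:
    """Most sensitive (lowest active median) BMC per chemical."""
    out = {}
    for chemical in sorted(table["chemical"].unique()):
        results, _ = bmc_results_for(table, chemical, worm_type)
        best = most_sensitive_bmc(results)
        if best is not None:
            out[chemical] = best.median_uM
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Full chain on one configuration; returns all intermediate tables."""
    raw = stage_simulate(cfg)
    normalized = stage_normalize(cfg, raw)
    bmc_table = stage_bmc(cfg, raw, normalized)
    out = {"raw": raw, "normalized": normalized, "bmc_table": bmc_table,
           "barcodes": {}, "clusters": {}, "class_links": {}}
    for worm_type in cfg.design.worm_types:
        barcode = stage_barcode(cfg, raw, normalized, worm_type)
        out["barcodes"][worm_type] = barcode
        if len(barcode.matrix) >= cfg.k_clusters:
            out["clusters"][worm_type] = ward_cluster(barcode, cfg.k_clusters)
        out["class_links"][worm_type] = stage_class_links(bmc_table, worm_type)
    return out
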