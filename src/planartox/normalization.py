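"""Normalization of raw per-worm observations into direction-split responses.

Continuous endpoint values are normalized against the median of the in-plate
vehicle controls (per plate, per day, per worm type) using the endpoint's
rule — subtract-and-scale, divide-and-scale, or plain subtraction for the
locomotor-burst endpoints, which keep their natural units.  Binary endpoints
are pooled across replicates into incidence counts; the control-normalized
variants (stickiness, scrunching) subtract the in-plate vehicle incidence,
and negative incidence rates are clamped to zero because only increases in
abnormal activity are scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema as sc
from .bmc import ConcentrationResponse

NORMALIZED_COLUMNS = ["chemical", "worm_type", "day", "endpoint", "kind",
                      "concentration_uM", "plate", "replicate",
                      "normalized_value"]


def normalize_continuous(value: float, vehicle_median: float, rule: str) -> float:
    """Apply one continuous normalization rule against the vehicle median."""
    if not math.isfinite(vehicle_median):
        raise ValueError("vehicle median must be finite")
    if rule == sc.SUBTRACT_X100:
        return (value - vehicle_median) * 100.0
    if rule == sc.DIVIDE_X100_MINUS100:
        if vehicle_median == 0:
            raise ZeroDivisionError("vehicle median is 0; endpoint unnormalizable")
        return (value / vehicle_median) * 100.0 - 100.0
    if rule == sc.SUBTRACT_RAW:
        return value - vehicle_median
    raise ValueError(f"unknown continuous rule {rule!r}")


def denormalize_continuous(norm: float, vehicle_median: float, rule: str) -> float:
    """Inverse of :func:`normalize_continuous` (round-trip identity)."""
    if rule == sc.SUBTRACT_X100:
        return norm / 100.0 + vehicle_median
    if rule == sc.DIVIDE_X100_MINUS100:
        return (norm + 100.0) / 100.0 * vehicle_median
    if rule == sc.SUBTRACT_RAW:
        return norm + vehicle_median
    raise ValueError(f"unknown continuous rule {rule!r}")


def aggregate_incidence(labels) -> dict[str, int]:
    """Pooled incidence counts; missing labels are excluded from the total."""
    arr = np.asarray(labels, dtype=float)
    ok = np.isfinite(arr)
    return {"affected": int(np.nansum(arr[ok])), "total": int(ok.sum())}


def normalize_incidence(condition: dict[str, int], control: dict[str, int] | None,
                        rule: str) -> float:
    """Incidence rate, optionally control-normalized, clamped at zero."""
    if condition["total"] <= 0:
        raise ValueError("condition total must be positive")
    rate = condition["affected"] / condition["total"]
    if rule == sc.INCIDENCE:
        return rate
    if rule == sc.INCIDENCE_CONTROL_NORM:
        if control is None or control["total"] <= 0:
            raise ValueError("control counts required for control-normalized rule")
        return max(0.0, rate - control["affected"] / control["total"])
    raise ValueError(f"unknown incidence rule {rule!r}")


def normalize_screen(raw: pd.DataFrame, schema: list[sc.EndpointSpec]) -> pd.DataFrame:
    """Per-worm normalized values for all continuous endpoints.

    Vehicle medians are computed per plate (which fixes worm type, day and
    replicate).  Plates where a divide-rule vehicle median is zero are
    flagged by dropping that endpoint-plate with a NaN marker row.
    Binary endpoints pass through unchanged (their pooling happens in
    :func:`build_concentration_responses`).
    """
    by_name = sc.schema_by_name(schema)
    cont = raw[raw["kind"] == "continuous"].copy()
    out = []
    for (chem, wt, day, endpoint, plate), grp in cont.groupby(
            ["chemical", "worm_type", "day", "endpoint", "plate"], sort=False):
        spec = by_name[endpoint]
        veh = grp.loc[grp["concentration_uM"] == 0.0, "value"]
        veh = veh[np.isfinite(veh)]
        if veh.empty:
            continue
        m = float(veh.median())
        if spec.rule == sc.DIVIDE_X100_MINUS100 and m == 0.0:
            continue  # unnormalizable for this plate
        g = grp[grp["concentration_uM"] > 0.0]
        vals = np.array([normalize_continuous(v, m, spec.rule)
                         for v in g["value"].to_numpy(float)])
        out.append(pd.DataFrame({
            "chemical": chem, "worm_type": wt, "day": day,
            "endpoint": endpoint, "kind": "continuous",
            "concentration_uM": g["concentration_uM"].to_numpy(float),
            "plate": plate, "replicate": g["replicate"].to_numpy(),
            "normalized_value": vals,
        }))
    if not out:
        return pd.DataFrame(columns=NORMALIZED_COLUMNS)
    return pd.concat(out, ignore_index=True)[NORMALIZED_COLUMNS]


def pooled_control_rate(raw: pd.DataFrame, endpoint: str, chemical: str,
                        worm_type: str, day: int) -> float:
    """Pooled vehicle incidence across replicates for one binary endpoint."""
    sel = raw[(raw["endpoint"] == endpoint) & (raw["chemical"] == chemical)
              & (raw["worm_type"] == worm_type) & (raw["day"] == day)
              & (raw["concentration_uM"] == 0.0)]
    counts = aggregate_incidence(sel["value"].to_numpy(float))
    return counts["affected"] / counts["total"] if counts["total"] else 0.0


@dataclass(frozen=True)
class MaskRule:
    """Declarative exclusion: mask a concentration or drop a replicate."""

    chemical: str
    endpoint: str
    concentration_uM: float | None = None
    replicate: int | None = None


def build_concentration_responses(
        raw: pd.DataFrame, normalized: pd.DataFrame,
        schema: list[sc.EndpointSpec], chemical: str, worm_type: str,
        masks: list[MaskRule] = ()) -> dict[sc.OutcomeMeasure, ConcentrationResponse]:
    """Direction-split per-measure concentration responses for one chemical.

    Continuous measures carry per-worm normalized values; binary measures
    carry per-worm 0/1 labels plus the pooled vehicle rate for the
    control-normalized rules.  Masked concentrations and excluded replicates
    from ``masks`` are applied here.
    """
    out: dict[sc.OutcomeMeasure, ConcentrationResponse] = {}
    my_masks = [m for m in masks if m.chemical == chemical]
    for spec in schema:
        if worm_type not in spec.worm_types:
            continue
        conc_masks = {m.concentration_uM for m in my_masks
                      if m.endpoint == spec.name and m.concentration_uM is not None}
        rep_excl = {m.replicate for m in my_masks
                    if m.endpoint == spec.name and m.replicate is not None}
        for day in spec.days:
            if spec.kind == "binary":
                src = raw[(raw["chemical"] == chemical)
                          & (raw["worm_type"] == worm_type)
                          & (raw["day"] == day) & (raw["endpoint"] == spec.name)
                          & (raw["concentration_uM"] > 0.0)]
            else:
                src = normalized[(normalized["chemical"] == chemical)
                                 & (normalized["worm_type"] == worm_type)
                                 & (normalized["day"] == day)
                                 & (normalized["endpoint"] == spec.name)]
            if rep_excl:
                src = src[~src["replicate"].isin(rep_excl)]
            if src.empty:
                continue
            concs = np.array(sorted(src["concentration_uM"].unique()))
            col = "value" if spec.kind == "binary" else "normalized_value"
            samples = [src.loc[src["concentration_uM"] == c, col].to_numpy(float)
                       for c in concs]
            keep = [i for i, s in enumerate(samples)
                    if np.isfinite(s).sum() > 0]
            if not keep:
                continue
            concs = concs[keep]
            samples = [samples[i] for i in keep]
            ctrl = 0.0
            if spec.rule == sc.INCIDENCE_CONTROL_NORM:
                ctrl = pooled_control_rate(raw, spec.name, chemical, worm_type, day)
            for direction in spec.directions:
                m = sc.OutcomeMeasure(spec.name, worm_type, day, direction)
                out[m] = ConcentrationResponse(
                    measure=m.label, concentrations=concs, samples=samples,
                    kind=spec.kind, direction=direction, control_rate=ctrl,
                    masked=frozenset(c for c in conc_masks if c in concs),
                )
    return out


def split_directions(cr: ConcentrationResponse, directions) -> list[ConcentrationResponse]:
    """One response object per allowed direction, sharing the signed samples."""
    return [ConcentrationResponse(cr.measure, cr.concentrations, cr.samples,
                                  cr.kind, d, cr.control_rate, cr.masked)
            for d in directions]
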