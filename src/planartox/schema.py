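"""Default endpoint schema for the planarian screening battery.

The battery scores each worm on a mix of binary morphological endpoints
(lethality, abnormal body shape, stickiness, abnormal eye regeneration,
failure to scrunch) and continuous behavioral endpoints extracted from the
phototaxis / thermotaxis / noxious-heat assays.  Every endpoint is assayed on
day 7 and/or day 12 of exposure, in adult (intact) and/or regenerating
(tail-piece) planarians, and may respond in one or both directions.

An *outcome measure* is one (endpoint, day, direction) combination for a
given worm type.  Enumerating the default schema yields exactly 70 adult and
71 regenerating outcome measures; the difference is eye regeneration, which
only exists for regenerating animals.

Control standard deviations (``control_sd``, in normalized response units)
and default benchmark responses (``bmr``) are the published reference values
for this battery and seed both the synthetic-screen noise model and the
barcode binarization defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

ADULT = "adult"
REGENERATING = "regenerating"
WORM_TYPES = (ADULT, REGENERATING)
DAYS = (7, 12)

# normalization rules
SUBTRACT_X100 = "subtract_x100"            # (v - vehicle_median) * 100
DIVIDE_X100_MINUS100 = "divide_x100_minus100"  # (v / vehicle_median) * 100 - 100
SUBTRACT_RAW = "subtract_raw"              # v - vehicle_median (no scaling)
INCIDENCE = "incidence"                    # affected / total
INCIDENCE_CONTROL_NORM = "incidence_control_normalized"  # max(0, rate - control rate)

INCIDENCE_RULES = frozenset({INCIDENCE, INCIDENCE_CONTROL_NORM})

# BMR-scan classes (threshold grids used by the benchmark-response scan)
SCAN_STANDARD = "standard"        # 5..95 step 5
SCAN_EXTENDED = "extended"        # 5..150 step 5 (high-variance endpoints)
SCAN_BURST_TOTAL = "burst_total"  # 1..30 step 1 (small response range)
SCAN_BURST_RATIO = "burst_ratio"  # 0.5..15 step 0.5


@dataclass(frozen=True)
class OutcomeMeasure:
    """One endpoint x day x direction combination for one worm type."""

    endpoint: str
    worm_type: str
    day: int
    direction: str  # '+' or '-'

    @property
    def label(self) -> str:
        return f"{self.endpoint}_d{self.day}({self.direction})"


@dataclass(frozen=True)
class EndpointSpec:
    """Declarative description of one endpoint in the battery.

    ``control_sd`` maps (worm_type, day) to the SD of the normalized control
    response; ``bmr`` maps (worm_type, day, direction) to the default
    benchmark response on the same scale.  Incidence endpoints use percent
    units (% of worms affected).
    """

    name: str
    kind: str  # 'binary' | 'continuous'
    rule: str
    days: tuple[int, ...]
    directions: tuple[str, ...]
    worm_types: tuple[str, ...] = WORM_TYPES
    control_sd: Mapping[tuple[str, int], float] = field(default_factory=dict)
    bmr: Mapping[tuple[str, int, str], float] = field(default_factory=dict)
    scan: str = SCAN_STANDARD
    baseline: float = 1.0  # raw-scale control baseline used by the simulator
    control_rate: float = 0.0  # control incidence (binary endpoints only)

    def __post_init__(self) -> None:
        if self.kind == "binary" and self.rule not in INCIDENCE_RULES:
            raise ValueError(f"binary endpoint {self.name} needs an incidence rule")
        if self.kind == "continuous" and self.rule in INCIDENCE_RULES:
            raise ValueError(f"continuous endpoint {self.name} cannot use {self.rule}")
        if not self.directions:
            raise ValueError(f"endpoint {self.name} has no directions")

    def measures(self, worm_type: str) -> list[OutcomeMeasure]:
        if worm_type not in self.worm_types:
            return []
        return [
            OutcomeMeasure(self.name, worm_type, day, d)
            for day in self.days
            for d in self.directions
        ]


def _sd(adult_d7=None, adult_d12=None, regen_d7=None, regen_d12=None):
    out = {}
    for (wt, day), v in {
        (ADULT, 7): adult_d7,
        (ADULT, 12): adult_d12,
        (REGENERATING, 7): regen_d7,
        (REGENERATING, 12): regen_d12,
    }.items():
        if v is not None:
            out[(wt, day)] = float(v)
    return out


def _bmr_both(adult_d7=None, adult_d12=None, regen_d7=None, regen_d12=None):
    """BMR map for endpoints scored in both directions; values are (+, -) pairs."""
    out = {}
    for (wt, day), pair in {
        (ADULT, 7): adult_d7,
        (ADULT, 12): adult_d12,
        (REGENERATING, 7): regen_d7,
        (REGENERATING, 12): regen_d12,
    }.items():
        if pair is not None:
            out[(wt, day, "+")] = float(pair[0])
            out[(wt, day, "-")] = float(pair[1])
    return out


def _bmr_single(direction, adult_d7=None, adult_d12=None, regen_d7=None, regen_d12=None):
    out = {}
    for (wt, day), v in {
        (ADULT, 7): adult_d7,
        (ADULT, 12): adult_d12,
        (REGENERATING, 7): regen_d7,
        (REGENERATING, 12): regen_d12,
    }.items():
        if v is not None:
            out[(wt, day, direction)] = float(v)
    return out


def _speed(name: str, sd, bmr) -> EndpointSpec:
    return EndpointSpec(
        name=name, kind="continuous", rule=SUBTRACT_X100, days=DAYS,
        directions=("+", "-"), control_sd=sd, bmr=bmr,
        scan=SCAN_EXTENDED, baseline=1.0,
    )


def default_schema() -> list[EndpointSpec]:
    """The full default battery (binary + continuous endpoints)."""
    return [
        # ---- binary endpoints (incidence, increase-only) ----
        EndpointSpec(
            "lethality", "binary", INCIDENCE, DAYS, ("+",),
            control_sd=_sd(1, 3, 0, 2),
            bmr=_bmr_single("+", 10, 20, 10, 15),
            control_rate=0.0,
        ),
        EndpointSpec(
            "body_shape", "binary", INCIDENCE, DAYS, ("+",),
            control_sd=_sd(2, 6, 6, 6),
            bmr=_bmr_single("+", 20, 25, 30, 25),
            control_rate=0.0,
        ),
        EndpointSpec(
            "stickiness", "binary", INCIDENCE_CONTROL_NORM, DAYS, ("+",),
            control_sd=_sd(26, 22, 18, 20),
            bmr=_bmr_single("+", 50, 50, 50, 50),
            control_rate=0.15,
        ),
        EndpointSpec(
            "eye_regeneration", "binary", INCIDENCE, (7,), ("+",),
            worm_types=(REGENERATING,),
            control_sd=_sd(regen_d7=12),
            bmr=_bmr_single("+", regen_d7=55),
            control_rate=0.05,
        ),
        EndpointSpec(
            "scrunching", "binary", INCIDENCE_CONTROL_NORM, (12,), ("+",),
            control_sd=_sd(adult_d12=11, regen_d12=13),
            bmr=_bmr_single("+", adult_d12=25, regen_d12=50),
            control_rate=0.05,
        ),
        # ---- continuous endpoints ----
        _speed("speed_dark1_1",
               _sd(58, 51, 37, 51),
               _bmr_both((90, 35), (85, 45), (60, 35), (90, 60))),
        _speed("speed_dark1_2",
               _sd(62, 54, 37, 54),
               _bmr_both((110, 90), (90, 45), (60, 40), (100, 60))),
        _speed("speed_green1",
               _sd(60, 49, 34, 51),
               _bmr_both((70, 65), (85, 45), (50, 30), (85, 60))),
        _speed("speed_green2",
               _sd(64, 57, 37, 55),
               _bmr_both((60, 95), (95, 60), (60, 115), (115, 65))),
        _speed("speed_dark2_1",
               _sd(52, 47, 26, 46),
               _bmr_both((50, 70), (60, 30), (35, 30), (55, 50))),
        _speed("speed_dark2_2",
               _sd(57, 53, 29, 48),
               _bmr_both((60, 90), (50, 55), (40, 30), (100, 45))),
        _speed("speed_dark2_3",
               _sd(57, 53, 32, 48),
               _bmr_both((65, 75), (65, 35), (40, 30), (90, 45))),
        _speed("speed_dark2_4",
               _sd(57, 53, 33, 48),
               _bmr_both((65, 90), (80, 45), (45, 30), (95, 60))),
        _speed("speed_blue1",
               _sd(49, 49, 27, 47),
               _bmr_both((45, 60), (65, 55), (45, 20), (70, 45))),
        _speed("speed_blue2",
               _sd(47, 49, 33, 49),
               _bmr_both((65, 75), (60, 70), (50, 45), (80, 55))),
        EndpointSpec(
            "resting", "continuous", SUBTRACT_X100, DAYS, ("+", "-"),
            control_sd=_sd(40, 42, 31, 38),
            bmr=_bmr_both((65, 40), (45, 70), (35, 60), (50, 55)),
            scan=SCAN_EXTENDED, baseline=0.3,
        ),
        EndpointSpec(
            "phototaxis", "continuous", SUBTRACT_X100, DAYS, ("+", "-"),
            control_sd=_sd(27, 23, 19, 26),
            bmr=_bmr_both((35, 45), (30, 40), (30, 20), (35, 35)),
            baseline=-0.3,
        ),
        EndpointSpec(
            "wall_preference", "continuous", DIVIDE_X100_MINUS100, DAYS, ("-",),
            control_sd=_sd(23, 32, 32, 32),
            bmr=_bmr_single("-", 35, 25, 40, 35),
            baseline=0.6,
        ),
        EndpointSpec(
            "locomotor_bursts_total", "continuous", SUBTRACT_RAW, DAYS, ("+", "-"),
            control_sd=_sd(19, 21, 23, 22),
            bmr=_bmr_both((11, 7), (11, 6), (18, 11), (9, 6)),
            scan=SCAN_BURST_TOTAL, baseline=30.0,
        ),
        EndpointSpec(
            "locomotor_bursts_ratio", "continuous", SUBTRACT_RAW, DAYS, ("+", "-"),
            control_sd=_sd(2.5, 3, 3, 3),
            bmr=_bmr_both((5.5, 3.5), (5.5, 3.5), (5.5, 4), (4.5, 3.5)),
            scan=SCAN_BURST_RATIO, baseline=1.5,
        ),
        EndpointSpec(
            "thermotaxis", "continuous", DIVIDE_X100_MINUS100, (12,), ("-",),
            control_sd=_sd(adult_d12=22, regen_d12=23),
            bmr=_bmr_single("-", adult_d12=45, regen_d12=40),
            baseline=0.5,
        ),
        EndpointSpec(
            "noxious_rate", "continuous", SUBTRACT_X100, (12,), ("+", "-"),
            control_sd=_sd(adult_d12=17, regen_d12=20),
            bmr=_bmr_both(adult_d12=(35, 25), regen_d12=(35, 30)),
            baseline=2.0,
        ),
        EndpointSpec(
            "noxious_strength", "continuous", DIVIDE_X100_MINUS100, (12,), ("+", "-"),
            control_sd=_sd(adult_d12=45, regen_d12=48),
            bmr=_bmr_both(adult_d12=(50, 65), regen_d12=(50, 65)),
            baseline=5.0,
        ),
    ]


def enumerate_measures(schema: list[EndpointSpec], worm_type: str) -> list[OutcomeMeasure]:
    """All outcome measures for one worm type, in schema order."""
    out: list[OutcomeMeasure] = []
    for spec in schema:
        out.extend(spec.measures(worm_type))
    return out


def schema_by_name(schema: list[EndpointSpec]) -> dict[str, EndpointSpec]:
    return {s.name: s for s in schema}


# Endpoint-class map used for chemical x endpoint-class association summaries.
# Dark-period speed, resting and locomotor bursts pool into "Motility".
ENDPOINT_CLASSES: dict[str, str] = {
    "lethality": "Lethality",
    "body_shape": "Body shape",
    "stickiness": "Stickiness",
    "eye_regeneration": "Eye regeneration",
    "scrunching": "Scrunching",
    "speed_blue1": "Speed(B)",
    "speed_blue2": "Speed(B)",
    "speed_green1": "Speed(G)",
    "speed_green2": "Speed(G)",
    "phototaxis": "Phototaxis",
    "thermotaxis": "Thermotaxis",
    "wall_preference": "Wall preference",
    "noxious_rate": "Noxious stimuli",
    "noxious_strength": "Noxious stimuli",
    "speed_dark1_1": "Motility",
    "speed_dark1_2": "Motility",
    "speed_dark2_1": "Motility",
    "speed_dark2_2": "Motility",
    "speed_dark2_3": "Motility",
    "speed_dark2_4": "Motility",
    "resting": "Motility",
    "locomotor_bursts_total": "Motility",
    "locomotor_bursts_ratio": "Motility",
}
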