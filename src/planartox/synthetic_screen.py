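"""Synthetic screens, trajectories and enzyme-inhibition datasets.

The generator emulates the screening design — 48-well plates holding 8 worms
in vehicle control plus 8 worms at each of 5 concentrations, at least 3
replicate plates, 10 quarter-log or 5 semi-log concentrations, adult and
regenerating worm types assayed on days 7 and 12 — with Hill-shaped
concentration-response on the normalized scale and Gaussian/Bernoulli control
noise seeded from the battery's published control standard deviations.
Because every downstream stage (normalization, BMC estimation, barcoding,
clustering) consumes these tables, a screen simulated with known ground
truth makes the whole pipeline testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import schema as sc
from .behavior_endpoints import DEFAULT_SCHEDULE, LightSchedule, TrajectoryTrace

# The normalized control SD is measured on vehicle worms normalized against
# their own in-plate median (8 vehicle worms), which shrinks the SD by a
# factor of ~0.958 (Monte Carlo, n=8 Gaussians); pre-scale the per-worm noise
# so the post-normalization control SD matches the configured value.
_VEHICLE_NORM_SHRINKAGE = 0.958

RAW_COLUMNS = ["chemical", "worm_type", "day", "replicate", "plate", "well",
               "concentration_uM", "endpoint", "kind", "value"]


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def make_dilution_series(highest: float, n: int, step_log10: float) -> list[float]:
    """Log-spaced dilution series, reported ascending, 3 significant figures.

    ``step_log10`` of 0.25 gives quarter-log steps, 0.5 semi-log steps.
    """
    if highest <= 0 or n < 1 or step_log10 <= 0:
        raise ValueError("highest, n and step_log10 must be positive (n >= 1)")
    top = math.log10(highest)
    # A 3-sig-fig anchor like 31.6 stands for the grid value 10^1.5; snap to
    # the step grid when doing so reproduces the stated highest concentration.
    snapped = round(top / step_log10) * step_log10
    if _round_sig(10.0 ** snapped) == _round_sig(highest):
        top = snapped
    logs = top - step_log10 * np.arange(n - 1, -1, -1)
    return [_round_sig(10.0 ** v) for v in logs]


@dataclass(frozen=True)
class StudyDesign:
    """Plate-level layout of one screen."""

    worm_types: tuple[str, ...] = sc.WORM_TYPES
    days: tuple[int, ...] = sc.DAYS
    wells_per_condition: int = 8
    replicates: int = 3
    plate_capacity: int = 48
    n_concentrations: int = 10
    step_log10: float = 0.25
    highest_uM: float = 31.6
    endpoint_schema: tuple[sc.EndpointSpec, ...] = field(
        default_factory=lambda: tuple(sc.default_schema()))

    def __post_init__(self) -> None:
        per_plate = min(self.n_concentrations, 5)
        if self.wells_per_condition * (1 + per_plate) > self.plate_capacity:
            raise ValueError("plate layout exceeds plate capacity")
        if self.step_log10 <= 0:
            raise ValueError("step_log10 must be positive")

    @property
    def concentrations(self) -> list[float]:
        return make_dilution_series(self.highest_uM, self.n_concentrations,
                                    self.step_log10)

    @property
    def concentrations_per_plate(self) -> int:
        return min(self.n_concentrations, 5)

    @property
    def plates_per_replicate(self) -> int:
        return math.ceil(self.n_concentrations / self.concentrations_per_plate)


@dataclass(frozen=True)
class HillEffect:
    """Hill-shaped effect of one chemical on one outcome, normalized scale.

    For continuous endpoints ``rmax`` is the plateau shift in normalized
    response units and ``direction`` its sign; for binary endpoints ``rmax``
    is the plateau incidence increase on the probability scale (0..1).
    """

    rmax: float
    ec50_uM: float
    h: float
    direction: str = "+"

    def __post_init__(self) -> None:
        if self.ec50_uM <= 0 or self.h <= 0:
            raise ValueError("EC50 and Hill slope must be positive")

    def at(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.rmax * c ** self.h / (c ** self.h + self.ec50_uM ** self.h)


@dataclass
class GroundTruth:
    """Per chemical x endpoint x worm-type x day effects; absent = flat."""

    effects: dict[tuple[str, str, str, int], HillEffect] = field(default_factory=dict)

    def get(self, chemical: str, endpoint: str, worm_type: str, day: int) -> HillEffect | None:
        return self.effects.get((chemical, endpoint, worm_type, day))

    def set(self, chemical: str, endpoint: str, worm_type: str, day: int,
            effect: HillEffect) -> None:
        self.effects[(chemical, endpoint, worm_type, day)] = effect

    def chemicals(self) -> list[str]:
        return sorted({k[0] for k in self.effects})


def simulate_screen(design: StudyDesign, truth: GroundTruth, seed,
                    chemicals: list[str] | None = None) -> pd.DataFrame:
    """Simulate a raw per-worm screen table.

    Continuous endpoint values are ``baseline + effect + noise`` on the raw
    scale of the endpoint's normalization rule, with noise scaled so the
    normalized control SD matches the schema.  Binary labels are Bernoulli
    draws from ``control_rate + effect``.  Worms dead on a given day emit no
    behavioral values on that day (lethality itself is always recorded).
    """
    rng = np.random.default_rng(seed)
    if chemicals is None:
        chemicals = truth.chemicals() or ["chem_0"]
    conc = design.concentrations
    per_plate = design.concentrations_per_plate
    rows: list[tuple] = []

    for chemical in chemicals:
        for worm_type in design.worm_types:
            for rep in range(1, design.replicates + 1):
                for pl in range(design.plates_per_replicate):
                    plate_conc = conc[pl * per_plate:(pl + 1) * per_plate]
                    plate_id = f"{chemical}_{worm_type}_r{rep}_p{pl + 1}"
                    _simulate_plate(rows, rng, design, truth, chemical,
                                    worm_type, rep, plate_id, plate_conc)
    df = pd.DataFrame(rows, columns=RAW_COLUMNS)
    df["day"] = df["day"].astype(int)
    return df


def _death_profile(truth: GroundTruth, chemical: str, worm_type: str,
                   c: float, days: tuple[int, ...]) -> dict[int, float]:
    """Cumulative death probability per assay day (non-decreasing)."""
    p_prev = 0.0
    out = {}
    for day in sorted(days):
        eff = truth.get(chemical, "lethality", worm_type, day)
        p = float(np.clip(eff.at(c), 0.0, 1.0)) if eff is not None else 0.0
        p_prev = max(p_prev, p)
        out[day] = p_prev
    return out


def _simulate_plate(rows, rng, design, truth, chemical, worm_type, rep,
                    plate_id, plate_conc) -> None:
    days = tuple(sorted(design.days))
    conditions = [0.0] + list(plate_conc)  # 0.0 = vehicle control
    specs = [s for s in design.endpoint_schema if worm_type in s.worm_types]
    well = 0
    for c in conditions:
        death = _death_profile(truth, chemical, worm_type, c, days) if c > 0 else {d: 0.0 for d in days}
        for _ in range(design.wells_per_condition):
            well += 1
            u_death = rng.uniform()
            dead_on = {d: u_death < death[d] for d in days}
            for spec in specs:
                for day in spec.days:
                    if day not in days:
                        continue
                    if spec.name == "lethality":
                        rows.append((chemical, worm_type, day, rep, plate_id,
                                     well, c, spec.name, spec.kind,
                                     float(dead_on[day])))
                        continue
                    if dead_on[day]:
                        continue  # dead worms emit no behavioral values
                    eff = truth.get(chemical, spec.name, worm_type, day) if c > 0 else None
                    value = _draw_value(rng, spec, worm_type, day, eff, c)
                    rows.append((chemical, worm_type, day, rep, plate_id,
                                 well, c, spec.name, spec.kind, value))


def _draw_value(rng, spec: sc.EndpointSpec, worm_type: str, day: int,
                eff: HillEffect | None, c: float) -> float:
    if spec.kind == "binary":
        p = spec.control_rate
        if eff is not None:
            p = p + float(eff.at(c))
        return float(rng.uniform() < np.clip(p, 0.0, 1.0))
    sd = spec.control_sd.get((worm_type, day), 0.0) / _VEHICLE_NORM_SHRINKAGE
    shift = 0.0
    if eff is not None:
        signed = float(eff.at(c))
        shift = signed if eff.direction == "+" else -signed
    noise = rng.normal(0.0, sd)
    if spec.rule == sc.SUBTRACT_X100:
        return spec.baseline + (shift + noise) / 100.0
    if spec.rule == sc.DIVIDE_X100_MINUS100:
        return spec.baseline * (1.0 + (shift + noise) / 100.0)
    if spec.rule == sc.SUBTRACT_RAW:
        return spec.baseline + shift + noise
    raise ValueError(f"unexpected rule {spec.rule} for continuous endpoint")


def null_truth() -> GroundTruth:
    """Ground truth with no effects anywhere (all responses flat)."""
    return GroundTruth()


def single_endpoint_truth(chemical: str, endpoint: str, *, rmax: float,
                          ec50_uM: float, h: float, direction: str = "+",
                          worm_types=sc.WORM_TYPES, days=sc.DAYS) -> GroundTruth:
    """Truth with one Hill effect replicated across worm types and days."""
    gt = GroundTruth()
    for wt in worm_types:
        for day in days:
            gt.set(chemical, endpoint, wt, day,
                   HillEffect(rmax, ec50_uM, h, direction))
    return gt


# ---------------------------------------------------------------------------
# trajectory simulation


def simulate_trajectory(*, mean_speed: float = 1.0, rest_prob: float = 0.2,
                        wall_affinity: float = 0.3, light_modulation: float = 1.0,
                        schedule: LightSchedule = DEFAULT_SCHEDULE,
                        dt: float = 0.5, radius_mm: float = 5.5,
                        seed=None) -> TrajectoryTrace:
    """Random-walk worm trace in a circular well under a light schedule.

    The worm rests (speed 0) with probability ``rest_prob`` per frame and
    otherwise moves with a persistent heading at gamma-distributed speeds
    whose mean is chosen so the overall mean frame speed equals
    ``mean_speed``.  ``light_modulation`` multiplies speed during green and
    blue phases (1 = no photic response; <1 = light-evoked slowing).
    ``wall_affinity`` in [0, 1] biases the heading toward the well rim.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    total = schedule.total_duration
    n = int(round(total / dt))
    times = np.arange(1, n + 1) * dt

    moving_mean = mean_speed / (1.0 - rest_prob) if rest_prob < 1.0 else 0.0
    shape = 9.0  # narrow gamma: CV = 1/3

    pos = np.empty((n + 1, 2))
    pos[0] = rng.uniform(-radius_mm / 2, radius_mm / 2, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    for i in range(n):
        phase = schedule.phase_at(times[i] if i else dt / 2)
        if rest_prob >= 1.0 or rng.uniform() < rest_prob:
            step = 0.0
        else:
            step = rng.gamma(shape, moving_mean / shape) * dt
            if phase is not None and phase.color in ("green", "blue"):
                step *= light_modulation
        heading += rng.normal(0.0, 0.5)
        p = pos[i]
        r = np.hypot(*p)
        if wall_affinity > 0 and r > 1e-9:
            outward = math.atan2(p[1], p[0])
            delta = (outward - heading + np.pi) % (2 * np.pi) - np.pi
            heading += wall_affinity * 0.5 * delta
        cand = p + step * np.array([math.cos(heading), math.sin(heading)])
        if np.hypot(*cand) > radius_mm:
            # slide along the wall, preserving step length
            tangent = math.atan2(p[1], p[0]) + math.pi / 2
            if math.cos(tangent - heading) < 0:
                tangent += math.pi
            cand = p + step * np.array([math.cos(tangent), math.sin(tangent)])
            rr = np.hypot(*cand)
            if rr > radius_mm:
                cand = cand * (radius_mm / rr)
            heading = tangent
        pos[i + 1] = cand

    t = np.concatenate([[0.0], times])
    phases = [schedule.phase_name_at(v) for v in t]
    df = pd.DataFrame({
        "t_s": t, "x_mm": pos[:, 0], "y_mm": pos[:, 1],
        "light_phase": phases, "tracked": True,
    })
    return TrajectoryTrace(df, center=(0.0, 0.0), radius_mm=radius_mm,
                           schedule=schedule)


# ---------------------------------------------------------------------------
# Ellman-assay simulation


def simulate_ellman(ic50_uM: float, b: float, concentrations, sd: float,
                    n_replicates: int, seed) -> pd.DataFrame:
    """Percent-activity table from a two-parameter log-logistic truth.

    Activity at concentration c is ``100 / (1 + (c/IC50)^b)`` plus Gaussian
    noise of SD ``sd`` (% activity units); vehicle rows are at 100 + noise.
    """
    if ic50_uM <= 0 or b <= 0:
        raise ValueError("IC50 and slope must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        rows.append(("vehicle", 0.0, rep, 100.0 + rng.normal(0.0, sd)))
        for c in concentrations:
            mu = 100.0 / (1.0 + (c / ic50_uM) ** b)
            rows.append(("chemical", float(c), rep, mu + rng.normal(0.0, sd)))
    return pd.DataFrame(rows, columns=["condition", "concentration_uM",
                                       "replicate", "percent_activity"])
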