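"""Benchmark-response selection and benchmark-concentration estimation.

The benchmark concentration (BMC) of an outcome measure is the concentration
at which the monotonized concentration-response curve first crosses the
benchmark response (BMR), interpolated linearly in log10(concentration).
The BMR itself is chosen data-adaptively: candidate thresholds are scanned
and, for each, the variance of bootstrap BMC estimates is computed; the
recommended BMR is the smallest threshold whose variance has reached the
plateau of the largest scanned thresholds.  Final BMC uncertainty is
summarized as the median and the 5th/95th percentiles of a larger bootstrap.

All curves are handled internally on a *magnitude* scale: responses in the
scored direction are positive, opposite-direction excursions are zeroed, and
monotonization is a conservative top-down clip (suffix minimum) that never
increases any response.  The resampling unit is the individual worm within
each concentration, for both continuous endpoints (per-worm normalized
values, summarized by the median) and binary endpoints (per-worm 0/1 labels,
summarized by the control-adjusted incidence in percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ACTIVE = "active"
INACTIVE = "inactive"
LOW_CENSORED = "low_censored"
UNESTIMABLE = "unestimable"

_STATUS_CODE = {ACTIVE: 0, INACTIVE: 1, LOW_CENSORED: 2}


@dataclass
class ConcentrationResponse:
    """Direction-split responses for one outcome measure of one chemical.

    ``samples[i]`` holds the per-worm data at ``concentrations[i]``: signed
    normalized values for continuous endpoints, 0/1 labels for binary ones.
    ``direction`` gives the scored direction ('+' or '-'); binary endpoints
    are always '+'.  ``control_rate`` is the pooled vehicle incidence used
    for control-normalized binary endpoints (fraction, not percent).
    """

    measure: str
    concentrations: np.ndarray
    samples: list[np.ndarray]
    kind: str  # 'continuous' | 'binary'
    direction: str = "+"
    control_rate: float = 0.0
    masked: frozenset[float] = frozenset()

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.samples) != len(self.concentrations):
            raise ValueError("one sample set per concentration required")
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        extra = set(self.masked) - set(np.round(self.concentrations, 12).tolist())
        if self.masked and extra:
            raise ValueError(f"masked concentrations not in series: {sorted(extra)}")

    def unmasked(self) -> "ConcentrationResponse":
        if not self.masked:
            return self
        keep = [i for i, c in enumerate(self.concentrations) if c not in self.masked]
        return ConcentrationResponse(
            self.measure, self.concentrations[keep],
            [self.samples[i] for i in keep], self.kind, self.direction,
            self.control_rate,
        )

    def point_curve(self) -> np.ndarray:
        """Observed (non-bootstrapped) magnitude curve, monotonized."""
        cr = self.unmasked()
        summ = np.array([_summarize(s, cr.kind, cr.control_rate) for s in cr.samples])
        return monotonize(summ, cr.direction)


def _summarize(values: np.ndarray, kind: str, control_rate: float) -> float:
    if kind == "binary":
        rate = float(np.mean(values))
        return max(0.0, rate - control_rate) * 100.0
    vals = values[np.isfinite(values)]
    return float(np.median(vals)) if vals.size else np.nan


def monotonize(responses, direction: str = "+") -> np.ndarray:
    """Conservative monotone correction of a summary response curve.

    Responses opposite to the scored direction are set to 0; the remainder is
    clipped top-down (each value limited by the minimum of all values at
    higher concentrations), yielding the pointwise-largest non-decreasing
    curve dominated by the input magnitudes.  The result is on the magnitude
    scale (non-negative, non-decreasing) regardless of direction; it is
    idempotent and never increases any |response|.
    """
    r = np.asarray(responses, dtype=float)
    if r.shape[-1] == 0:
        raise ValueError("empty response curve")
    if direction == "-":
        r = -r
    elif direction != "+":
        raise ValueError(f"unknown direction {direction!r}")
    r = np.where(np.isnan(r), 0.0, r)
    r = np.clip(r, 0.0, None)
    return np.minimum.accumulate(r[..., ::-1], axis=-1)[..., ::-1]


def bmc_at_threshold(curve, concentrations, bmr: float):
    """First crossing of a monotone magnitude curve with the BMR.

    Returns ``(bmc_uM, status)``.  Interpolation is linear in log10
    concentration.  ``status`` is ``'inactive'`` when the top response stays
    below the BMR, ``'low_censored'`` (with the lowest tested concentration
    as the value) when already at/above the BMR at the lowest concentration.
    """
    curve = np.asarray(curve, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    values, codes = _cross_batch(curve[None, :], np.log10(conc), float(bmr))
    status = {v: k for k, v in _STATUS_CODE.items()}[int(codes[0])]
    value = float(values[0]) if status != INACTIVE else math.nan
    return value, status


def _cross_batch(curves: np.ndarray, logc: np.ndarray, bmr: float):
    """Vectorized BMR crossing for a (B, C) stack of monotone curves.

    Returns (log10 BMC values, status codes); values are NaN for inactive
    samples and log10(lowest concentration) for low-censored ones.
    """
    B, C = curves.shape
    above = curves >= bmr
    any_above = above.any(axis=1)
    first = np.where(any_above, above.argmax(axis=1), -1)

    codes = np.full(B, _STATUS_CODE[INACTIVE], dtype=np.int8)
    values = np.full(B, np.nan)

    low = any_above & (first == 0)
    codes[low] = _STATUS_CODE[LOW_CENSORED]
    values[low] = logc[0]

    act = any_above & (first > 0)
    if act.any():
        i = first[act]
        r_hi = curves[act, i]
        r_lo = curves[act, i - 1]
        frac = np.where(r_hi > r_lo, (bmr - r_lo) / (r_hi - r_lo), 0.0)
        values[act] = logc[i - 1] + frac * (logc[i] - logc[i - 1])
        codes[act] = _STATUS_CODE[ACTIVE]
    # crossing is reported in concentration units by callers
    values = np.where(codes == _STATUS_CODE[INACTIVE], np.nan, 10.0 ** values)
    return values, codes


def _bootstrap_curves(cr: ConcentrationResponse, B: int, rng: np.random.Generator) -> np.ndarray:
    """(B, C) stack of monotonized bootstrap summary curves.

    Each bootstrap sample resamples worms with replacement within each
    concentration, recomputes the per-concentration summary (median of
    normalized values, or control-adjusted incidence in percent), and
    monotonizes.
    """
    cr = cr.unmasked()
    C = len(cr.concentrations)
    summ = np.empty((B, C))
    for j, s in enumerate(cr.samples):
        if cr.kind == "continuous":
            s = s[np.isfinite(s)]
        n = s.size
        if n == 0:
            raise ValueError(f"no samples at concentration index {j}")
        idx = rng.integers(0, n, size=(B, n))
        draws = s[idx]
        if cr.kind == "binary":
            rate = draws.mean(axis=1)
            summ[:, j] = np.maximum(0.0, rate - cr.control_rate) * 100.0
        else:
            summ[:, j] = np.median(draws, axis=1)
    return monotonize(summ, cr.direction)


def bootstrap_bmcs(cr: ConcentrationResponse, bmr: float, B: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap BMC sample set at a fixed BMR.

    Returns ``(values_uM, statuses)`` of length B; inactive samples carry NaN
    values, low-censored samples carry the lowest tested concentration.
    """
    rng = np.random.default_rng(seed)
    curves = _bootstrap_curves(cr, B, rng)
    logc = np.log10(cr.unmasked().concentrations)
    values, codes = _cross_batch(curves, logc, float(bmr))
    inv = {v: k for k, v in _STATUS_CODE.items()}
    statuses = np.array([inv[int(c)] for c in codes])
    return values, statuses


@dataclass
class BMRScan:
    """Threshold grid and bootstrap sizes for benchmark-response selection."""

    thresholds: np.ndarray
    B_select: int = 100
    B_final: int = 1000
    max_censored: float = 0.5   # skip thresholds with more censoring than this
    plateau_tol: float = 0.05   # variance within 5% of the tail plateau
    plateau_n: int = 3          # thresholds in the tail plateau

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(self.thresholds <= 0) or np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be positive and strictly increasing")
        if self.B_select < 1 or self.B_final < 1:
            raise ValueError("bootstrap counts must be >= 1")

    @classmethod
    def for_class(cls, scan_class: str, **kw) -> "BMRScan":
        grids = {
            "standard": np.arange(5.0, 96.0, 5.0),
            "extended": np.arange(5.0, 151.0, 5.0),
            "burst_total": np.arange(1.0, 31.0, 1.0),
            "burst_ratio": np.arange(0.5, 15.1, 0.5),
        }
        return cls(thresholds=grids[scan_class], **kw)


@dataclass
class BMRSelection:
    bmr: float | None
    variances: dict[float, float]
    plateau: float | None
    manual: bool = False


def select_bmr(crs, scan: BMRScan, seed,
               manual_bmr: float | None = None) -> BMRSelection:
    """Scan candidate BMRs and pick the smallest variance-stabilized one.

    One BMR is selected per outcome measure, so ``crs`` is normally the
    collection of that measure's concentration-responses across all screened
    chemicals (a single response is accepted too).  For each candidate
    threshold, each chemical contributes the variance of its log10 bootstrap
    BMCs over non-censored samples; chemicals with more than
    ``scan.max_censored`` censoring at that threshold are excluded, and a
    threshold with no contributing chemical is skipped.  The per-threshold
    statistic is the mean variance over contributing chemicals.  The plateau
    is the mean statistic of the ``plateau_n`` largest evaluable thresholds,
    and the recommendation is the smallest evaluable threshold whose
    statistic lies within ``plateau_tol`` of it.  A ``manual_bmr`` bypasses
    the scan but the scan diagnostics are still returned.
    """
    if isinstance(crs, ConcentrationResponse):
        crs = [crs]
    rng = np.random.default_rng(seed)
    stacks = [(_bootstrap_curves(cr, scan.B_select, rng),
               np.log10(cr.unmasked().concentrations)) for cr in crs]

    raw_vars: dict[float, float] = {}
    n_contrib: dict[float, int] = {}
    for t in scan.thresholds:
        per_chem = []
        for curves, logc in stacks:
            values, codes = _cross_batch(curves, logc, float(t))
            ok = codes == _STATUS_CODE[ACTIVE]
            if ok.mean() < 1.0 - scan.max_censored or ok.sum() < 2:
                continue
            per_chem.append(float(np.var(np.log10(values[ok]))))
        if per_chem:
            raw_vars[float(t)] = float(np.mean(per_chem))
            n_contrib[float(t)] = len(per_chem)

    # Thresholds near or above the achievable response plateau are crossed
    # only by the few chemicals whose noise happens to exceed them; their
    # variances are biased low (crossings squeezed against the top tested
    # concentration).  Keep only thresholds retaining at least half the
    # maximum number of contributing chemicals, so the plateau is estimated
    # from a consistent population of curves.
    if n_contrib:
        n_max = max(n_contrib.values())
        variances = {t: v for t, v in raw_vars.items()
                     if n_contrib[t] * 2 >= n_max}
    else:
        variances = {}

    if manual_bmr is not None:
        plateau = None
        if variances:
            tail = sorted(variances)[-scan.plateau_n:]
            plateau = float(np.mean([variances[t] for t in tail]))
        return BMRSelection(float(manual_bmr), variances, plateau, manual=True)

    if not variances:
        return BMRSelection(None, variances, None)

    # The variance-vs-threshold curve decays from a noise-dominated maximum
    # to a plateau; the recommended BMR is where the decay has run its
    # course: the smallest threshold whose variance is within plateau_tol of
    # the plateau, measured against the decay amplitude.  A flat variance
    # curve therefore recommends the smallest scanned threshold.
    ts = sorted(variances)
    tail = ts[-scan.plateau_n:]
    plateau = float(np.mean([variances[t] for t in tail]))
    amplitude = max(max(variances.values()) - plateau, 0.0)
    cutoff = plateau + scan.plateau_tol * amplitude + 1e-12
    for t in ts:
        if variances[t] <= cutoff:
            return BMRSelection(float(t), variances, plateau)
    return BMRSelection(float(ts[-1]), variances, plateau)


@dataclass
class BMCResult:
    """Bootstrap BMC summary for one outcome measure of one chemical."""

    measure: str
    direction: str
    bmr: float | None
    median_uM: float
    p5_uM: float
    p95_uM: float
    status: str
    censored_fraction: float

    @property
    def active(self) -> bool:
        return self.status == ACTIVE


def summarize_bmc(values: np.ndarray, statuses: np.ndarray, *,
                  measure: str = "", direction: str = "+",
                  bmr: float | None = None,
                  max_censored: float = 0.5) -> BMCResult:
    """Median and 5th/95th percentile of the bootstrap BMC distribution.

    Samples with no crossing are censored; if they exceed ``max_censored``
    the result is inactive.  Low-censored samples contribute the lowest
    tested concentration; if they dominate the non-censored samples the
    result is flagged low-censored.
    """
    values = np.asarray(values, dtype=float)
    statuses = np.asarray(statuses)
    n = len(values)
    censored = statuses == INACTIVE
    frac_cens = float(censored.mean()) if n else 1.0
    if n == 0 or frac_cens > max_censored:
        return BMCResult(measure, direction, bmr, math.nan, math.nan, math.nan,
                         INACTIVE, frac_cens)
    keep = ~censored
    logs = np.log10(values[keep])
    p5, med, p95 = 10.0 ** np.percentile(logs, [5, 50, 95])
    low_frac = float((statuses[keep] == LOW_CENSORED).mean())
    status = LOW_CENSORED if low_frac > 0.5 else ACTIVE
    return BMCResult(measure, direction, bmr, float(med), float(p5), float(p95),
                     status, frac_cens)


def estimate_bmc(cr: ConcentrationResponse, scan: BMRScan, seed,
                 manual_bmr: float | None = None) -> tuple[BMCResult, BMRSelection]:
    """Single-chemical pipeline: select BMR, final bootstrap, summarize."""
    results, sel = estimate_bmcs([cr], scan, seed, manual_bmr=manual_bmr)
    return results[0], sel


def estimate_bmcs(crs: list[ConcentrationResponse], scan: BMRScan, seed,
                  manual_bmr: float | None = None
                  ) -> tuple[list[BMCResult], BMRSelection]:
    """Measure-level pipeline across chemicals.

    The BMR is selected once from all chemicals' responses for the measure;
    each chemical then gets its own final bootstrap BMC summary at that BMR.
    """
    seeds = _child_seeds(seed, 1 + len(crs))
    sel = select_bmr(crs, scan, seeds[0], manual_bmr=manual_bmr)
    results = []
    for cr, s in zip(crs, seeds[1:]):
        if sel.bmr is None:
            results.append(BMCResult(cr.measure, cr.direction, None, math.nan,
                                     math.nan, math.nan, UNESTIMABLE, 1.0))
            continue
        values, statuses = bootstrap_bmcs(cr, sel.bmr, scan.B_final, s)
        results.append(summarize_bmc(values, statuses, measure=cr.measure,
                                     direction=cr.direction, bmr=sel.bmr,
                                     max_censored=scan.max_censored))
    return results, sel


def most_sensitive_bmc(results: list[BMCResult]) -> BMCResult | None:
    """The active result with the lowest median BMC, or None if none active."""
    active = [r for r in results if r.active and np.isfinite(r.median_uM)]
    if not active:
        return None
    return min(active, key=lambda r: r.median_uM)


def _child_seeds(seed, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) derived from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def child_seed(seed, *tokens) -> int:
    """Stable per-task seed derived from a master seed and hashable tokens."""
    h = 0
    for t in tokens:
        for ch in str(t):
            h = (h * 1000003 + ord(ch)) % (2 ** 31)
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), h])
    return int(ss.generate_state(1)[0]) % (2 ** 31)
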