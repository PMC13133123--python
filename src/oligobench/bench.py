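"""Evaluation harness: decode trials, adaptive threshold scans, Pareto
fronts, and the literature benchmark protocols.

The standard performance metric is the parameter value at which decoding
succeeds with 95% probability, estimated by logistic regression of 30
binary trial outcomes on the log-parameter.  Outcomes come from a
three-stage adaptive scan: ten logarithmically spaced points across the
full range, then twice ten more across ``[t/2, 2t]`` around the current
rough threshold estimate.  Two-parameter trade-offs are mapped by
fixing one parameter at ten log-spaced values while scanning the other,
keeping only the Pareto-efficient threshold pairs.
"""

from __future__ import annotations

import time
import traceback
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm

from .core import ArgumentError

LOGIT_95 = float(np.log(0.95 / 0.05))

HARDER_IS_LARGER = "harder_is_larger"
HARDER_IS_SMALLER = "harder_is_smaller"


@dataclass(frozen=True)
class ResourceLimits:
    """Per-stage trial limits; violations convert the outcome to failure.

    The paper-scale configuration is one hour of wall time, 8 GiB and a
    single core per decode attempt; the default here is a desk-scale
    limit.  Wall time is enforced by cooperative per-stage checks (and
    real timeouts for subprocess codecs); the memory limit is advisory
    for in-process codecs.
    """

    wall_time_s: float = 60.0
    memory_bytes: int = 1 << 30
    cpu_cores: int = 1

    @classmethod
    def paper_scale(cls) -> "ResourceLimits":
        return cls(wall_time_s=3600.0, memory_bytes=8 << 30, cpu_cores=1)


@dataclass
class TrialOutcome:
    x: float
    success: bool
    runtime_s: float = 0.0
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ThresholdEstimate:
    """95%-success parameter value from a logistic fit of trial outcomes."""

    threshold: float
    intercept: float | None
    slope: float | None
    outcomes: list[TrialOutcome]
    censoring: str = "none"  # none | all_success | all_fail
    method: str = "logit"  # logit | bisection | censored
    direction: str = HARDER_IS_LARGER


def run_trial(
    codec,
    channel_fn: Callable,
    clusterer: Callable,
    payload: bytes,
    x: float,
    limits: ResourceLimits | None = None,
) -> TrialOutcome:
    """Execute encode → channel(x) → cluster/consensus → decode.

    Success requires byte-identical payload recovery within the per-stage
    wall-time limit.  Component crashes become failure outcomes with a
    diagnostic; no exception escapes the harness.  A decoder claiming
    success with a non-identical payload is recorded in the
    ``wrong_success`` diagnostic (and still counts as failure).
    """
    limits = limits or ResourceLimits()
    start = time.perf_counter()
    diag: dict = {}

    def overtime(stage: str, stage_start: float) -> bool:
        elapsed = time.perf_counter() - stage_start
        if elapsed > limits.wall_time_s:
            diag["timeout"] = stage
            return True
        return False

    try:
        t0 = time.perf_counter()
        pool = codec.encode(payload)
        if overtime("encode", t0):
            return TrialOutcome(x, False, time.perf_counter() - start, diag)

        t0 = time.perf_counter()
        readset = channel_fn(pool, x)
        if overtime("channel", t0):
            return TrialOutcome(x, False, time.perf_counter() - start, diag)
        if not len(readset):
            diag["empty_readset"] = True
            return TrialOutcome(x, False, time.perf_counter() - start, diag)

        t0 = time.perf_counter()
        consensus = clusterer(readset, pool.design_length)
        if overtime("cluster", t0):
            return TrialOutcome(x, False, time.perf_counter() - start, diag)

        t0 = time.perf_counter()
        result = codec.decode(consensus.sequences, abundances=consensus.sizes)
        if overtime("decode", t0):
            return TrialOutcome(x, False, time.perf_counter() - start, diag)
        diag.update(result.diagnostics)
        success = result.success and result.payload == payload
        if result.success and result.payload != payload:
            diag["wrong_success"] = True
        return TrialOutcome(x, success, time.perf_counter() - start, diag)
    except Exception as exc:  # noqa: BLE001 - the harness never raises
        diag["error"] = f"{type(exc).__name__}: {exc}"
        diag["traceback"] = traceback.format_exc(limit=3)
        return TrialOutcome(x, False, time.perf_counter() - start, diag)


def _hard_extreme(xs: Sequence[float], direction: str) -> float:
    return max(xs) if direction == HARDER_IS_LARGER else min(xs)


def _easy_extreme(xs: Sequence[float], direction: str) -> float:
    return min(xs) if direction == HARDER_IS_LARGER else max(xs)


def fit_logistic_threshold(
    outcomes: Sequence[TrialOutcome],
    p_star: float = 0.95,
    direction: str = HARDER_IS_LARGER,
) -> ThresholdEstimate:
    """Maximum-likelihood logistic regression of success on log-parameter.

    All-success or all-fail outcomes yield a censored estimate at the
    corresponding range extreme.  On complete separation (all successes
    strictly easier than all failures) the fit degenerates; the
    threshold falls back to the geometric midpoint between the extreme
    success and failure points, flagged via ``method='bisection'``.
    """
    if len(outcomes) < 2:
        raise ArgumentError("need at least two outcomes")
    if direction not in (HARDER_IS_LARGER, HARDER_IS_SMALLER):
        raise ArgumentError(f"unknown direction {direction!r}")
    xs = np.array([o.x for o in outcomes], dtype=float)
    ys = np.array([o.success for o in outcomes], dtype=float)
    if np.any(xs <= 0):
        raise ArgumentError("parameter values must be positive (log-space fit)")

    outs = list(outcomes)
    if ys.all():
        return ThresholdEstimate(_hard_extreme(xs, direction), None, None, outs,
                                 censoring="all_success", method="censored",
                                 direction=direction)
    if not ys.any():
        return ThresholdEstimate(_easy_extreme(xs, direction), None, None, outs,
                                 censoring="all_fail", method="censored",
                                 direction=direction)

    succ, fail = xs[ys == 1], xs[ys == 0]
    if direction == HARDER_IS_LARGER:
        separated = succ.max() < fail.min()
        edge_s, edge_f = succ.max(), fail.min()
    else:
        separated = succ.min() > fail.max()
        edge_s, edge_f = succ.min(), fail.max()

    def quantile_point() -> float:
        # interpolate to the p* quantile in log space between the extreme
        # success and failure points (the midpoint would estimate the 50%
        # point and overshoot a 95% threshold)
        return float(np.exp(p_star * np.log(edge_s)
                            + (1.0 - p_star) * np.log(edge_f)))

    if separated:
        return ThresholdEstimate(quantile_point(), None, None, outs,
                                 method="bisection", direction=direction)

    expected_sign = -1.0 if direction == HARDER_IS_LARGER else 1.0
    try:
        model = sm.Logit(ys, sm.add_constant(np.log(xs)))
        fit = model.fit(disp=0, maxiter=200)
        b0, b1 = float(fit.params[0]), float(fit.params[1])
    except Exception:
        b1 = 0.0
    if b1 == 0.0 or np.sign(b1) != expected_sign or not np.isfinite(b0 + b1):
        # noisy overlap without a usable slope
        return ThresholdEstimate(quantile_point(), None, None, outs,
                                 method="bisection", direction=direction)
    target = float(np.log(p_star / (1.0 - p_star)))
    t = float(np.exp((target - b0) / b1))
    return ThresholdEstimate(t, b0, b1, outs, method="logit", direction=direction)


def adaptive_scan(
    trial_fn: Callable[[float], TrialOutcome | bool],
    x_min: float,
    x_max: float,
    direction: str = HARDER_IS_LARGER,
    p_star: float = 0.95,
    points_per_stage: int = 10,
) -> ThresholdEstimate:
    """Three-stage adaptive one-dimensional sensitivity analysis.

    Stage 1 tests ten log-spaced points across the full range; stages 2
    and 3 each test ten more log-spaced points across ``[t/2, 2t]``
    around the current rough threshold (clipped to the range; a censored
    rough fit refines the hard — or easy — decade of the range instead).
    The final estimate fits all 30 outcomes.
    """
    if not 0 < x_min < x_max:
        raise ArgumentError("need 0 < x_min < x_max")

    def run_points(points: np.ndarray) -> list[TrialOutcome]:
        outs = []
        for x in points:
            res = trial_fn(float(x))
            if isinstance(res, TrialOutcome):
                outs.append(res)
            else:
                outs.append(TrialOutcome(float(x), bool(res)))
        return outs

    def window(estimate: ThresholdEstimate) -> tuple[float, float]:
        if estimate.censoring == "all_success":
            # refine the hard extreme decade
            if direction == HARDER_IS_LARGER:
                return max(x_min, x_max / 10.0), x_max
            return x_min, min(x_max, x_min * 10.0)
        if estimate.censoring == "all_fail":
            if direction == HARDER_IS_LARGER:
                return x_min, min(x_max, x_min * 10.0)
            return max(x_min, x_max / 10.0), x_max
        t = estimate.threshold
        lo = max(x_min, t / 2.0)
        hi = min(x_max, 2.0 * t)
        if lo >= hi:  # threshold pinned at a range edge
            lo, hi = max(x_min, hi / 2.0), min(x_max, lo * 2.0)
        return lo, hi

    outcomes = run_points(np.geomspace(x_min, x_max, points_per_stage))
    for _stage in (2, 3):
        rough = fit_logistic_threshold(outcomes, p_star, direction)
        lo, hi = window(rough)
        outcomes += run_points(np.geomspace(lo, hi, points_per_stage))
    return fit_logistic_threshold(outcomes, p_star, direction)


@dataclass
class ParetoFront:
    """Non-dominated feasible (x, y) threshold combinations."""

    points: list[tuple[float, float]]
    directions: tuple[str, str]
    axes: tuple[str, str] = ("x", "y")


def _dominates(a, b, directions) -> bool:
    """True if a is at least as hard as b everywhere and harder somewhere."""
    ge_all = True
    gt_any = False
    for av, bv, d in zip(a, b, directions):
        if d == HARDER_IS_LARGER:
            if av < bv:
                ge_all = False
            if av > bv:
                gt_any = True
        else:
            if av > bv:
                ge_all = False
            if av < bv:
                gt_any = True
    return ge_all and gt_any


def pareto_filter(
    points: Sequence[tuple[float, float]], directions: tuple[str, str]
) -> list[tuple[float, float]]:
    """Keep the Pareto-efficient points under the declared directions."""
    kept = []
    for i, p in enumerate(points):
        if not any(
            _dominates(q, p, directions) for j, q in enumerate(points) if j != i
        ):
            kept.append(tuple(p))
    # deduplicate while preserving order
    seen: set = set()
    unique = []
    for p in kept:
        if p not in seen:
            seen.add(p)
            unique.append(p)
    return unique


def pareto_scan(
    trial_fn: Callable[[float, float], TrialOutcome | bool],
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    directions: tuple[str, str] = (HARDER_IS_LARGER, HARDER_IS_LARGER),
    n_fixed: int = 10,
    points_per_stage: int = 10,
) -> ParetoFront:
    """Two sets of one-dimensional scans → Pareto-efficient thresholds.

    For each of ``n_fixed`` log-spaced x values, y is scanned adaptively
    (and vice versa); scans whose outcomes are all failures contribute
    no point.
    """
    points: list[tuple[float, float]] = []
    for x_fixed in np.geomspace(*x_range, n_fixed):
        est = adaptive_scan(
            lambda y: trial_fn(float(x_fixed), y),
            y_range[0], y_range[1],
            direction=directions[1], points_per_stage=points_per_stage,
        )
        if est.censoring != "all_fail":
            points.append((float(x_fixed), est.threshold))
    for y_fixed in np.geomspace(*y_range, n_fixed):
        est = adaptive_scan(
            lambda x: trial_fn(x, float(y_fixed)),
            x_range[0], x_range[1],
            direction=directions[0], points_per_stage=points_per_stage,
        )
        if est.censoring != "all_fail":
            points.append((est.threshold, float(y_fixed)))
    return ParetoFront(points=pareto_filter(points, directions),
                       directions=directions)


def literature_protocol(
    iteration_fn: Callable[[int, int], bool],
    max_iterations: int,
    n_repeats: int = 10,
    seed: int = 0,
) -> int:
    """Highest iteration count with all ``n_repeats`` decodes successful.

    ``iteration_fn(i, seed)`` runs one decode attempt of protocol
    iteration ``i`` (1-based).  Each iteration is tested with
    ``n_repeats`` distinct seeds; the scan stops at the first iteration
    with any failure and reports the previous one (0 when the first
    iteration already fails).
    """
    highest = 0
    for i in range(1, max_iterations + 1):
        if all(iteration_fn(i, seed * 10_000 + i * 100 + r)
               for r in range(n_repeats)):
            highest = i
        else:
            break
    return highest


def serial_dilution_iteration(
    codec, payload: bytes, clusterer, base_params, dilution_factor: float = 10.0,
    limits: ResourceLimits | None = None,
):
    """Iteration function for the serial-dilution protocol.

    Iteration i divides the physical redundancy by dilution_factor**i.
    """
    from dataclasses import replace

    from .channel import run_workflow

    def fn(i: int, seed: int) -> bool:
        params = replace(
            base_params,
            redundancy=base_params.redundancy / dilution_factor**i,
            seed=seed,
        )
        out = run_trial(codec, lambda pool, _x: run_workflow(pool, params),
                        clusterer, payload, x=float(i), limits=limits)
        return out.success

    return fn


def serial_amplification_iteration(
    codec, payload: bytes, clusterer, base_params, cycles_per_iteration: int = 10,
    limits: ResourceLimits | None = None,
):
    """Iteration i adds i·cycles_per_iteration extra second-round PCR cycles."""
    from dataclasses import replace

    from .channel import run_workflow

    def fn(i: int, seed: int) -> bool:
        params = replace(
            base_params,
            pcr2_cycles=base_params.pcr2_cycles + i * cycles_per_iteration,
            seed=seed,
        )
        out = run_trial(codec, lambda pool, _x: run_workflow(pool, params),
                        clusterer, payload, x=float(i), limits=limits)
        return out.success

    return fn


def downsampling_iteration(
    codec, payload: bytes, clusterer, base_params, depth_grid: Sequence[float],
    limits: ResourceLimits | None = None,
):
    """Iteration i sequences at the i-th (descending) depth of the grid."""
    from dataclasses import replace

    from .channel import run_workflow

    grid = sorted(depth_grid, reverse=True)

    def fn(i: int, seed: int) -> bool:
        if i > len(grid):
            return False
        params = replace(base_params, depth=grid[i - 1], seed=seed)
        out = run_trial(codec, lambda pool, _x: run_workflow(pool, params),
                        clusterer, payload, x=float(grid[i - 1]), limits=limits)
        return out.success

    return fn
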