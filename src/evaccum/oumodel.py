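"""Ornstein–Uhlenbeck leaky-accumulator agent and reward-landscape search.

The agent accumulates the signed momentary coherence M_t of a stimulus
block according to

    X_t = (1 + lambda) * X_{t-1} + g * M_t + eps_t,   eps_t ~ N(0, sigma^2)

with leak lambda in [-1, 0] (lambda = 0 recovers drift-diffusion
accumulation), gain g, and per-step noise sigma, on the block's 10 ms
sample grid.  Whenever |X| reaches the decision threshold theta the agent
emits a press in the direction of sign(X) and X resets to 0 from the next
sample.  The agent's presses are scored with the same task reward rule as
human presses, so correct/incorrect presses terminate response periods
(closed loop through :func:`evaccum.stimgen.score_responses`).

``grid_search_ou`` maps mean points over a (lambda, theta) grid, using
common noise draws per stream across cells; ``model_kernel_sweep``
recovers integration kernels from the agent's false alarms to show how
threshold and leak shape the kernel's decay constant and amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from . import behaviour
from .stimgen import (
    Direction,
    Outcome,
    ResponseEvent,
    ScoreResult,
    StimulusBlock,
    score_responses,
)

__all__ = [
    "OUParams",
    "OUSimResult",
    "GridSearchResult",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_THETA_GRID",
    "COMPARISON_LAMBDA_GRID",
    "COMPARISON_THETA_GRID",
    "simulate_ou_block",
    "run_closed_loop",
    "grid_search_ou",
    "model_kernel_sweep",
]

# Absolute guard on the threshold comparison so exact deterministic ramps
# cross at the intended step despite float accumulation rounding.
_CROSS_TOL = 1e-9

# Default landscape grid: leak magnitudes spanning integration times of
# 0.2-10 s (log-spaced; the leak is constrained negative, as a pure
# drift-diffusion accumulator cannot discount stale evidence in this
# task), thresholds bracketing the reward-positive ridge for unit-gain
# accumulation of per-sample coherence.
DEFAULT_LAMBDA_GRID = -np.geomspace(0.05, 0.001, 18)
DEFAULT_THETA_GRID = np.linspace(10.0, 150.0, 15)

# Focused grid for condition comparisons of per-block optima: fine leak
# resolution around multi-second integration times, where the optimum
# lives for every condition, so matched blocks can resolve the small
# shifts the environment statistics induce.
COMPARISON_LAMBDA_GRID = -np.geomspace(0.005, 0.001, 8)
COMPARISON_THETA_GRID = np.array([45.0, 70.0, 100.0, 140.0])


@dataclass(frozen=True)
class OUParams:
    """Leaky-accumulator parameters on the 10 ms step grid."""

    leak_lambda: float = -0.002
    threshold_theta: float = 70.0
    gain_g: float = 1.0
    noise_sigma: float = 0.25
    dt_s: float = 0.010

    def __post_init__(self) -> None:
        if not (-1.0 <= self.leak_lambda <= 0.0):
            raise ValueError("leak_lambda must lie in [-1, 0]")
        if self.threshold_theta <= 0:
            raise ValueError("threshold_theta must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class OUSimResult:
    responses: list[ResponseEvent]
    params: OUParams
    seed: Optional[int]
    trajectory: Optional[np.ndarray] = None


@dataclass
class GridSearchResult:
    """Reward landscape over the (lambda, theta) grid."""

    lambda_grid: np.ndarray
    theta_grid: np.ndarray
    points: np.ndarray  # (n_lambda, n_theta) mean total points per block
    points_per_stream: np.ndarray  # (n_lambda, n_theta, n_streams)
    top_decile_mask: np.ndarray
    argmax: tuple[float, float]
    per_stream_argmax: list[tuple[float, float]]


@njit(cache=False)
def _ou_core(coh, one_plus_lam, g, theta, eps, record_traj):
    n = coh.shape[0]
    times = np.empty(n, dtype=np.int64)
    dirs = np.empty(n, dtype=np.int64)
    traj = np.zeros(n if record_traj else 1)
    k = 0
    x = 0.0
    for t in range(n):
        x = one_plus_lam * x + g * coh[t] + eps[t]
        if record_traj:
            traj[t] = x
        if (x >= theta - _CROSS_TOL) or (x <= -theta + _CROSS_TOL):
            times[k] = t
            dirs[k] = 1 if x > 0 else -1
            k += 1
            x = 0.0
    return times[:k], dirs[:k], traj


def simulate_ou_block(
    block: StimulusBlock,
    params: OUParams,
    seed=None,
    *,
    record_trajectory: bool = False,
    eps: Optional[np.ndarray] = None,
) -> OUSimResult:
    """Run the accumulator over one block and collect its presses.

    ``eps`` may supply a pre-drawn per-sample noise vector (used by the
    grid search for common random numbers across cells); otherwise noise is
    drawn from ``seed`` with SD ``params.noise_sigma``.
    """
    if abs(1.0 / block.fs_hz - params.dt_s) > 1e-12:
        raise ValueError("params.dt_s must match the block sample step")
    n = len(block.coherence)
    if eps is None:
        rng = np.random.default_rng(seed)
        eps = (
            rng.normal(0.0, params.noise_sigma, n)
            if params.noise_sigma > 0
            else np.zeros(n)
        )
    elif len(eps) != n:
        raise ValueError("eps length must match the block")
    times, dirs, traj = _ou_core(
        np.ascontiguousarray(block.coherence, dtype=np.float64),
        1.0 + params.leak_lambda,
        params.gain_g,
        params.threshold_theta,
        np.ascontiguousarray(eps, dtype=np.float64),
        record_trajectory,
    )
    responses = [
        ResponseEvent(
            time_s=float(t) / block.fs_hz,
            direction=Direction.RIGHT if d > 0 else Direction.LEFT,
        )
        for t, d in zip(times, dirs)
    ]
    return OUSimResult(
        responses=responses,
        params=params,
        seed=seed if isinstance(seed, int) else None,
        trajectory=traj if record_trajectory else None,
    )


def simulate_and_score(
    block: StimulusBlock, params: OUParams, seed=None, eps=None
) -> tuple[OUSimResult, ScoreResult]:
    """Simulate the agent on a block and score its presses with the task rule."""
    sim = simulate_ou_block(block, params, seed=seed, eps=eps)
    return sim, score_responses(block, sim.responses)


@njit(cache=False)
def _ou_interval(x0, m, one_plus_lam, g, theta, eps):
    """Step the accumulator through one constant-coherence interval.

    Returns (crossing sample offsets, crossing signs, x at interval end).
    """
    n = eps.shape[0]
    times = np.empty(n, dtype=np.int64)
    dirs = np.empty(n, dtype=np.int64)
    k = 0
    x = x0
    for t in range(n):
        x = one_plus_lam * x + g * m + eps[t]
        if (x >= theta - _CROSS_TOL) or (x <= -theta + _CROSS_TOL):
            times[k] = t
            dirs[k] = 1 if x > 0 else -1
            k += 1
            x = 0.0
    return times[:k], dirs[:k], x


def run_closed_loop(
    condition,
    params: OUParams,
    seed: int,
    cfg: Optional["TaskConfig"] = None,
    *,
    fs_hz: float = 100.0,
    duration_s: float = 300.0,
):
    """Simulate the agent and the stimulus together, closed loop.

    As in the live task, a correct or incorrect press inside a response
    period terminates that period immediately: the next scheduled baseline
    (with its already-sampled duration) starts at the press time, and
    subsequent noise intervals draw from baseline statistics.  A press
    within the 500 ms tolerance after an unclaimed period's end still
    counts for that period.  Coherence statistics of each noise interval
    follow the period active at the interval's onset.

    The root seed splits into sub-streams for the period schedule, the
    interval durations, the coherence draws and the accumulator noise, so
    two parameterisations on the same seed share stimulus randomness up to
    the point their behaviour diverges.

    Returns ``(block, sim, score)`` where ``block`` is the materialised
    behaviour-coupled stimulus and ``score`` the task-rule scoring of the
    agent's presses.  Re-scoring ``block`` with ``sim.responses`` through
    :func:`evaccum.stimgen.score_responses` reproduces ``score``.
    """
    from .stimgen import (
        CONDITIONS,
        NoiseInterval,
        Period,
        PeriodKind,
        PeriodSchedule,
        RESPONSE_MEANS,
        ScoredResponse,
        TaskConfig,
    )

    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    if cfg is None:
        cfg = TaskConfig()
    if abs(1.0 / fs_hz - params.dt_s) > 1e-12:
        raise ValueError("params.dt_s must match the sample step")

    ss = np.random.SeedSequence(seed)
    s_sched, s_int, s_coh, s_eps = ss.spawn(4)
    r_sched = np.random.default_rng(s_sched)
    r_int = np.random.default_rng(s_int)
    r_coh = np.random.default_rng(s_coh)
    r_eps = np.random.default_rng(s_eps)

    lo, hi = condition.baseline_range_s
    resp_dur = condition.response_period_s
    n_total = int(round(duration_s * fs_hz))

    def next_period(kind: PeriodKind, onset: float) -> Period:
        if kind is PeriodKind.BASELINE:
            d = float(r_sched.uniform(lo, hi))
            return Period(PeriodKind.BASELINE, onset, d, 0.0,
                          min(onset + d, duration_s))
        m = float(r_sched.choice(RESPONSE_MEANS))
        return Period(PeriodKind.RESPONSE, onset, resp_dur, m,
                      min(onset + resp_dur, duration_s))

    def draw_duration() -> float:
        while True:
            d = float(r_int.exponential(cfg.isi_mean_s))
            if cfg.isi_min_s <= d <= cfg.isi_max_s:
                return d

    periods: list[Period] = [next_period(PeriodKind.BASELINE, 0.0)]
    current = periods[0]
    # most recent response period eligible for the post-end tolerance press
    pending: Optional[Period] = None

    intervals: list[NoiseInterval] = []
    coh_series = np.empty(n_total)
    scored: list[ScoredResponse] = []
    responses: list[ResponseEvent] = []
    misses = 0

    one_plus_lam = 1.0 + params.leak_lambda
    x = 0.0
    sample = 0  # next sample index to fill
    t_interval = 0.0  # unquantised interval onset

    while sample < n_total:
        # advance the period state to the interval onset
        t_onset = sample / fs_hz
        while t_onset >= current.actual_end_s and current.actual_end_s < duration_s:
            if current.kind is PeriodKind.RESPONSE:
                pending = current
            nxt = next_period(
                PeriodKind.RESPONSE
                if current.kind is PeriodKind.BASELINE
                else PeriodKind.BASELINE,
                current.actual_end_s,
            )
            periods.append(nxt)
            current = nxt

        dur = draw_duration()
        end_sample = min(int(round((t_interval + dur) * fs_hz)), n_total)
        if end_sample <= sample:
            t_interval += dur
            continue
        if current.kind is PeriodKind.RESPONSE:
            m = float(r_coh.normal(current.mean_coherence, cfg.sd_response))
        else:
            m = float(r_coh.normal(0.0, cfg.sd_baseline))
        m = float(np.clip(m, -1.0, 1.0))
        intervals.append(NoiseInterval(t_interval, dur, m))
        t_interval += dur

        n_sub = end_sample - sample
        eps = (
            r_eps.normal(0.0, params.noise_sigma, n_sub)
            if params.noise_sigma > 0
            else np.zeros(n_sub)
        )
        offs, dirs, x = _ou_interval(
            x, m, one_plus_lam, params.gain_g, params.threshold_theta, eps
        )
        coh_series[sample:end_sample] = m

        for off, d in zip(offs, dirs):
            t_press = (sample + int(off)) / fs_hz
            direction = Direction.RIGHT if d > 0 else Direction.LEFT
            ev = ResponseEvent(time_s=t_press, direction=direction)
            responses.append(ev)
            # keep the period state current at the press time
            while (
                t_press >= current.actual_end_s
                and current.actual_end_s < duration_s
            ):
                if current.kind is PeriodKind.RESPONSE:
                    pending = current
                nxt = next_period(
                    PeriodKind.RESPONSE
                    if current.kind is PeriodKind.BASELINE
                    else PeriodKind.BASELINE,
                    current.actual_end_s,
                )
                periods.append(nxt)
                current = nxt
            target = None
            if current.kind is PeriodKind.RESPONSE:
                target = current
            elif (
                pending is not None
                and t_press < pending.actual_end_s + cfg.response_tolerance_s
            ):
                target = pending
            if target is None:
                scored.append(
                    ScoredResponse(ev, Outcome.FALSE_ALARM, cfg.penalty_false_alarm)
                )
                continue
            match = (direction is Direction.RIGHT) == (target.mean_coherence > 0)
            outcome = Outcome.CORRECT if match else Outcome.INCORRECT
            pts = cfg.reward_correct if match else cfg.penalty_incorrect
            target_idx = next(
                i for i, p in enumerate(periods) if p is target
            )
            scored.append(
                ScoredResponse(
                    ev, outcome, pts,
                    period_index=target_idx,
                    rt_s=t_press - target.onset_s,
                )
            )
            if target is current:
                # terminate the period: baseline resumes at the press time
                current.actual_end_s = t_press
                pending = None
                nxt = next_period(PeriodKind.BASELINE, t_press)
                periods.append(nxt)
                current = nxt
            else:
                pending = None

        sample = end_sample

    # drop trailing periods that never started, and a final unclaimed
    # response stub shorter than one sample (too short to count)
    claimed_idx = {
        s.period_index
        for s in scored
        if s.outcome in (Outcome.CORRECT, Outcome.INCORRECT)
    }
    while periods:
        last_i = len(periods) - 1
        last = periods[last_i]
        unstarted = last.onset_s >= duration_s
        stub = (
            last.kind is PeriodKind.RESPONSE
            and last.actual_end_s - last.onset_s < 0.010
            and last_i not in claimed_idx
        )
        if unstarted or stub:
            periods.pop()
        else:
            break
    misses = sum(
        1
        for i, p in enumerate(periods)
        if p.kind is PeriodKind.RESPONSE and i not in claimed_idx
    )

    from .stimgen import ScoreResult, StimulusBlock

    schedule = PeriodSchedule(periods)
    block = StimulusBlock(
        condition=condition,
        cfg=cfg,
        fs_hz=fs_hz,
        duration_s=duration_s,
        coherence=coh_series,
        intervals=intervals,
        schedule=schedule,
        seed=int(seed),
    )
    n_c = sum(1 for s in scored if s.outcome is Outcome.CORRECT)
    n_i = sum(1 for s in scored if s.outcome is Outcome.INCORRECT)
    n_fa = sum(1 for s in scored if s.outcome is Outcome.FALSE_ALARM)
    total = (
        cfg.reward_correct * n_c
        + cfg.penalty_incorrect * n_i
        + cfg.penalty_false_alarm * n_fa
        + cfg.penalty_miss * misses
    )
    sim = OUSimResult(responses=responses, params=params, seed=int(seed))
    score = ScoreResult(
        scored=scored, misses=misses, total_points=float(total), schedule=schedule
    )
    return block, sim, score


def grid_search_ou(
    streams: Sequence[StimulusBlock],
    lambda_grid: Sequence[float],
    theta_grid: Sequence[float],
    params_base: OUParams = OUParams(),
    seed: int = 0,
    *,
    closed_loop: bool = True,
) -> GridSearchResult:
    """Mean points per block over the (lambda, theta) grid.

    g and sigma are held constant at ``params_base`` values.  By default
    each cell re-runs the agent closed loop (the stimulus reacts to the
    agent's presses, as in the live task), with each stream contributing
    its condition, task config and seed; streams on the same seed share
    stimulus and accumulator randomness across cells up to the point
    behaviour diverges (common random numbers).  With
    ``closed_loop=False`` the agent runs open loop over the fixed
    materialised streams.  Either way the points come from the task
    scoring rule (no separate scoring path).  The top-decile mask marks
    the 10% of cells (rounded, at least one) with the highest mean points.
    """
    if len(streams) == 0:
        raise ValueError("need at least one stream")
    lam = np.asarray(lambda_grid, dtype=float)
    th = np.asarray(theta_grid, dtype=float)
    if lam.size == 0 or th.size == 0:
        raise ValueError("grids must be non-empty")

    ss = np.random.SeedSequence(seed)
    eps_list = None
    if not closed_loop:
        eps_list = []
        for s, blk in zip(ss.spawn(len(streams)), streams):
            rng = np.random.default_rng(s)
            n = len(blk.coherence)
            eps_list.append(
                rng.normal(0.0, params_base.noise_sigma, n)
                if params_base.noise_sigma > 0
                else np.zeros(n)
            )

    pts = np.empty((lam.size, th.size, len(streams)))
    for i, lv in enumerate(lam):
        for j, tv in enumerate(th):
            p = replace(params_base, leak_lambda=float(lv), threshold_theta=float(tv))
            for k, blk in enumerate(streams):
                if closed_loop:
                    _, _, scored = run_closed_loop(
                        blk.condition, p, blk.seed, blk.cfg,
                        fs_hz=blk.fs_hz, duration_s=blk.duration_s,
                    )
                else:
                    _, scored = simulate_and_score(blk, p, eps=eps_list[k])
                pts[i, j, k] = scored.total_points

    mean_pts = pts.mean(axis=2)
    ncells = mean_pts.size
    k_top = max(1, int(round(0.10 * ncells)))
    flat_order = np.argsort(mean_pts, axis=None)[::-1]
    mask = np.zeros(ncells, dtype=bool)
    mask[flat_order[:k_top]] = True
    mask = mask.reshape(mean_pts.shape)

    bi, bj = np.unravel_index(int(np.argmax(mean_pts)), mean_pts.shape)
    per_stream = []
    for k in range(len(streams)):
        si, sj = np.unravel_index(int(np.argmax(pts[:, :, k])), mean_pts.shape)
        per_stream.append((float(lam[si]), float(th[sj])))

    return GridSearchResult(
        lambda_grid=lam,
        theta_grid=th,
        points=mean_pts,
        points_per_stream=pts,
        top_decile_mask=mask,
        argmax=(float(lam[bi]), float(th[bj])),
        per_stream_argmax=per_stream,
    )


def model_kernel_sweep(
    theta_values: Sequence[float],
    lambda_values: Sequence[float],
    params_base: OUParams,
    streams: Sequence[StimulusBlock],
    seed: int = 0,
    *,
    min_events: int = 50,
    window_s: float = 5.0,
    closed_loop: bool = True,
) -> pd.DataFrame:
    """Integration-kernel fits to the agent's false alarms along 1-D sweeps.

    Two sweeps are run: theta varies with lambda fixed at
    ``params_base.leak_lambda``, and lambda varies with theta fixed at
    ``params_base.threshold_theta``.  For each setting the agent runs over
    all streams, its false alarms are reverse-correlated into a kernel and
    fit with the exponential-decay model.  Settings yielding fewer than
    ``min_events`` false alarms are flagged ``under_sampled`` (fit values
    are NaN when no event exists at all).

    Returns a DataFrame with columns (sweep, leak_lambda, threshold_theta,
    A, tau_s, r_squared, n_false_alarms, under_sampled).
    """
    settings = [
        ("theta", params_base.leak_lambda, float(tv)) for tv in theta_values
    ] + [("lambda", float(lv), params_base.threshold_theta) for lv in lambda_values]

    rows = []
    ss = np.random.SeedSequence(seed)
    for (sweep, lv, tv), sub in zip(settings, ss.spawn(len(settings))):
        p = replace(params_base, leak_lambda=lv, threshold_theta=tv)
        scored_blocks = []
        n_fa = 0
        for s, blk in zip(sub.spawn(len(streams)), streams):
            if closed_loop:
                sim_blk, _, scored = run_closed_loop(
                    blk.condition, p, blk.seed, blk.cfg,
                    fs_hz=blk.fs_hz, duration_s=blk.duration_s,
                )
                scored_blocks.append(
                    behaviour.ScoredBlock(block=sim_blk, result=scored)
                )
            else:
                _, scored = simulate_and_score(
                    blk, p, seed=np.random.default_rng(s)
                )
                scored_blocks.append(behaviour.ScoredBlock(block=blk, result=scored))
            n_fa += scored.n_false_alarm
        under = n_fa < min_events
        if n_fa > 0:
            kern = behaviour.compute_integration_kernel(
                scored_blocks, Outcome.FALSE_ALARM, window_s=window_s
            )
            fit = behaviour.fit_exponential_kernel(kern)
            a_hat, tau_hat, r2 = fit.A, fit.tau_s, fit.r_squared
        else:
            a_hat = tau_hat = r2 = float("nan")
        rows.append(
            {
                "sweep": sweep,
                "leak_lambda": lv,
                "threshold_theta": tv,
                "A": a_hat,
                "tau_s": tau_hat,
                "r_squared": r2,
                "n_false_alarms": n_fa,
                "under_sampled": under,
            }
        )
    return pd.DataFrame(rows)
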