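"""Continuous random-dot-motion stimulus generation and response scoring.

The task presents a single continuously varying motion-coherence stream for
5-minute blocks.  The stream is piecewise constant over short "noise
intervals" whose durations follow a truncated exponential distribution
(mean 270 ms, bounds 10–1000 ms).  Each block alternates zero-mean
"baseline" periods with non-zero-mean "response" periods; the observer's
job is to press left/right whenever they believe a response period is
ongoing.  Scoring follows the task's points rule: +3 correct, −3 incorrect
direction, −1.5 for a miss or a false alarm.

Four environment conditions form a 2×2 design: response periods are LONG
(5 s) or SHORT (3 s), and RARE (baseline durations uniform on 5–40 s) or
FREQUENT (3–8 s).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LengthClass",
    "FrequencyClass",
    "PeriodKind",
    "Direction",
    "Outcome",
    "Condition",
    "CONDITIONS",
    "TaskConfig",
    "NoiseInterval",
    "Period",
    "PeriodSchedule",
    "StimulusBlock",
    "ResponseEvent",
    "ScoredResponse",
    "ScoreResult",
    "RESPONSE_MEANS",
    "sample_noise_intervals",
    "schedule_periods",
    "generate_block",
    "score_responses",
]

#: Candidate mean coherences for response periods (signed fraction of
#: coherently moving dots; drawn uniformly per response period).
RESPONSE_MEANS: tuple[float, ...] = (-0.5, -0.4, -0.3, 0.3, 0.4, 0.5)


class LengthClass(enum.Enum):
    LONG = "LONG"
    SHORT = "SHORT"


class FrequencyClass(enum.Enum):
    RARE = "RARE"
    FREQUENT = "FREQUENT"


class PeriodKind(enum.Enum):
    BASELINE = "BASELINE"
    RESPONSE = "RESPONSE"


class Direction(enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Outcome(enum.Enum):
    CORRECT = "CORRECT"
    INCORRECT = "INCORRECT"
    FALSE_ALARM = "FALSE_ALARM"


@dataclass(frozen=True)
class Condition:
    """One cell of the 2×2 environment design."""

    length_class: LengthClass
    frequency_class: FrequencyClass

    @property
    def response_period_s(self) -> float:
        return 5.0 if self.length_class is LengthClass.LONG else 3.0

    @property
    def baseline_range_s(self) -> tuple[float, float]:
        if self.frequency_class is FrequencyClass.RARE:
            return (5.0, 40.0)
        return (3.0, 8.0)

    @property
    def name(self) -> str:
        return f"{self.length_class.value.lower()}-{self.frequency_class.value.lower()}"


#: The four distinct task conditions, keyed by "<length>-<frequency>".
CONDITIONS: dict[str, Condition] = {
    c.name: c
    for c in (
        Condition(lc, fc)
        for lc in (LengthClass.LONG, LengthClass.SHORT)
        for fc in (FrequencyClass.RARE, FrequencyClass.FREQUENT)
    )
}


@dataclass(frozen=True)
class TaskConfig:
    """Reward rule and noise-process parameters of the task."""

    reward_correct: float = 3.0
    penalty_incorrect: float = -3.0
    penalty_miss: float = -1.5
    penalty_false_alarm: float = -1.5
    response_tolerance_s: float = 0.5
    sd_baseline: float = 0.5
    sd_response: float = 0.3
    isi_mean_s: float = 0.270
    isi_min_s: float = 0.010
    isi_max_s: float = 1.000

    def __post_init__(self) -> None:
        if not (self.penalty_incorrect <= 0 <= self.reward_correct):
            raise ValueError("penalties must be <= 0 <= reward")
        if not (self.penalty_miss <= 0 and self.penalty_false_alarm <= 0):
            raise ValueError("penalties must be <= 0")
        if not (0 < self.isi_min_s < self.isi_mean_s < self.isi_max_s):
            raise ValueError("require 0 < isi_min_s < isi_mean_s < isi_max_s")


@dataclass(frozen=True)
class NoiseInterval:
    """A piecewise-constant segment of the coherence stream."""

    onset_s: float
    duration_s: float
    coherence: float


@dataclass
class Period:
    """One baseline or response period of a block's schedule."""

    kind: PeriodKind
    onset_s: float
    nominal_duration_s: float
    mean_coherence: float
    actual_end_s: float

    @property
    def nominal_end_s(self) -> float:
        return self.onset_s + self.nominal_duration_s


@dataclass
class PeriodSchedule:
    """Alternating baseline/response periods tiling a block."""

    periods: list[Period]

    def __iter__(self):
        return iter(self.periods)

    def __len__(self) -> int:
        return len(self.periods)

    def kind_at(self, t_s: float) -> PeriodKind:
        """Period kind at time ``t_s`` (by scheduled onsets)."""
        idx = self.index_at(t_s)
        return self.periods[idx].kind

    def index_at(self, t_s: float) -> int:
        onsets = np.array([p.onset_s for p in self.periods])
        idx = int(np.searchsorted(onsets, t_s, side="right") - 1)
        return max(idx, 0)

    def response_periods(self) -> list[Period]:
        return [p for p in self.periods if p.kind is PeriodKind.RESPONSE]

    def baseline_time_s(self) -> float:
        return float(
            sum(
                min(p.nominal_end_s, p.actual_end_s) - p.onset_s
                for p in self.periods
                if p.kind is PeriodKind.BASELINE
            )
        )

    def copy(self) -> "PeriodSchedule":
        return PeriodSchedule([replace(p) for p in self.periods])


@dataclass(frozen=True)
class ResponseEvent:
    """A buttonpress at ``time_s`` reporting net leftward/rightward motion."""

    time_s: float
    direction: Direction


@dataclass(frozen=True)
class ScoredResponse:
    event: ResponseEvent
    outcome: Outcome
    points: float
    period_index: Optional[int] = None
    rt_s: Optional[float] = None


@dataclass
class StimulusBlock:
    """A materialised stimulus block: per-sample coherence plus structure."""

    condition: Condition
    cfg: TaskConfig
    fs_hz: float
    duration_s: float
    coherence: np.ndarray
    intervals: list[NoiseInterval]
    schedule: PeriodSchedule
    seed: int

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


@dataclass
class ScoreResult:
    """Outcome of scoring a press sequence against a block."""

    scored: list[ScoredResponse]
    misses: int
    total_points: float
    schedule: PeriodSchedule

    @property
    def n_correct(self) -> int:
        return sum(1 for s in self.scored if s.outcome is Outcome.CORRECT)

    @property
    def n_incorrect(self) -> int:
        return sum(1 for s in self.scored if s.outcome is Outcome.INCORRECT)

    @property
    def n_false_alarm(self) -> int:
        return sum(1 for s in self.scored if s.outcome is Outcome.FALSE_ALARM)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_noise_intervals(
    total_duration_s: float, cfg: TaskConfig = TaskConfig(), seed=None
) -> np.ndarray:
    """Sample interval durations tiling ``total_duration_s``.

    Durations are exponential with mean ``cfg.isi_mean_s``, truncated to
    ``[cfg.isi_min_s, cfg.isi_max_s]`` by rejection resampling (which
    preserves the exponential shape within the bounds, unlike clipping).
    The final duration is clipped so the intervals exactly tile the block.

    Returns an array of durations in seconds summing to ``total_duration_s``.
    """
    if total_duration_s <= 0:
        raise ValueError("total_duration_s must be positive")
    rng = _as_rng(seed)
    # Expected draws ~ total/mean; sample in batches with rejection.
    durations: list[float] = []
    acc = 0.0
    while acc < total_duration_s:
        batch = rng.exponential(cfg.isi_mean_s, size=256)
        ok = batch[(batch >= cfg.isi_min_s) & (batch <= cfg.isi_max_s)]
        for d in ok:
            durations.append(float(d))
            acc += float(d)
            if acc >= total_duration_s:
                break
    # clip the tail so the tiling is exact
    overshoot = acc - total_duration_s
    durations[-1] -= overshoot
    if durations[-1] <= 0:  # tail smaller than float noise; drop it
        durations.pop()
    return np.asarray(durations)


def schedule_periods(
    condition: Condition, duration_s: float, seed=None
) -> PeriodSchedule:
    """Alternate baseline and response periods until the block is full.

    Baseline durations are Uniform over the condition's range; each response
    period's mean coherence is drawn uniformly from ``RESPONSE_MEANS``.  The
    final period is truncated at the block end; a truncated response period
    is kept only if at least one 10 ms sample of it remains.
    """
    lo, hi = condition.baseline_range_s
    if duration_s < lo + condition.response_period_s:
        raise ValueError(
            "duration_s too short for one baseline plus one response period"
        )
    rng = _as_rng(seed)
    periods: list[Period] = []
    t = 0.0
    while t < duration_s:
        b = float(rng.uniform(lo, hi))
        periods.append(
            Period(
                kind=PeriodKind.BASELINE,
                onset_s=t,
                nominal_duration_s=b,
                mean_coherence=0.0,
                actual_end_s=min(t + b, duration_s),
            )
        )
        t += b
        if t >= duration_s:
            break
        m = float(rng.choice(RESPONSE_MEANS))
        r = condition.response_period_s
        periods.append(
            Period(
                kind=PeriodKind.RESPONSE,
                onset_s=t,
                nominal_duration_s=r,
                mean_coherence=m,
                actual_end_s=min(t + r, duration_s),
            )
        )
        t += r
    # Drop a trailing response period shorter than one sample.
    last = periods[-1]
    if last.kind is PeriodKind.RESPONSE and last.actual_end_s - last.onset_s < 0.010:
        periods.pop()
    return PeriodSchedule(periods)


def generate_block(
    condition: Condition,
    cfg: TaskConfig = TaskConfig(),
    seed: int = 0,
    *,
    fs_hz: float = 100.0,
    duration_s: float = 300.0,
    schedule: Optional[PeriodSchedule] = None,
) -> StimulusBlock:
    """Generate one stimulus block.

    The root seed is split into independent sub-streams for the period
    schedule, the interval durations, and the coherence draws, so e.g. RARE
    and FREQUENT blocks with the same seed share identical noise draws.

    Each noise interval's coherence is drawn N(mean, SD) with mean/SD taken
    from the period active at the *interval onset*; draws outside [−1, +1]
    are set to ±1.  ``schedule`` may be supplied to override the sampled
    period schedule (useful for controlled experiments).
    """
    ss = np.random.SeedSequence(seed)
    s_sched, s_int, s_coh = ss.spawn(3)
    if schedule is None:
        schedule = schedule_periods(
            condition, duration_s, np.random.default_rng(s_sched)
        )
    durations = sample_noise_intervals(
        duration_s, cfg, np.random.default_rng(s_int)
    )
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])

    rng = np.random.default_rng(s_coh)
    period_onsets = np.array([p.onset_s for p in schedule.periods])
    idx = np.searchsorted(period_onsets, onsets, side="right") - 1
    idx = np.clip(idx, 0, len(schedule.periods) - 1)
    means = np.array([schedule.periods[i].mean_coherence for i in idx])
    sds = np.where(
        [schedule.periods[i].kind is PeriodKind.RESPONSE for i in idx],
        cfg.sd_response,
        cfg.sd_baseline,
    )
    coh = rng.normal(means, sds)
    coh = np.clip(coh, -1.0, 1.0)  # out-of-range draws set to ±1

    intervals = [
        NoiseInterval(onset_s=float(o), duration_s=float(d), coherence=float(c))
        for o, d, c in zip(onsets, durations, coh)
    ]

    # materialise at the sample grid; interval onsets rounded to nearest sample
    n = int(round(duration_s * fs_hz))
    series = np.empty(n)
    start_samples = np.minimum(np.round(onsets * fs_hz).astype(int), n - 1)
    bounds = np.concatenate([start_samples, [n]])
    for k in range(len(intervals)):
        series[bounds[k] : bounds[k + 1]] = coh[k]

    return StimulusBlock(
        condition=condition,
        cfg=cfg,
        fs_hz=fs_hz,
        duration_s=duration_s,
        coherence=series,
        intervals=intervals,
        schedule=schedule,
        seed=int(seed),
    )


def score_responses(
    block: StimulusBlock,
    responses: Sequence[ResponseEvent],
    cfg: Optional[TaskConfig] = None,
) -> ScoreResult:
    """Score a time-ordered press sequence against a block.

    A press inside a response period (or within ``response_tolerance_s``
    after its nominal end, if no earlier press claimed the period) is scored
    CORRECT when its direction matches the sign of the period's mean
    coherence, else INCORRECT; either terminates the period, recorded by
    setting ``actual_end_s`` to the press time.  Later presses — including
    presses after a claimed period's termination — are false alarms.
    Response periods never claimed count as misses.
    """
    if cfg is None:
        cfg = block.cfg
    times = [r.time_s for r in responses]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("responses must be sorted by time")

    schedule = block.schedule.copy()
    periods = schedule.periods
    claimed: set[int] = set()
    scored: list[ScoredResponse] = []

    for ev in responses:
        t = ev.time_s
        if not (0 <= t < block.duration_s):
            raise ValueError("response time outside block")
        attributed = None
        for i, p in enumerate(periods):
            if p.kind is not PeriodKind.RESPONSE or i in claimed:
                continue
            in_period = p.onset_s <= t < p.actual_end_s
            in_tolerance = p.actual_end_s <= t < p.actual_end_s + cfg.response_tolerance_s
            if in_period or in_tolerance:
                attributed = i
                break
        if attributed is None:
            scored.append(
                ScoredResponse(
                    event=ev,
                    outcome=Outcome.FALSE_ALARM,
                    points=cfg.penalty_false_alarm,
                )
            )
            continue
        p = periods[attributed]
        claimed.add(attributed)
        match = (ev.direction is Direction.RIGHT) == (p.mean_coherence > 0)
        outcome = Outcome.CORRECT if match else Outcome.INCORRECT
        points = cfg.reward_correct if match else cfg.penalty_incorrect
        # early termination: period ends at the press (never extended)
        p.actual_end_s = min(p.actual_end_s, t)
        scored.append(
            ScoredResponse(
                event=ev,
                outcome=outcome,
                points=points,
                period_index=attributed,
                rt_s=t - p.onset_s,
            )
        )

    misses = sum(
        1
        for i, p in enumerate(periods)
        if p.kind is PeriodKind.RESPONSE and i not in claimed
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
    return ScoreResult(
        scored=scored, misses=misses, total_points=float(total), schedule=schedule
    )
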