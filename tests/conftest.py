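import numpy as np
import pytest

from evaccum import stimgen


@pytest.fixture(scope="session")
def default_cfg():
    return stimgen.TaskConfig()


def make_block_from_series(
    coherence,
    schedule=None,
    condition=stimgen.CONDITIONS["long-rare"],
    cfg=stimgen.TaskConfig(),
    fs_hz=100.0,
):
    """Hand-built StimulusBlock around a given per-sample coherence series."""
    coherence = np.asarray(coherence, dtype=float)
    duration_s = len(coherence) / fs_hz
    if schedule is None:
        schedule = stimgen.PeriodSchedule(
            [
                stimgen.Period(
                    kind=stimgen.PeriodKind.BASELINE,
                    onset_s=0.0,
                    nominal_duration_s=duration_s,
                    mean_coherence=0.0,
                    actual_end_s=duration_s,
                )
            ]
        )
    intervals = [
        stimgen.NoiseInterval(onset_s=0.0, duration_s=duration_s,
                              coherence=float(coherence[0]))
    ]
    return stimgen.StimulusBlock(
        condition=condition,
        cfg=cfg,
        fs_hz=fs_hz,
        duration_s=duration_s,
        coherence=coherence,
        intervals=intervals,
        schedule=schedule,
        seed=0,
    )


def make_schedule(periods_spec, duration_s):
    """Schedule from (kind, onset, nominal_dur, mean) tuples."""
    periods = [
        stimgen.Period(
            kind=k,
            onset_s=o,
            nominal_duration_s=d,
            mean_coherence=m,
            actual_end_s=min(o + d, duration_s),
        )
        for (k, o, d, m) in periods_spec
    ]
    return stimgen.PeriodSchedule(periods)
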