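"""Serialisation of stimulus blocks, kernels, landscapes and TRF sets.

Array payloads go to NumPy ``.npz`` containers (self-describing named
arrays plus a JSON-encoded header); tabular views go to tab-separated
text for interoperability.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behaviour import ExponentialFit, IntegrationKernel
from .oumodel import GridSearchResult
from .stimgen import (
    CONDITIONS,
    NoiseInterval,
    Period,
    PeriodKind,
    PeriodSchedule,
    StimulusBlock,
    TaskConfig,
)
from .trf import TRFSet

__all__ = [
    "save_block",
    "load_block",
    "intervals_frame",
    "write_intervals_tsv",
    "write_kernel_tsv",
    "write_fit_tsv",
    "write_landscape_tsv",
    "save_trfset",
    "write_trf_tsv",
]


def intervals_frame(block: StimulusBlock) -> pd.DataFrame:
    """One row per noise interval with its period context."""
    rows = []
    for iv in block.intervals:
        p = block.schedule.periods[block.schedule.index_at(iv.onset_s)]
        rows.append(
            {
                "onset_s": iv.onset_s,
                "duration_s": iv.duration_s,
                "coherence": iv.coherence,
                "period_kind": p.kind.value,
                "period_mean": p.mean_coherence,
            }
        )
    return pd.DataFrame(rows)


def write_intervals_tsv(block: StimulusBlock, path) -> None:
    intervals_frame(block).to_csv(path, sep="\t", index=False)


def save_block(block: StimulusBlock, path) -> None:
    header = {
        "condition": block.condition.name,
        "cfg": dataclasses.asdict(block.cfg),
        "fs_hz": block.fs_hz,
        "duration_s": block.duration_s,
        "seed": block.seed,
    }
    sched = np.array(
        [
            (
                1.0 if p.kind is PeriodKind.RESPONSE else 0.0,
                p.onset_s,
                p.nominal_duration_s,
                p.mean_coherence,
                p.actual_end_s,
            )
            for p in block.schedule.periods
        ]
    )
    ivals = np.array(
        [(iv.onset_s, iv.duration_s, iv.coherence) for iv in block.intervals]
    )
    np.savez(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        coherence=block.coherence,
        schedule=sched,
        intervals=ivals,
    )


def load_block(path) -> StimulusBlock:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"].tobytes()).decode())
        coherence = z["coherence"]
        sched = z["schedule"]
        ivals = z["intervals"]
    periods = [
        Period(
            kind=PeriodKind.RESPONSE if row[0] > 0.5 else PeriodKind.BASELINE,
            onset_s=float(row[1]),
            nominal_duration_s=float(row[2]),
            mean_coherence=float(row[3]),
            actual_end_s=float(row[4]),
        )
        for row in sched
    ]
    intervals = [
        NoiseInterval(onset_s=float(r[0]), duration_s=float(r[1]), coherence=float(r[2]))
        for r in ivals
    ]
    return StimulusBlock(
        condition=CONDITIONS[header["condition"]],
        cfg=TaskConfig(**header["cfg"]),
        fs_hz=float(header["fs_hz"]),
        duration_s=float(header["duration_s"]),
        coherence=coherence,
        intervals=intervals,
        schedule=PeriodSchedule(periods),
        seed=int(header["seed"]),
    )


def write_kernel_tsv(kernel: IntegrationKernel, path) -> None:
    pd.DataFrame(
        {"lag_s": kernel.lags_s, "mean_evidence": kernel.mean_evidence}
    ).to_csv(path, sep="\t", index=False)


def write_fit_tsv(rows: list[dict], path) -> None:
    """Rows of (condition, event_class, A, tau_s, r_squared, n_events)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_landscape_tsv(result: GridSearchResult, path) -> None:
    rows = []
    for i, lv in enumerate(result.lambda_grid):
        for j, tv in enumerate(result.theta_grid):
            rows.append(
                {
                    "lambda": lv,
                    "theta": tv,
                    "mean_points": result.points[i, j],
                    "in_top_decile": bool(result.top_decile_mask[i, j]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_trfset(trfs: TRFSet, path) -> None:
    np.savez(
        path,
        betas=trfs.betas,
        lag_ms=trfs.column_index["lag_ms"].values.astype(float),
        regressor=np.array(trfs.column_index["regressor"].values, dtype="U32"),
        channel_labels=np.array(trfs.channel_labels, dtype="U32"),
        fs_hz=np.array([trfs.fs_hz]),
        n_valid_rows=np.array([trfs.n_valid_rows]),
        rank_deficient=np.array([trfs.rank_deficient]),
    )


def write_trf_tsv(trfs: TRFSet, path) -> None:
    trfs.to_frame().to_csv(path, sep="\t", index=False)
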