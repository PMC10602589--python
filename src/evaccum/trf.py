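"""Deconvolutional GLM: time-expanded design matrices and TRF estimation.

Continuous EEG recorded during the task is modelled as a superposition of
lagged responses to eleven regressors derived from the stimulus and the
response log: stick functions at coherence change-points ("jump events")
with parametric modulators (|new level|, |delta evidence|), the continuous
absolute and signed evidence, response-period onsets (with a coherence
modulator), and correct / false-alarm buttonpresses with signed twins.
Each regressor is "staircased" into one column per lag; ordinary least
squares on the concatenated matrix then recovers the temporal response
function (TRF) of every regressor at every channel, deconvolving the
overlap between nearby events.

Evidence-derived regressors are estimated from baseline periods only
(their values are zeroed during response periods), where the noise
statistics are identical across task conditions.

The module also synthesises continuous EEG from known ground-truth TRFs
for recovery testing, and reports the collinearity (squared correlation)
between the un-expanded evidence regressors over baseline samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .stimgen import (
    Direction,
    Outcome,
    PeriodKind,
    ScoreResult,
    StimulusBlock,
)

__all__ = [
    "RegressorSpec",
    "DEFAULT_SPECS",
    "DesignMatrix",
    "TRFSet",
    "SyntheticEEGConfig",
    "extract_regressor_streams",
    "build_design_matrix",
    "fit_trf",
    "simulate_eeg",
    "regressor_collinearity",
    "artifact_mask",
]

#: Regressors estimated from baseline periods only.
BASELINE_ONLY = (
    "jump_event",
    "jump_level",
    "jump_abs_delta",
    "cont_abs_evidence",
    "cont_signed_evidence",
)


@dataclass(frozen=True)
class RegressorSpec:
    """Lag window of one regressor in the time-expanded design."""

    name: str
    pre_ms: int
    post_ms: int
    kind: str  # stick | stick_modulated | continuous
    baseline_only: bool = False

    def n_lags(self, fs_hz: float = 100.0) -> int:
        step = 1000.0 / fs_hz
        return int(round((self.pre_ms + self.post_ms) / step)) + 1

    def lags_ms(self, fs_hz: float = 100.0) -> np.ndarray:
        step = 1000.0 / fs_hz
        return np.arange(-self.pre_ms, self.post_ms + step / 2, step)


#: The full 11-regressor model with its per-regressor lag windows
#: (251 / 301 / 851 columns each at 100 Hz).
DEFAULT_SPECS: tuple[RegressorSpec, ...] = (
    RegressorSpec("jump_event", 1000, 1500, "stick", True),
    RegressorSpec("jump_level", 1000, 1500, "stick_modulated", True),
    RegressorSpec("jump_abs_delta", 1500, 1500, "stick_modulated", True),
    RegressorSpec("cont_abs_evidence", 1500, 1500, "continuous", True),
    RegressorSpec("cont_signed_evidence", 1500, 1500, "continuous", True),
    RegressorSpec("bp_correct", 5000, 3500, "stick"),
    RegressorSpec("bp_correct_signed", 5000, 3500, "stick_modulated"),
    RegressorSpec("bp_false_alarm", 5000, 3500, "stick"),
    RegressorSpec("bp_false_alarm_signed", 5000, 3500, "stick_modulated"),
    RegressorSpec("resp_period_onset", 500, 8000, "stick"),
    RegressorSpec("resp_period_coherence", 500, 8000, "stick_modulated"),
)

SPEC_BY_NAME = {s.name: s for s in DEFAULT_SPECS}


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_samples, n_columns)
    column_index: pd.DataFrame  # columns: regressor, lag_ms
    valid_rows: np.ndarray  # boolean mask
    fs_hz: float

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def columns_for(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.column_index["regressor"].values == name)


@dataclass
class TRFSet:
    """Estimated per-channel, per-lag regression weights."""

    betas: np.ndarray  # (n_columns, n_channels)
    column_index: pd.DataFrame
    channel_labels: list[str]
    fs_hz: float
    n_valid_rows: int
    rank_deficient: bool = False

    def curve(self, name: str, channel: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """(lags_ms, beta) curve of one regressor at one channel."""
        sel = self.column_index["regressor"].values == name
        return (
            self.column_index.loc[sel, "lag_ms"].values.astype(float),
            self.betas[sel, channel],
        )

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for ch, label in enumerate(self.channel_labels):
            df = self.column_index.copy()
            df["channel"] = label
            df["beta"] = self.betas[:, ch]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass
class SyntheticEEGConfig:
    """Ground truth and noise model for synthetic continuous EEG."""

    truth: dict[str, np.ndarray]  # regressor name -> beta curve on its lag grid
    n_channels: int = 1
    spatial_weights: Optional[dict[str, np.ndarray]] = None  # name -> (n_channels,)
    noise_kind: str = "white"  # white | ar1
    noise_sd: float = 1.0
    ar_coef: float = 0.0

    def weight(self, name: str) -> np.ndarray:
        if self.spatial_weights and name in self.spatial_weights:
            return np.asarray(self.spatial_weights[name], dtype=float)
        return np.ones(self.n_channels)


def extract_regressor_streams(
    block: StimulusBlock, scored: Optional[ScoreResult] = None
) -> dict[str, np.ndarray]:
    """Derive the per-sample regressor series of one block.

    Stick regressors carry their value at the event sample and zero
    elsewhere; continuous regressors are valued at every sample.  The five
    evidence-derived regressors are zeroed outside baseline periods
    (baseline-only estimation); buttonpress and period-onset regressors
    span the whole block.  Jump values at the first interval take the
    pre-block coherence as 0.
    """
    fs = block.fs_hz
    n = len(block.coherence)
    streams = {name: np.zeros(n) for name in SPEC_BY_NAME}

    prev_c = 0.0
    for iv in block.intervals:
        s = min(int(round(iv.onset_s * fs)), n - 1)
        streams["jump_event"][s] = 1.0
        streams["jump_level"][s] = abs(iv.coherence)
        streams["jump_abs_delta"][s] = abs(iv.coherence - prev_c)
        prev_c = iv.coherence

    streams["cont_abs_evidence"][:] = np.abs(block.coherence)
    streams["cont_signed_evidence"][:] = block.coherence

    baseline = np.zeros(n, dtype=bool)
    for p in block.schedule.periods:
        if p.kind is PeriodKind.BASELINE:
            a = int(round(p.onset_s * fs))
            b = int(round(min(p.nominal_end_s, block.duration_s) * fs))
            baseline[a:b] = True
        else:
            s = min(int(round(p.onset_s * fs)), n - 1)
            streams["resp_period_onset"][s] = 1.0
            streams["resp_period_coherence"][s] = abs(p.mean_coherence)
    for name in BASELINE_ONLY:
        streams[name][~baseline] = 0.0

    if scored is not None:
        for sr in scored.scored:
            s = int(round(sr.event.time_s * fs))
            if s >= n:
                continue
            sign = 1.0 if sr.event.direction is Direction.RIGHT else -1.0
            if sr.outcome is Outcome.FALSE_ALARM:
                streams["bp_false_alarm"][s] = 1.0
                streams["bp_false_alarm_signed"][s] = sign
            else:
                streams["bp_correct"][s] = 1.0
                streams["bp_correct_signed"][s] = sign
    return streams


def build_design_matrix(
    streams: dict[str, np.ndarray],
    specs: Sequence[RegressorSpec] = DEFAULT_SPECS,
    fs_hz: float = 100.0,
    valid_rows: Optional[np.ndarray] = None,
) -> DesignMatrix:
    """Time-expand regressor streams into the deconvolutional design matrix.

    Each regressor contributes one column per lag from −pre_ms to +post_ms
    in sample steps; the column at lag ℓ holds the regressor value ℓ
    samples earlier (zero-padded at block edges), so a positive lag models
    activity after the event.
    """
    step_ms = 1000.0 / fs_hz
    n = len(next(iter(streams.values())))
    blocks = []
    idx_rows = []
    for spec in specs:
        if (spec.pre_ms % step_ms) or (spec.post_ms % step_ms):
            raise ValueError(
                f"{spec.name}: lag window must be a multiple of the sample step"
            )
        x = np.asarray(streams[spec.name], dtype=float)
        if len(x) != n:
            raise ValueError("all streams must share the sample grid")
        pre_n = int(round(spec.pre_ms / step_ms))
        post_n = int(round(spec.post_ms / step_ms))
        cols = np.zeros((n, pre_n + post_n + 1))
        for c, lag in enumerate(range(-pre_n, post_n + 1)):
            if lag >= 0:
                cols[lag:, c] = x[: n - lag] if lag else x
            else:
                cols[:lag, c] = x[-lag:]
            idx_rows.append({"regressor": spec.name, "lag_ms": lag * step_ms})
        blocks.append(cols)
    matrix = np.concatenate(blocks, axis=1)
    if valid_rows is None:
        valid_rows = np.ones(n, dtype=bool)
    return DesignMatrix(
        matrix=matrix,
        column_index=pd.DataFrame(idx_rows),
        valid_rows=np.asarray(valid_rows, dtype=bool),
        fs_hz=fs_hz,
    )


def fit_trf(
    X: DesignMatrix,
    Y: np.ndarray,
    valid_rows: Optional[np.ndarray] = None,
    channel_labels: Optional[Sequence[str]] = None,
) -> TRFSet:
    """Ordinary-least-squares TRF estimation from continuous data.

    ``Y`` is (n_samples,) or (n_samples, n_channels).  Masked rows are
    dropped from both sides.  The normal equations are solved by Cholesky
    factorisation; on rank deficiency the minimum-norm solution is taken
    via the pseudoinverse and flagged in the metadata with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.matrix.shape[0]:
        raise ValueError("X and Y must have aligned rows")
    mask = X.valid_rows if valid_rows is None else np.asarray(valid_rows, bool)
    Xv = X.matrix[mask]
    Yv = Y[mask]
    rank_deficient = Xv.shape[0] < Xv.shape[1]

    G = Xv.T @ Xv
    b = Xv.T @ Yv
    try:
        if rank_deficient:
            raise LinAlgError("fewer valid rows than columns")
        betas = cho_solve(cho_factor(G), b)
    except (LinAlgError, np.linalg.LinAlgError):
        rank_deficient = True
        warnings.warn(
            "design matrix is rank deficient; returning minimum-norm solution",
            RuntimeWarning,
        )
        betas = np.linalg.pinv(G) @ b

    if channel_labels is None:
        channel_labels = [f"ch{c}" for c in range(Y.shape[1])]
    return TRFSet(
        betas=betas,
        column_index=X.column_index.copy(),
        channel_labels=list(channel_labels),
        fs_hz=X.fs_hz,
        n_valid_rows=int(mask.sum()),
        rank_deficient=rank_deficient,
    )


def _convolve_lagged(stream: np.ndarray, beta: np.ndarray, pre_n: int) -> np.ndarray:
    """y[s] = sum_l stream[s - l] * beta[l], lags l = -pre_n .. +post_n."""
    full = np.convolve(stream, beta)
    return full[pre_n : pre_n + len(stream)]


def simulate_eeg(
    block: StimulusBlock,
    scored: Optional[ScoreResult],
    cfg: SyntheticEEGConfig,
    seed=None,
    specs: Sequence[RegressorSpec] = DEFAULT_SPECS,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Synthesise continuous multichannel EEG from known ground-truth TRFs.

    Y[:, c] = sum_r convolve(stream_r, truth_r) * weight_r[c] + noise.
    Returns (Y of shape (n_samples, n_channels), the exact truth curves
    used).  Noise is white Gaussian or AR(1) with innovation SD
    ``noise_sd``.
    """
    streams = extract_regressor_streams(block, scored)
    spec_by_name = {s.name: s for s in specs}
    n = len(block.coherence)
    Y = np.zeros((n, cfg.n_channels))
    step_ms = 1000.0 / block.fs_hz
    for name, curve in cfg.truth.items():
        spec = spec_by_name[name]
        curve = np.asarray(curve, dtype=float)
        if len(curve) != spec.n_lags(block.fs_hz):
            raise ValueError(f"{name}: truth curve length must match the lag grid")
        pre_n = int(round(spec.pre_ms / step_ms))
        contrib = _convolve_lagged(streams[name], curve, pre_n)
        Y += contrib[:, None] * cfg.weight(name)[None, :]
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, cfg.noise_sd, size=Y.shape)
        if cfg.noise_kind == "ar1":
            for t in range(1, n):
                eps[t] += cfg.ar_coef * eps[t - 1]
        elif cfg.noise_kind != "white":
            raise ValueError("noise_kind must be 'white' or 'ar1'")
        Y += eps
    return Y, dict(cfg.truth)


def regressor_collinearity(
    streams: dict[str, np.ndarray],
    baseline_mask: Optional[np.ndarray] = None,
    names: Sequence[str] = (
        "jump_event",
        "jump_level",
        "jump_abs_delta",
        "cont_abs_evidence",
    ),
) -> pd.DataFrame:
    """Pairwise squared correlation of un-expanded regressors.

    Computed over baseline samples (the streams are already zeroed
    elsewhere when derived from :func:`extract_regressor_streams`); a
    zero-variance series yields NaN entries.
    """
    table = np.ones((len(names), len(names)))
    series = []
    for nm in names:
        x = np.asarray(streams[nm], dtype=float)
        if baseline_mask is not None:
            x = x[baseline_mask]
        series.append(x)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            xi, xj = series[i], series[j]
            if xi.std() == 0 or xj.std() == 0:
                r2 = np.nan
            else:
                r2 = float(np.corrcoef(xi, xj)[0, 1] ** 2)
            table[i, j] = table[j, i] = r2
    return pd.DataFrame(table, index=list(names), columns=list(names))


def artifact_mask(
    Y: np.ndarray, fs_hz: float = 100.0, threshold_uv: float = 100.0,
    window_s: float = 0.5,
) -> np.ndarray:
    """Valid-row mask excluding ±window_s around any |sample| ≥ threshold."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    bad = np.flatnonzero(np.any(np.abs(Y) >= threshold_uv, axis=1))
    mask = np.ones(Y.shape[0], dtype=bool)
    half = int(round(window_s * fs_hz))
    for b in bad:
        mask[max(0, b - half) : b + half + 1] = False
    return mask
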