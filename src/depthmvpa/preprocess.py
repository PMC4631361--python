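"""From run time series to normalized, averaged voxel patterns.

Fixed pipeline order: high-pass/detrend -> hemodynamic shift -> voxel
ranking -> per-trial extraction -> within-condition trial averaging ->
per-run z-scoring -> per-pattern mean subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import EventTable, parse_condition
from .synthetic_data import RunTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PatternSet",
    "VoxelRanking",
    "TrialPatterns",
    "highpass_detrend",
    "shift_timeseries",
    "rank_voxels",
    "extract_trial_patterns",
    "average_trials",
    "normalize",
    "preprocess_runs",
]


@dataclass
class PatternSet:
    """Labeled voxel patterns: one row per (run, condition, group) average."""

    patterns: np.ndarray           # n_patterns x n_voxels
    levels: np.ndarray             # signal level per pattern
    signs: np.ndarray              # +1 near / -1 far per pattern
    run_ids: np.ndarray
    voxel_index: np.ndarray        # retained voxel identifiers
    zero_variance_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        self.signs = np.asarray(self.signs, dtype=int)
        self.run_ids = np.asarray(self.run_ids, dtype=int)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        n = len(self.patterns)
        if not (len(self.levels) == len(self.signs) == len(self.run_ids) == n):
            raise ValueError("labels must align with pattern rows")
        if self.patterns.shape[1] != len(self.voxel_index):
            raise ValueError("voxel_index must align with pattern columns")

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def select(self, mask: np.ndarray) -> "PatternSet":
        return PatternSet(
            self.patterns[mask],
            self.levels[mask],
            self.signs[mask],
            self.run_ids[mask],
            self.voxel_index,
            self.zero_variance_voxels,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.patterns, columns=[f"v{int(v)}" for v in self.voxel_index])
        df.insert(0, "run", self.run_ids)
        df.insert(1, "level", self.levels)
        df.insert(2, "sign", self.signs)
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PatternSet":
        df = pd.read_csv(path, sep="\t")
        vox_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        return cls(
            df[vox_cols].to_numpy(),
            df["level"].to_numpy(),
            df["sign"].to_numpy(),
            df["run"].to_numpy(),
            np.array([int(c[1:]) for c in vox_cols]),
        )


@dataclass
class VoxelRanking:
    """Per-voxel stimulus-vs-fixation t values and the retained subset."""

    t_values: np.ndarray
    retained: np.ndarray  # voxel indices, descending t, t > 0 only, at most k

    def to_tsv(self, path: str | Path) -> None:
        retained = set(self.retained.tolist())
        pd.DataFrame(
            {
                "voxel": np.arange(len(self.t_values)),
                "t": self.t_values,
                "retained": [int(v in retained) for v in range(len(self.t_values))],
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.8g")


@dataclass
class TrialPatterns:
    """Raw per-trial patterns (stimulus trials only), in presentation order."""

    patterns: np.ndarray
    levels: np.ndarray
    signs: np.ndarray
    run_ids: np.ndarray


def highpass_detrend(ts: RunTimeSeries, cycles_cutoff: int = 3) -> RunTimeSeries:
    """Remove each voxel's linear trend and Fourier components at
    1..cycles_cutoff cycles per run.

    The least-squares line (with intercept) is subtracted first, so the
    output is mean-zero per voxel; discrete-Fourier bins 1..cutoff are then
    zeroed.
    """
    if cycles_cutoff < 1:
        raise ValueError("cycles_cutoff must be >= 1")
    n = ts.n_volumes
    t = np.arange(n, dtype=float)
    # joint projection keeps untargeted frequencies essentially untouched
    cols = [np.ones(n), t]
    for c in range(1, cycles_cutoff + 1):
        cols.append(np.cos(2 * np.pi * c * t / n))
        cols.append(np.sin(2 * np.pi * c * t / n))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    out = ts.data - X @ beta
    return RunTimeSeries(out, tr=ts.tr, run_id=ts.run_id, roi_name=ts.roi_name)


def shift_timeseries(ts: RunTimeSeries, delay_volumes: int = 3) -> RunTimeSeries:
    """Advance the series by ``delay_volumes`` (hemodynamic delay); trailing
    volumes are dropped and event onsets are left untouched."""
    if delay_volumes < 0:
        raise ValueError("delay_volumes must be >= 0")
    if delay_volumes >= ts.n_volumes:
        raise ValueError("delay_volumes must be smaller than the number of volumes")
    return RunTimeSeries(
        ts.data[delay_volumes:], tr=ts.tr, run_id=ts.run_id, roi_name=ts.roi_name
    )


def _trial_windows(events: EventTable, tr: float, response_width: int):
    """Yield (volume_start, sign, level, dummy) per trial; 0-based half-open."""
    for onset, label, dummy in zip(
        events.frame["onset"], events.frame["trial_type"], events.frame["dummy"]
    ):
        sign, level = parse_condition(label)
        yield int(round(onset / tr)), sign, level, bool(dummy)


def rank_voxels(
    runs: Sequence[RunTimeSeries],
    events: Sequence[EventTable],
    k: int = 300,
    response_width: int = 2,
) -> VoxelRanking:
    """Rank voxels by a two-sample t statistic of stimulus vs fixation volumes.

    Volumes inside stimulus-trial windows (all conditions, all runs, dummy
    excluded) form one sample and fixation-trial volumes the other; the
    pooled-variance t is computed per voxel.  Voxels with t > 0 are ordered
    by descending t (ties broken by ascending index) and the top ``k`` (or
    all available, if fewer) are retained.
    """
    stim_rows, fix_rows = [], []
    for ts, ev in zip(runs, events):
        for v0, sign, _level, dummy in _trial_windows(ev, ts.tr, response_width):
            if dummy:
                continue
            if v0 + response_width > ts.n_volumes:
                raise ValueError("trial window exceeds the (shifted) run")
            window = ts.data[v0 : v0 + response_width]
            (fix_rows if sign == 0 else stim_rows).append(window)
    if not fix_rows:
        raise ValueError("no fixation trials: cannot form a baseline contrast")
    if not stim_rows:
        raise ValueError("no stimulus trials")
    stim = np.concatenate(stim_rows, axis=0)
    fix = np.concatenate(fix_rows, axis=0)
    t = stats.ttest_ind(stim, fix, axis=0, equal_var=True).statistic
    t = np.asarray(t)
    positive = np.flatnonzero(np.nan_to_num(t, nan=-np.inf) > 0)
    # stable sort on -t keeps ascending voxel index among exact ties
    order = positive[np.argsort(-t[positive], kind="stable")]
    return VoxelRanking(t_values=t, retained=order[:k])


def extract_trial_patterns(
    ts_shifted: RunTimeSeries,
    events: EventTable,
    response_width: int = 2,
) -> TrialPatterns:
    """Average each stimulus trial's ``response_width`` volumes into a pattern.

    The window starts at ``round(onset / tr)`` in the shifted series.
    Fixation and dummy trials yield no pattern.
    """
    pats, lvls, sgns = [], [], []
    for v0, sign, level, dummy in _trial_windows(events, ts_shifted.tr, response_width):
        if v0 + response_width > ts_shifted.n_volumes:
            raise ValueError(
                f"trial window [{v0}, {v0 + response_width}) exceeds the shifted run "
                f"({ts_shifted.n_volumes} volumes)"
            )
        if dummy or sign == 0:
            continue
        pats.append(ts_shifted.data[v0 : v0 + response_width].mean(axis=0))
        lvls.append(level)
        sgns.append(sign)
    return TrialPatterns(
        patterns=np.asarray(pats),
        levels=np.asarray(lvls, dtype=float),
        signs=np.asarray(sgns, dtype=int),
        run_ids=np.full(len(pats), ts_shifted.run_id, dtype=int),
    )


def average_trials(
    raw: TrialPatterns | Sequence[TrialPatterns],
    grouping: Sequence[int] = (4, 4, 3),
    voxel_index: np.ndarray | None = None,
) -> PatternSet:
    """Average consecutive trials within each (run, condition) into patterns.

    Trials are taken in presentation order and split into groups of sizes
    ``grouping`` (default 4, 4, 3 -> three averaged patterns from 11
    trials).  Every (run, condition) cell must contain exactly
    ``sum(grouping)`` trials.
    """
    if isinstance(raw, TrialPatterns):
        raw = [raw]
    grouping = tuple(int(g) for g in grouping)
    if any(g < 1 for g in grouping):
        raise ValueError("grouping sizes must be positive")
    need = sum(grouping)
    pats, lvls, sgns, rids = [], [], [], []
    for tp in raw:
        keys = sorted(set(zip(tp.levels, tp.signs)))
        for level, sign in keys:
            idx = np.flatnonzero((tp.levels == level) & (tp.signs == sign))
            if len(idx) != need:
                run = tp.run_ids[0] if len(tp.run_ids) else "?"
                raise ValueError(
                    f"run {run}, condition (level={level:g}, sign={sign:+d}): "
                    f"{len(idx)} trials, expected {need} for grouping {grouping}"
                )
            pos = 0
            for g in grouping:
                pats.append(tp.patterns[idx[pos : pos + g]].mean(axis=0))
                lvls.append(level)
                sgns.append(sign)
                rids.append(tp.run_ids[0])
                pos += g
    pats = np.asarray(pats)
    if voxel_index is None:
        voxel_index = np.arange(pats.shape[1])
    return PatternSet(pats, lvls, sgns, rids, voxel_index)


def normalize(ps: PatternSet, zscore: bool = True) -> PatternSet:
    """Per run, z-score each voxel across patterns, then subtract each
    pattern's cross-voxel mean.

    Zero-variance voxels are set to zero and recorded in
    ``zero_variance_voxels``.  Set ``zscore=False`` when the raw series were
    z-scored upstream; the cross-voxel mean subtraction still applies.
    """
    out = ps.patterns.astype(float).copy()
    flagged: set[int] = set()
    if zscore:
        for run in np.unique(ps.run_ids):
            rows = ps.run_ids == run
            if rows.sum() < 2:
                raise ValueError(f"run {run} has fewer than 2 patterns")
            block = out[rows]
            mean = block.mean(axis=0)
            sd = block.std(axis=0)
            dead = sd == 0
            sd_safe = np.where(dead, 1.0, sd)
            out[rows] = (block - mean) / sd_safe
            out[np.ix_(rows, dead)] = 0.0
            flagged.update(ps.voxel_index[dead].tolist())
        if flagged:
            logger.warning("zero-variance voxels zeroed during z-scoring: %s", sorted(flagged))
    out -= out.mean(axis=1, keepdims=True)
    return PatternSet(
        out,
        ps.levels,
        ps.signs,
        ps.run_ids,
        ps.voxel_index,
        np.array(sorted(flagged), dtype=int),
    )


def zscore_series(ts: RunTimeSeries) -> RunTimeSeries:
    """Z-score each voxel's time series within the run (alternative stage)."""
    sd = ts.data.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return RunTimeSeries(
        (ts.data - ts.data.mean(axis=0)) / sd, tr=ts.tr, run_id=ts.run_id, roi_name=ts.roi_name
    )


def preprocess_runs(
    runs: Sequence[RunTimeSeries],
    events: Sequence[EventTable],
    k: int = 300,
    cycles_cutoff: int = 3,
    delay_volumes: int = 3,
    response_width: int = 2,
    grouping: Sequence[int] = (4, 4, 3),
    zscore_stage: str = "patterns",
) -> PatternSet:
    """Full preprocessing pipeline across runs; returns the combined PatternSet.

    ``zscore_stage`` selects where per-run z-scoring happens: on the averaged
    patterns (default) or on the shifted raw series ('series').
    """
    if zscore_stage not in ("patterns", "series"):
        raise ValueError("zscore_stage must be 'patterns' or 'series'")
    if len(runs) != len(events):
        raise ValueError("runs and events must align")
    clean = [highpass_detrend(ts, cycles_cutoff) for ts in runs]
    shifted = [shift_timeseries(ts, delay_volumes) for ts in clean]
    ranking = rank_voxels(shifted, events, k=k, response_width=response_width)
    if zscore_stage == "series":
        shifted = [zscore_series(ts) for ts in shifted]
    raw = []
    for ts, ev in zip(shifted, events):
        tp = extract_trial_patterns(ts, ev, response_width=response_width)
        tp.patterns = tp.patterns[:, ranking.retained]
        raw.append(tp)
    ps = average_trials(raw, grouping=grouping, voxel_index=ranking.retained)
    return normalize(ps, zscore=(zscore_stage == "patterns"))
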