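"""Synthetic ROI voxel time series and in-scanner behavior.

The generative model matches what the downstream analysis assumes rather
than scanner physics: each non-fixation trial adds a delayed boxcar
increment ``amplitude_max * g(level) * sign * selectivity_v`` to
``response_width`` volumes starting ``delay_volumes`` after the trial onset,
on top of a baseline, slow drift, and i.i.d. Gaussian noise.  Behavioral
responses are Bernoulli draws from a psychometric function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .design import EventTable, assign_timing, generate_balanced_sequence, make_conditions, parse_condition
from .psychometrics import PsychometricFunction

__all__ = [
    "RunTimeSeries",
    "RoiSimConfig",
    "linear_coupling",
    "psychometric_coupling",
    "step_coupling",
    "zero_coupling",
    "simulate_roi_run",
    "simulate_experiment",
]


# ---------------------------------------------------------------------------
# coupling maps: signal level -> signal fraction in [0, 1]

def linear_coupling(max_level: float) -> Callable[[float], float]:
    return lambda level: float(level) / float(max_level)


def psychometric_coupling(pf: PsychometricFunction, max_level: float, min_level: float = 0.0) -> Callable[[float], float]:
    """Coupling proportional to the observer's above-chance performance."""
    if min_level > 0:
        lo = float(pf.predict([min_level])[0])
    elif pf.axis == "linear":
        lo = float(pf.predict([0.0])[0])
    else:
        lo = pf.guess
    hi = float(pf.predict([max_level])[0])
    if hi <= lo:
        raise ValueError("psychometric coupling needs hi > lo performance")

    def g(level: float) -> float:
        if level <= min_level:
            return 0.0
        return (float(pf.predict([level])[0]) - lo) / (hi - lo)

    return g


def step_coupling(max_level: float) -> Callable[[float], float]:
    """Full signal only at the top level; nothing below it."""
    return lambda level: 1.0 if level >= max_level else 0.0


def zero_coupling(level: float) -> float:
    return 0.0


@dataclass
class RunTimeSeries:
    """Volumes x voxels response matrix for one run of one ROI."""

    data: np.ndarray
    tr: float
    run_id: int = 0
    roi_name: str = "ROI"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a volumes x voxels matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV plus a JSON sidecar with tr/run/ROI."""
        path = Path(path)
        np.savetxt(path, self.data, delimiter="\t", fmt="%.8g")
        meta = {"tr": self.tr, "run_id": self.run_id, "roi_name": self.roi_name}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RunTimeSeries":
        path = Path(path)
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(data=data, **meta)


@dataclass
class RoiSimConfig:
    """Generative parameters for one synthetic ROI.

    ``selectivity`` holds per-voxel preferences in [-1, 1]; when None it is
    drawn once per experiment from ``selectivity_dist`` ('uniform' on [-1,1]
    or 'bimodal' at +/-1).  ``coupling`` maps signal level to [0, 1].
    """

    n_voxels: int = 300
    amplitude_max: float = 1.0
    activation: float = 0.0  # nonselective response of every voxel to any stimulus
    noise_sd: float = 1.0
    coupling: Callable[[float], float] = field(default=zero_coupling)
    selectivity: np.ndarray | None = None
    selectivity_dist: str = "uniform"
    baseline: float = 100.0
    drift_slope: float = 0.0
    drift_sine_amp: float = 0.0
    delay_volumes: int = 3
    response_width: int = 2
    roi_name: str = "ROI"

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.delay_volumes < 0:
            raise ValueError("delay_volumes must be >= 0")
        if self.response_width < 1:
            raise ValueError("response_width must be >= 1")
        if self.selectivity_dist not in ("uniform", "bimodal"):
            raise ValueError("selectivity_dist must be 'uniform' or 'bimodal'")
        if self.selectivity is not None:
            self.selectivity = np.asarray(self.selectivity, dtype=float)
            if self.selectivity.shape != (self.n_voxels,):
                raise ValueError("selectivity must have shape (n_voxels,)")

    def draw_selectivity(self, rng: np.random.Generator) -> np.ndarray:
        if self.selectivity is not None:
            return self.selectivity
        if self.selectivity_dist == "bimodal":
            return rng.choice([-1.0, 1.0], size=self.n_voxels)
        return rng.uniform(-1.0, 1.0, size=self.n_voxels)


def simulate_roi_run(
    cfg: RoiSimConfig,
    events: EventTable,
    tr: float,
    seed: int,
) -> RunTimeSeries:
    """Generate one run's volumes x voxels matrix for the given event table."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    n_vol_f = events.total_duration / tr
    n_vol = int(round(n_vol_f))
    if abs(n_vol_f - n_vol) > 1e-9:
        raise ValueError("run duration must be an integer number of volumes")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sel_rng, noise_rng, drift_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    sel = cfg.draw_selectivity(sel_rng)

    data = np.full((n_vol, cfg.n_voxels), cfg.baseline, dtype=float)

    # slow drift: shared linear ramp + one-cycle sinusoid with per-voxel phase
    if cfg.drift_slope or cfg.drift_sine_amp:
        t = np.arange(n_vol) / max(n_vol - 1, 1)
        data += cfg.drift_slope * (t - 0.5)[:, None]
        if cfg.drift_sine_amp:
            phase = drift_rng.uniform(0, 2 * np.pi, size=cfg.n_voxels)
            data += cfg.drift_sine_amp * np.sin(2 * np.pi * t[:, None] + phase[None, :])

    for onset, label in zip(events.frame["onset"], events.frame["trial_type"]):
        sign, level = parse_condition(label)
        if sign == 0:
            continue
        v0 = int(round(onset / tr)) + cfg.delay_volumes
        if v0 + cfg.response_width > n_vol:
            raise ValueError(
                f"trial at onset {onset}s (+delay) extends past the run end "
                f"({v0 + cfg.response_width} > {n_vol} volumes)"
            )
        g = float(cfg.coupling(level))
        data[v0 : v0 + cfg.response_width, :] += (
            cfg.activation + cfg.amplitude_max * g * sign * sel[None, :]
        )

    if cfg.noise_sd:
        data += noise_rng.normal(0.0, cfg.noise_sd, size=data.shape)
    return RunTimeSeries(data=data, tr=tr, run_id=events.run_id, roi_name=cfg.roi_name)


def simulate_experiment(
    cfgs: RoiSimConfig | Mapping[str, RoiSimConfig],
    pf: PsychometricFunction,
    n_runs: int,
    seed: int,
    levels: Sequence[float] = (0, 20, 40, 60, 100),
    reps: int = 11,
    tr: float = 1.5,
    trial_duration: float = 3.0,
    lead_fixation: float = 9.0,
    tail_fixation: float = 9.0,
) -> tuple[dict[str, list[RunTimeSeries]], list[EventTable]]:
    """Simulate a whole session: per-run sequences, ROI matrices, responses.

    Every ROI shares the run event tables; each ROI's voxel selectivity is
    drawn once and reused across runs.  Behavioral correctness is drawn per
    non-fixation trial from ``pf`` at that trial's level; the recorded
    response is the true sign when correct and its opposite otherwise.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 (leave-one-run-out needs >= 2 runs)")
    if isinstance(cfgs, RoiSimConfig):
        cfgs = {cfgs.roi_name: cfgs}

    conditions = make_conditions(levels)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    roi_ss, run_ss = ss.spawn(2)
    roi_seeds = {name: s for name, s in zip(sorted(cfgs), roi_ss.spawn(len(cfgs)))}

    # fix each ROI's selectivity once so it is identical across runs
    fixed_cfgs = {}
    for name in sorted(cfgs):
        cfg = cfgs[name]
        sel = cfg.draw_selectivity(np.random.default_rng(roi_seeds[name]))
        fixed_cfgs[name] = replace(cfg, selectivity=sel, roi_name=name)

    runs_by_roi: dict[str, list[RunTimeSeries]] = {name: [] for name in fixed_cfgs}
    event_tables: list[EventTable] = []
    for run_id, run_seed in enumerate(run_ss.spawn(n_runs)):
        seq_s, tim_s, beh_s, *roi_s = run_seed.spawn(3 + len(fixed_cfgs))
        seq = generate_balanced_sequence(conditions, reps, seed=seq_s, run_id=run_id)
        events = assign_timing(
            seq,
            trial_duration=trial_duration,
            lead_fixation=lead_fixation,
            tail_fixation=tail_fixation,
            seed=tim_s,
        )

        # behavioral responses
        rng = np.random.default_rng(beh_s)
        signs, levels_t, resp, corr = [], [], [], []
        for label in events.frame["trial_type"]:
            sign, level = parse_condition(label)
            if sign == 0:
                resp.append(np.nan)
                corr.append(np.nan)
                continue
            p = float(pf.predict([level])[0]) if (pf.axis == "linear" or level > 0) else pf.guess
            ok = rng.random() < p
            resp.append(sign if ok else -sign)
            corr.append(1.0 if ok else 0.0)
        events.frame["response"] = resp
        events.frame["correct"] = corr
        event_tables.append(events)

        for name, rs in zip(sorted(fixed_cfgs), roi_s):
            runs_by_roi[name].append(simulate_roi_run(fixed_cfgs[name], events, tr=tr, seed=rs))
    return runs_by_roi, event_tables
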