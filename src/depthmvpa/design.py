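"""Event-related trial sequences balanced for one-trial-back history.

A run presents ``n_conditions`` condition labels ``reps`` times each, in an
order where every ordered pair of conditions (self-pairs included) occurs
equally often as a consecutive transition.  Such an order is exactly an
Eulerian circuit on the complete digraph with self-loops whose every arc has
multiplicity ``reps / n_conditions``; the circuit's start vertex is prepended
as an unanalyzed dummy trial so the second trial's history is balanced too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FIXATION = "fixation"

__all__ = [
    "FIXATION",
    "TrialSequence",
    "EventTable",
    "make_conditions",
    "parse_condition",
    "generate_balanced_sequence",
    "assign_timing",
]


def make_conditions(levels: Sequence[float], signs: Sequence[str] = ("near", "far")) -> list[str]:
    """Condition labels for a depth-sign experiment: fixation + sign:level pairs."""
    labels = [FIXATION]
    for lv in levels:
        for s in signs:
            labels.append(f"{s}:{lv:g}")
    return labels


def parse_condition(label: str) -> tuple[int, float | None]:
    """Return ``(sign, level)`` for a condition label.

    Sign is +1 for near, -1 for far, 0 for fixation (level ``None``).
    """
    if label == FIXATION:
        return 0, None
    sign_name, _, lv = label.partition(":")
    if sign_name not in ("near", "far") or not lv:
        raise ValueError(f"unparseable condition label: {label!r}")
    return (1 if sign_name == "near" else -1), float(lv)


@dataclass
class TrialSequence:
    """Ordered condition labels for one run; trial 0 is an unanalyzed dummy."""

    conditions: list[str]
    dummy_first: bool = True
    run_id: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.conditions)

    @property
    def analyzed(self) -> list[str]:
        return self.conditions[1:] if self.dummy_first else list(self.conditions)

    def labels(self) -> list[str]:
        """Distinct condition labels in first-appearance order."""
        return list(dict.fromkeys(self.conditions))

    def transition_counts(self) -> pd.DataFrame:
        """Counts of consecutive ordered pairs (rows: from, cols: to)."""
        labs = sorted(set(self.conditions))
        idx = {c: i for i, c in enumerate(labs)}
        mat = np.zeros((len(labs), len(labs)), dtype=int)
        for a, b in zip(self.conditions[:-1], self.conditions[1:]):
            mat[idx[a], idx[b]] += 1
        return pd.DataFrame(mat, index=labs, columns=labs)


def generate_balanced_sequence(
    conditions: int | Sequence[str], reps: int, seed: int, run_id: int = 0
) -> TrialSequence:
    """Generate a trial order whose one-back transition counts are uniform.

    Parameters
    ----------
    conditions : int or sequence of str
        Number of conditions (generic labels ``c0..``) or explicit labels.
    reps : int
        Repetitions of each condition among analyzed trials.  Must be a
        positive multiple of the number of conditions so that every ordered
        pair can occur ``reps / n_conditions`` times.
    seed : int
        Seed for the random Eulerian circuit.

    Returns
    -------
    TrialSequence
        ``n_conditions * reps + 1`` trials; the first is the dummy.
    """
    if isinstance(conditions, int):
        labels = [f"c{i}" for i in range(conditions)]
    else:
        labels = list(conditions)
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be distinct")
    n = len(labels)
    if n < 1:
        raise ValueError("need at least one condition")
    if reps <= 0 or reps % n != 0:
        raise ValueError(
            f"reps={reps} must be a positive multiple of n_conditions={n} so that "
            f"each ordered condition pair can occur an equal whole number of times"
        )
    mult = reps // n

    rng = np.random.default_rng(seed)
    # Arc lists of the complete digraph with self-loops, each arc `mult` times,
    # in seeded random order.  Hierholzer's algorithm then emits a random
    # Eulerian circuit (the graph is regular and strongly connected).
    adj = []
    for _ in range(n):
        targets = np.repeat(np.arange(n), mult)
        rng.shuffle(targets)
        adj.append(targets)
    ptr = [0] * n
    start = int(rng.integers(n))
    stack = [start]
    circuit: list[int] = []
    while stack:
        v = stack[-1]
        if ptr[v] < len(adj[v]):
            stack.append(int(adj[v][ptr[v]]))
            ptr[v] += 1
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    assert len(circuit) == n * reps + 1 and circuit[0] == circuit[-1] == start
    # the circuit's n*reps arcs give n*reps+1 vertices: dummy + analyzed trials
    seq = [labels[i] for i in circuit]
    return TrialSequence(conditions=seq, dummy_first=True, run_id=run_id)


@dataclass
class EventTable:
    """Per-trial timing and labels for one run.

    ``frame`` columns: onset, duration (stimulus), delay, cue_onset,
    cue_offset, trial_type, dummy; simulation may append response/correct.
    """

    frame: pd.DataFrame
    run_id: int = 0
    trial_duration: float = 3.0
    lead_fixation: float = 9.0
    tail_fixation: float = 9.0

    @property
    def n_trials(self) -> int:
        return len(self.frame)

    @property
    def total_duration(self) -> float:
        return self.lead_fixation + self.trial_duration * self.n_trials + self.tail_fixation

    def analyzed(self) -> pd.DataFrame:
        return self.frame[self.frame["dummy"] == 0]

    def to_tsv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write BIDS-events-style TSV (plus a JSON sidecar with run metadata)."""
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        if sidecar:
            meta = {
                "run_id": self.run_id,
                "trial_duration": self.trial_duration,
                "lead_fixation": self.lead_fixation,
                "tail_fixation": self.tail_fixation,
            }
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventTable":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        side = path.with_suffix(path.suffix + ".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        return cls(frame=frame, **meta)


def assign_timing(
    seq: TrialSequence,
    trial_duration: float = 3.0,
    lead_fixation: float = 9.0,
    tail_fixation: float = 9.0,
    seed: int = 0,
    stimulus_duration: float = 0.3,
    delay_values: tuple[float, float] = (1.2, 1.4),
    delay_split: float = 0.75,
    cue_gap: float = 0.3,
) -> EventTable:
    """Assign onsets and within-trial timing to a trial sequence.

    Trials occupy contiguous ``trial_duration`` slots after a lead-in fixation
    interval.  The post-stimulus delay is ``delay_values[0]`` on a
    ``delay_split`` fraction of trials and ``delay_values[1]`` otherwise
    (counts rounded to nearest, ties toward the short delay), allocated by a
    seeded shuffle.  The response cue extinguishes ``cue_gap`` before the next
    trial onset.
    """
    if min(trial_duration, lead_fixation, tail_fixation, stimulus_duration) < 0:
        raise ValueError("durations must be non-negative")
    if trial_duration < stimulus_duration + max(delay_values) + cue_gap:
        raise ValueError("trial_duration too short for stimulus + delay + cue window")

    n = seq.n_trials
    n_short = int(np.floor(delay_split * n + 0.5))  # ties toward the short delay
    delays = np.r_[np.full(n_short, delay_values[0]), np.full(n - n_short, delay_values[1])]
    np.random.default_rng(seed).shuffle(delays)

    onsets = lead_fixation + trial_duration * np.arange(n)
    frame = pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.full(n, stimulus_duration),
            "delay": delays,
            "cue_onset": onsets + stimulus_duration + delays,
            "cue_offset": onsets + trial_duration - cue_gap,
            "trial_type": seq.conditions,
            "dummy": np.r_[1, np.zeros(n - 1, dtype=int)] if (seq.dummy_first and n) else np.zeros(n, dtype=int),
        }
    )
    return EventTable(
        frame=frame,
        run_id=seq.run_id,
        trial_duration=trial_duration,
        lead_fixation=lead_fixation,
        tail_fixation=tail_fixation,
    )
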