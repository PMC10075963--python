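"""Miniblock schedules for the localizer and main word-similarity runs.

A run alternates brief homogeneous stimulus blocks with jittered fixation
periods, framed by lead-in/lead-out fixations; the main runs additionally
interleave a handful of fixation-only blocks.  All durations live on a
50-ms grid and are accumulated in integer grid units, so event onsets tile
each run exactly and the printed run lengths (798 s -> 399 volumes for a
main run, 552 s -> 276 volumes for the localizer at TR = 2 s) come out
without floating-point drift.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRID",
    "MAIN_TIMING",
    "LOCALIZER_TIMING",
    "LOCALIZER_CATEGORIES",
    "TimingSpec",
    "Event",
    "Schedule",
    "order_block_items",
    "build_main_run",
    "build_main_session",
    "build_localizer_run",
    "schedule_summary",
]

#: Scheduling grid in seconds; every duration must be a multiple of this.
GRID = 0.05

#: Catch targets: hashtags in the main runs, a star in the localizer.
MAIN_CATCH_TARGET = "######"
LOCALIZER_CATCH_TARGET = "*"

#: Localizer condition labels (word conditions named per language id).
LOCALIZER_CATEGORIES = (
    "word_E",
    "word_F",
    "numbers",
    "false_fonts",
    "faces",
    "bodies",
    "houses",
    "tools",
    "checkerboard",
)


def _units(seconds: float) -> int:
    u = round(seconds / GRID)
    if abs(u * GRID - seconds) > 1e-9:
        raise ValueError(f"duration {seconds} s is not on the {GRID * 1000:.0f} ms grid")
    return u


@dataclass(frozen=True)
class TimingSpec:
    """Block and fixation timing parameters of one run type."""

    stim_dur: float
    isi: float
    items_per_block: int
    iti_choices: tuple[float, ...]
    iti_mean: float
    lead_in: float
    lead_out: float
    tr: float = 2.0
    n_fixation_blocks: int = 0
    fixation_choices: tuple[float, ...] = ()
    fixation_total: float = 0.0

    def __post_init__(self) -> None:
        for name in ("stim_dur", "isi", "lead_in", "lead_out", "tr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.iti_mean not in self.iti_choices:
            raise ValueError("the declared ITI mean must be one of the jitter values")

    @property
    def block_duration(self) -> float:
        return self.items_per_block * (self.stim_dur + self.isi)


#: Main-run timing: 12 x (150 + 200) ms = 4.2-s blocks, ITIs {3.8, 5.8, 7.8} s
#: (mean 5.8), 7 fixation-only blocks from {8, 10, 12} s summing to 68 s,
#: 16-s lead-in and 14-s lead-out.
MAIN_TIMING = TimingSpec(
    stim_dur=0.150,
    isi=0.200,
    items_per_block=12,
    iti_choices=(3.8, 5.8, 7.8),
    iti_mean=5.8,
    lead_in=16.0,
    lead_out=14.0,
    n_fixation_blocks=7,
    fixation_choices=(8.0, 10.0, 12.0),
    fixation_total=68.0,
)

#: Localizer timing: 20 x (100 + 200) ms = 6-s blocks, ITIs {4, 6, 8} s
#: (mean 6), 6-s leads.
LOCALIZER_TIMING = TimingSpec(
    stim_dur=0.100,
    isi=0.200,
    items_per_block=20,
    iti_choices=(4.0, 6.0, 8.0),
    iti_mean=6.0,
    lead_in=6.0,
    lead_out=6.0,
)


@dataclass(frozen=True)
class Event:
    """One timed element of a run."""

    onset: float
    duration: float
    kind: str  # "lead" | "stimulus" | "fixation"
    condition: str | None = None
    items: tuple[str, ...] = ()
    catch: bool = False
    catch_pos: int | None = None  # 1-based position of the target in the block

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class Schedule:
    """An ordered, gap-free sequence of events covering one run."""

    events: list[Event]
    tr: float = 2.0
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("schedule must contain at least one event")
        if abs(self.events[0].onset) > 1e-9:
            raise ValueError("first event must start at 0")
        for prev, nxt in zip(self.events, self.events[1:]):
            if abs(prev.end - nxt.onset) > 1e-9:
                raise ValueError(
                    f"events do not tile: {prev.end} != {nxt.onset}"
                )

    @property
    def total_duration(self) -> float:
        return self.events[-1].end

    @property
    def n_volumes(self) -> int:
        return math.ceil(round(self.total_duration / self.tr, 9))

    @property
    def stimulus_blocks(self) -> list[Event]:
        return [e for e in self.events if e.kind == "stimulus"]

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.stimulus_blocks:
            counts[e.condition] = counts.get(e.condition, 0) + 1
        return counts

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (one row per block)."""
        rows = []
        for e in self.events:
            rows.append(
                {
                    "onset": round(e.onset, 3),
                    "duration": round(e.duration, 3),
                    "trial_type": e.condition if e.kind == "stimulus" else e.kind,
                    "stim_file": " ".join(e.items) if e.items else "n/a",
                    "catch": int(e.catch),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_events_frame().to_csv(path, sep="\t", index=False)

    def save_manifest(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(self.manifest, fh, indent=2, default=float)


def _conflicts(a: str, b: str) -> bool:
    return any(x == y for x, y in zip(a, b))


def order_block_items(items: Sequence[str], seed: int = 0) -> list[str]:
    """Order a block so no two consecutive strings share a letter position.

    Randomized backtracking: candidate order is shuffled per depth, so the
    result is deterministic given the seed.  Raises if the exhaustive search
    proves no valid ordering exists.
    """
    items = list(items)
    rng = np.random.default_rng(seed)
    order: list[int] = []
    used = [False] * len(items)
    budget = [200_000]  # node expansions; dense conflict graphs prune fast

    def extend() -> bool:
        if len(order) == len(items):
            return True
        budget[0] -= 1
        if budget[0] < 0:
            raise ValueError(
                "no ordering found within the search budget for the "
                "shared-letter-position constraint"
            )
        cand = [i for i in range(len(items)) if not used[i]]
        rng.shuffle(cand)
        for i in cand:
            if order and _conflicts(items[order[-1]], items[i]):
                continue
            order.append(i)
            used[i] = True
            if extend():
                return True
            order.pop()
            used[i] = False
        return False

    if not extend():
        raise ValueError(
            "no ordering satisfies the shared-letter-position constraint"
        )
    return [items[i] for i in order]


def _best_effort_order(items: Sequence[str], rng) -> list[str]:
    """Greedy ordering minimizing adjacent shared-position violations."""
    remaining = list(items)
    rng.shuffle(remaining)
    out = [remaining.pop()]
    while remaining:
        clean = [i for i, s in enumerate(remaining) if not _conflicts(out[-1], s)]
        idx = clean[0] if clean else 0
        out.append(remaining.pop(idx))
    return out


def _balanced_jitter(n: int, choices: Sequence[float], mean: float, rng) -> list[float]:
    """A length-n multiset from ``choices`` averaging exactly ``mean``.

    Built from balanced triples (one of each jitter value) padded with
    mean-valued entries when n is not divisible by 3, then shuffled.
    """
    if abs(sum(choices) / len(choices) - mean) > 1e-9 or mean not in choices:
        raise ValueError("jitter choices must average to the declared mean")
    triples, rest = divmod(n, len(choices))
    seq = list(choices) * triples + [mean] * rest
    rng.shuffle(seq)
    return seq


def _fixation_composition(spec: TimingSpec, rng) -> list[float]:
    """Fixation-only block durations from the declared set, matching the total."""
    n, choices, total = spec.n_fixation_blocks, spec.fixation_choices, spec.fixation_total
    if n == 0:
        return []
    base = [min(choices)] * n
    deficit = _units(total) - sum(_units(d) for d in base)
    steps = sorted(
        {_units(c) - _units(min(choices)) for c in choices} - {0}, reverse=True
    )
    out_units = [_units(d) for d in base]
    i = 0
    while deficit > 0:
        for step in steps:
            if step <= deficit and out_units[i % n] == _units(min(choices)):
                out_units[i % n] += step
                deficit -= step
                break
        else:
            raise ValueError(
                f"cannot compose {total} s from {n} blocks of {choices}"
            )
        i += 1
    seq = [u * GRID for u in out_units]
    rng.shuffle(seq)
    return seq


def _no_repeat_sequence(labels: Sequence[str], reps: int, rng, max_tries: int = 10000):
    seq = [lab for lab in labels for _ in range(reps)]
    for _ in range(max_tries):
        rng.shuffle(seq)
        if all(a != b for a, b in zip(seq, seq[1:])):
            return list(seq)
    raise ValueError("could not find a block order without immediate repeats")


def _build_run(
    labels: Sequence[str],
    blocks_by_condition: Mapping[str, list[list[str]]],
    catch_flags: Mapping[str, list[bool]],
    timing: TimingSpec,
    seed: int,
    catch_target: str,
    order_items: bool,
    no_repeat: bool = True,
) -> Schedule:
    rng = np.random.default_rng(seed)
    reps = {lab: len(blocks_by_condition[lab]) for lab in labels}
    n_reps = set(reps.values())
    if len(n_reps) != 1:
        raise ValueError("all conditions must have the same number of blocks")
    reps_per_condition = n_reps.pop()
    if no_repeat:
        cond_seq = _no_repeat_sequence(labels, reps_per_condition, rng)
    else:
        cond_seq = [lab for lab in labels for _ in range(reps_per_condition)]
        rng.shuffle(cond_seq)
    n_blocks = len(cond_seq)
    itis = _balanced_jitter(n_blocks, timing.iti_choices, timing.iti_mean, rng)
    fix_durs = _fixation_composition(timing, rng)
    fix_after = (
        set(rng.choice(n_blocks, size=len(fix_durs), replace=False).tolist())
        if fix_durs
        else set()
    )
    next_rep = {lab: 0 for lab in labels}
    n_unorderable = 0
    events: list[Event] = []
    t = 0
    events.append(Event(0.0, timing.lead_in, "lead"))
    t += _units(timing.lead_in)
    fix_i = 0
    block_u = _units(timing.block_duration)
    for bi, lab in enumerate(cond_seq):
        r = next_rep[lab]
        next_rep[lab] += 1
        items = list(blocks_by_condition[lab][r])
        catch = bool(catch_flags[lab][r])
        catch_pos = None
        if order_items and len(items) == timing.items_per_block:
            try:
                items = order_block_items(items, seed=int(rng.integers(2**31)))
            except ValueError:
                # dense alphabets can make a block unorderable; fall back to
                # the fewest-violations ordering rather than dropping the run
                items = _best_effort_order(items, rng)
                n_unorderable += 1
        if catch:
            # the target replaces one stimulus strictly after the fifth
            pos0 = int(rng.integers(5, timing.items_per_block))
            items[pos0] = catch_target
            catch_pos = pos0 + 1
        events.append(
            Event(
                t * GRID,
                timing.block_duration,
                "stimulus",
                condition=lab,
                items=tuple(items),
                catch=catch,
                catch_pos=catch_pos,
            )
        )
        t += block_u
        events.append(Event(t * GRID, itis[bi], "fixation"))
        t += _units(itis[bi])
        if bi in fix_after:
            events.append(Event(t * GRID, fix_durs[fix_i], "fixation"))
            t += _units(fix_durs[fix_i])
            fix_i += 1
    events.append(Event(t * GRID, timing.lead_out, "lead"))
    manifest = {
        "seed": seed,
        "iti_sequence": itis,
        "fixation_blocks": fix_durs,
        "condition_sequence": cond_seq,
        "n_unorderable_blocks": n_unorderable,
    }
    return Schedule(events, tr=timing.tr, manifest=manifest)


def _placeholder_blocks(labels, reps, items_per_block, prefix=""):
    return {
        lab: [
            [f"{prefix}{lab}_{r:02d}_{i:02d}" for i in range(items_per_block)]
            for r in range(reps)
        ]
        for lab in labels
    }


def _catch_flags(labels, reps, catch_per_condition, rng, exempt=()):
    flags = {}
    for lab in labels:
        f = [False] * reps
        if lab not in exempt:
            if catch_per_condition > reps:
                raise ValueError("more catch blocks than repetitions")
            for i in rng.choice(reps, size=catch_per_condition, replace=False):
                f[int(i)] = True
        flags[lab] = f
    return flags


def build_main_run(
    labels: Sequence[str],
    seed: int = 0,
    timing: TimingSpec = MAIN_TIMING,
    reps_per_condition: int = 5,
    catch_per_condition: int = 2,
    stimulus_blocks: Mapping[str, list[list[str]]] | None = None,
    order_items: bool | None = None,
    no_repeat: bool = True,
) -> Schedule:
    """One main fMRI run: each condition repeated ``reps_per_condition`` times.

    With the default 14 conditions and 5 repetitions the run holds 70
    stimulus blocks and spans 798 s (399 volumes at TR = 2 s); 2 of the 5
    blocks per condition carry a '######' catch target.
    """
    rng = np.random.default_rng(seed)
    if stimulus_blocks is None:
        stimulus_blocks = _placeholder_blocks(
            labels, reps_per_condition, timing.items_per_block
        )
        order_items = False if order_items is None else order_items
    else:
        order_items = True if order_items is None else order_items
    flags = _catch_flags(labels, reps_per_condition, catch_per_condition, rng)
    return _build_run(
        labels,
        stimulus_blocks,
        flags,
        timing,
        int(rng.integers(2**31)),
        MAIN_CATCH_TARGET,
        order_items,
        no_repeat=no_repeat,
    )


def build_main_session(
    design_labels: Sequence[str],
    stimuli: pd.DataFrame | None = None,
    n_runs: int = 3,
    reps_per_condition: int = 5,
    catch_per_condition: int = 2,
    timing: TimingSpec = MAIN_TIMING,
    seed: int = 0,
) -> list[Schedule]:
    """Counterbalanced session of ``n_runs`` main runs.

    If a stimulus table (columns ``string``, ``category``) is given, each
    condition's items are shuffled once and dealt into
    ``n_runs * reps_per_condition`` blocks, so every stimulus is shown exactly
    once across the session.
    """
    rng = np.random.default_rng(seed)
    per_run_blocks: list[dict[str, list[list[str]]]] | None = None
    if stimuli is not None:
        need = n_runs * reps_per_condition * timing.items_per_block
        per_run_blocks = [dict() for _ in range(n_runs)]
        for lab in design_labels:
            pool = stimuli.loc[stimuli["category"] == lab, "string"].tolist()
            if len(pool) < need:
                raise ValueError(
                    f"condition {lab}: {len(pool)} items, need {need} for the session"
                )
            pool = [pool[i] for i in rng.permutation(len(pool))[:need]]
            blocks = [
                pool[i : i + timing.items_per_block]
                for i in range(0, need, timing.items_per_block)
            ]
            for run in range(n_runs):
                per_run_blocks[run][lab] = blocks[
                    run * reps_per_condition : (run + 1) * reps_per_condition
                ]
    runs = []
    for run in range(n_runs):
        runs.append(
            build_main_run(
                design_labels,
                seed=int(rng.integers(2**31)),
                timing=timing,
                reps_per_condition=reps_per_condition,
                catch_per_condition=catch_per_condition,
                stimulus_blocks=None if per_run_blocks is None else per_run_blocks[run],
            )
        )
    return runs


def build_localizer_run(
    categories: Sequence[str] = LOCALIZER_CATEGORIES,
    seed: int = 0,
    timing: TimingSpec = LOCALIZER_TIMING,
    blocks_per_category: int = 5,
    catch_per_condition: int = 2,
    catch_exempt: Sequence[str] = ("checkerboard",),
) -> Schedule:
    """The visual-category localizer run: 45 6-s blocks, 552 s, 276 volumes.

    Every category is shown in 5 blocks, 2 of which carry a star catch
    target - except the checkerboard condition, which has none.
    """
    rng = np.random.default_rng(seed)
    blocks = _placeholder_blocks(categories, blocks_per_category, timing.items_per_block)
    flags = _catch_flags(
        categories, blocks_per_category, catch_per_condition, rng, exempt=catch_exempt
    )
    return _build_run(
        categories,
        blocks,
        flags,
        timing,
        int(rng.integers(2**31)),
        LOCALIZER_CATCH_TARGET,
        order_items=False,
    )


def schedule_summary(schedules: Sequence[Schedule]) -> dict:
    """Per-run and pooled block counts, durations, volumes and catch rates."""
    if not schedules:
        raise ValueError("at least one schedule is required")
    runs = []
    total_blocks = 0
    total_catch = 0
    pooled_counts: dict[str, int] = {}
    for s in schedules:
        blocks = s.stimulus_blocks
        n_catch = sum(e.catch for e in blocks)
        counts = s.condition_counts()
        for k, v in counts.items():
            pooled_counts[k] = pooled_counts.get(k, 0) + v
        runs.append(
            {
                "n_stimulus_blocks": len(blocks),
                "total_duration": round(s.total_duration, 3),
                "n_volumes": s.n_volumes,
                "catch_pct": 100.0 * n_catch / len(blocks) if blocks else 0.0,
                "condition_counts": counts,
            }
        )
        total_blocks += len(blocks)
        total_catch += n_catch
    return {
        "runs": runs,
        "pooled": {
            "n_stimulus_blocks": total_blocks,
            "total_duration": round(sum(s.total_duration for s in schedules), 3),
            "n_volumes": sum(s.n_volumes for s in schedules),
            "catch_pct": 100.0 * total_catch / total_blocks if total_blocks else 0.0,
            "condition_counts": pooled_counts,
        },
    }
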