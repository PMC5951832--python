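"""Blocked Pavlovian task structure and trial-schedule generation.

The task presents rewards in blocks of five identical trials. Two training
block types exist, distinguished only by reward size: ``s1`` (1 µL) and
``s2`` (10 µL). After a deterministic alternation phase, block transitions
become probabilistic (50% switch probability at each block start). In the
probe phase, every other day three training blocks are swapped for
intermediate-reward blocks (2, 4, 6 or 8 µL), each intermediate volume
appearing at most once per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIALS_PER_BLOCK = 5
BLOCKS_PER_DAY = 30

S1_VOLUME = 1.0
S2_VOLUME = 10.0
INTERMEDIATE_VOLUMES = (2.0, 4.0, 6.0, 8.0)
ALL_VOLUMES = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

BLOCK_TYPES = ("s1", "s2", "intermediate")
PHASES = ("deterministic", "probabilistic", "probe")

#: Default day counts reproducing the study-scale exposure
#: (~3980 trials of each training block, ~42 of each intermediate volume).
DEFAULT_DAYS = {"deterministic": 13, "probabilistic": 19, "probe": 22}


def normalize_reward(volume: float) -> float:
    """Map reward volume (µL) to the normalized reward r ∈ [0, 1].

    The two training anchors define the scale: 1 µL → 0 and 10 µL → 1,
    so r = (volume − 1) / 9.

    Raises
    ------
    ValueError
        If ``volume`` lies outside [1, 10].
    """
    v = float(volume)
    if not 1.0 <= v <= 10.0:
        raise ValueError(f"reward volume {v} µL outside the task range [1, 10]")
    return (v - 1.0) / 9.0


@dataclass(frozen=True)
class BlockSpec:
    """One block of five identical trials."""

    block_type: str
    reward_volume: float
    n_trials: int = TRIALS_PER_BLOCK

    def __post_init__(self):
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block type {self.block_type!r}")
        if self.n_trials != TRIALS_PER_BLOCK:
            raise ValueError("blocks always contain 5 trials")
        v = self.reward_volume
        if self.block_type == "s1" and v != S1_VOLUME:
            raise ValueError("s1 blocks deliver 1 µL")
        if self.block_type == "s2" and v != S2_VOLUME:
            raise ValueError("s2 blocks deliver 10 µL")
        if self.block_type == "intermediate" and v not in INTERMEDIATE_VOLUMES:
            raise ValueError(f"intermediate volume must be one of {INTERMEDIATE_VOLUMES}")


def _training_block(block_type: str) -> BlockSpec:
    return BlockSpec(block_type, S1_VOLUME if block_type == "s1" else S2_VOLUME)


@dataclass
class SessionSchedule:
    """Ordered blocks for one or more days of a single phase.

    ``days[d]`` is the ordered list of :class:`BlockSpec` for day ``d``.
    """

    days: list[list[BlockSpec]]
    phase: str
    blocks_per_day: int = BLOCKS_PER_DAY
    probe_days: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        for d, blocks in enumerate(self.days):
            if len(blocks) != self.blocks_per_day:
                raise ValueError(
                    f"day {d} has {len(blocks)} blocks, expected {self.blocks_per_day}"
                )

    @property
    def n_days(self) -> int:
        return len(self.days)

    def iter_blocks(self):
        for d, blocks in enumerate(self.days):
            for b, spec in enumerate(blocks):
                yield d, b, spec

    def to_trial_table(
        self, mouse_id: str = "m0", day_offset: int = 0, prev_of_first: str = "none"
    ) -> pd.DataFrame:
        """Expand to one row per trial.

        ``prev_block_type`` is the type of the immediately preceding block in
        the history ("none" only for the first block overall); it carries
        across day boundaries, matching the way expectations at block start
        depend on the previous block regardless of session breaks.
        """
        rows = []
        prev = prev_of_first
        for d, b, spec in self.iter_blocks():
            for t in range(1, spec.n_trials + 1):
                rows.append(
                    (
                        mouse_id,
                        day_offset + d,
                        b,
                        t,
                        spec.block_type,
                        spec.reward_volume,
                        normalize_reward(spec.reward_volume),
                        prev,
                    )
                )
            prev = spec.block_type
        return pd.DataFrame(
            rows,
            columns=[
                "mouse_id",
                "day",
                "block_index",
                "trial_in_block",
                "block_type",
                "reward_volume_ul",
                "reward_norm",
                "prev_block_type",
            ],
        )


def generate_training_schedule(
    n_days: int,
    phase: str = "deterministic",
    blocks_per_day: int = BLOCKS_PER_DAY,
    seed: int | np.random.Generator = 0,
    start_type: str = "s1",
) -> SessionSchedule:
    """Generate training days of alternating or probabilistically switching blocks.

    In the deterministic phase block types strictly alternate (across day
    boundaries as well). In the probabilistic phase the type switches with
    probability 0.5 at each block start.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if phase not in ("deterministic", "probabilistic"):
        raise ValueError(f"invalid training phase {phase!r}")
    if start_type not in ("s1", "s2"):
        raise ValueError("start_type must be 's1' or 's2'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    days: list[list[BlockSpec]] = []
    current = start_type
    other = {"s1": "s2", "s2": "s1"}
    for _ in range(n_days):
        blocks = []
        for _ in range(blocks_per_day):
            blocks.append(_training_block(current))
            if phase == "deterministic" or rng.random() < 0.5:
                current = other[current]
        days.append(blocks)
    return SessionSchedule(days=days, phase=phase, blocks_per_day=blocks_per_day)


def generate_probe_schedule(
    base: SessionSchedule,
    seed: int | np.random.Generator = 0,
    probe_every: int = 2,
    n_intermediate: int = 3,
) -> SessionSchedule:
    """Swap training blocks for intermediate blocks on probe days.

    Every ``probe_every``-th day (starting with the first day of ``base``)
    exactly ``n_intermediate`` non-first blocks are replaced by intermediate
    blocks of distinct volumes, so no intermediate volume repeats within a
    day. Replacement positions are uniform-random.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if base.blocks_per_day - 1 < n_intermediate:
        raise ValueError("not enough replaceable blocks for the probe day")

    days: list[list[BlockSpec]] = []
    probe_days = []
    for d, blocks in enumerate(base.days):
        blocks = list(blocks)
        if d % probe_every == 0:
            probe_days.append(d)
            # never the first block of a day; tone-signaled day start stays a training block
            positions = rng.choice(
                np.arange(1, len(blocks)), size=n_intermediate, replace=False
            )
            volumes = rng.choice(
                np.asarray(INTERMEDIATE_VOLUMES), size=n_intermediate, replace=False
            )
            for pos, vol in zip(positions, volumes):
                blocks[int(pos)] = BlockSpec("intermediate", float(vol))
        days.append(blocks)
    return SessionSchedule(
        days=days,
        phase="probe",
        blocks_per_day=base.blocks_per_day,
        probe_days=probe_days,
    )


def generate_full_history(
    seed: int = 0,
    n_det_days: int | None = None,
    n_prob_days: int | None = None,
    n_probe_days: int | None = None,
    blocks_per_day: int = BLOCKS_PER_DAY,
    mouse_id: str = "m0",
) -> pd.DataFrame:
    """Full training history: deterministic → probabilistic → probe phases.

    Defaults reproduce the study-scale exposure per mouse (~3980 trials of
    each training block and ~42 trials of each intermediate volume).
    Returns the concatenated trial table.
    """
    rng = np.random.default_rng(seed)
    n_det = DEFAULT_DAYS["deterministic"] if n_det_days is None else n_det_days
    n_prob = DEFAULT_DAYS["probabilistic"] if n_prob_days is None else n_prob_days
    n_probe = DEFAULT_DAYS["probe"] if n_probe_days is None else n_probe_days

    det = generate_training_schedule(
        n_det, "deterministic", blocks_per_day, rng,
        start_type="s1" if rng.random() < 0.5 else "s2",
    )
    last_type = det.days[-1][-1].block_type
    prob = generate_training_schedule(
        n_prob, "probabilistic", blocks_per_day, rng,
        start_type=last_type if rng.random() < 0.5 else {"s1": "s2", "s2": "s1"}[last_type],
    )
    probe_base = generate_training_schedule(
        n_probe, "probabilistic", blocks_per_day, rng, start_type="s1"
    )
    probe = generate_probe_schedule(probe_base, rng)

    tables = []
    offset = 0
    prev = "none"
    for sched in (det, prob, probe):
        tab = sched.to_trial_table(mouse_id=mouse_id, day_offset=offset, prev_of_first=prev)
        tables.append(tab)
        offset += sched.n_days
        prev = tab["block_type"].iloc[-1]
    return pd.concat(tables, ignore_index=True)
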