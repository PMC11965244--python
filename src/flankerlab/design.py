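"""Balanced trial-schedule construction for the three experiment designs.

Each builder returns an ordered list of :class:`TrialSpec` covering practice
and experimental blocks.  Randomization is block-local: every block shuffles
its cell list with an RNG seeded from ``(master_seed, block_index)`` so the
schedule of one block never depends on how another block was drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

# experiment identifiers
EXP1 = "EXP1"
EXP2A = "EXP2A"
EXP2B = "EXP2B"
EXP3 = "EXP3"
EXPERIMENTS = (EXP1, EXP2A, EXP2B, EXP3)

# factor levels
CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
CONGRUENCIES = (CONGRUENT, INCONGRUENT)
LEFT = "left"
RIGHT = "right"
DIRECTIONS = (LEFT, RIGHT)

FIXED = "fixed"
VARIABLE = "variable"
NA = "na"

FIXED_CENTER = "center"
OFFSET_LOCATIONS = ("V1", "V2", "V3", "V4")

SOAS_MS = (-400, -200, -100, -50, 0, 30, 50, 100, 200)
T_DELTAS_MS = (33, 50, 67, 83)  # plus the constant (no-change) condition = None

EXP1_N_BLOCKS = 8
EXP1_TRIALS_PER_BLOCK = 108
EXP23_N_BLOCKS = 12
EXP23_TRIALS_PER_BLOCK = 80

# stimulus geometry (degrees of visual angle)
OFFSET_DEG = 0.75


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: design factors only, no response fields."""

    experiment: str
    block_index: int
    trial_index: int
    congruency: str
    target_direction: str
    soa_ms: Optional[int] = None       # EXP1 only
    t_delta_ms: Optional[int] = None   # EXP2 only; None = constant-contrast
    location: str = FIXED_CENTER
    block_condition: str = NA          # EXP3 only
    is_practice: bool = False


@dataclass(frozen=True)
class DesignSpec:
    """Shape summary of one experiment's schedule."""

    experiment: str
    n_blocks: int
    trials_per_block: int
    counterbalance: str = NA  # "ABBA" | "BAAB" | "na"
    rng_seed: int = 0


def _block_rng(seed: int, block_index: int) -> np.random.Generator:
    # offset keeps both words non-negative (practice blocks use indices <= 0)
    return np.random.default_rng([int(seed) & 0xFFFFFFFF, int(block_index) + 1000])


def build_exp1(seed: int) -> list[TrialSpec]:
    """Full schedule: one 36-trial exhaustive practice block, then 8 blocks
    of 108 trials where each congruency x direction configuration appears
    3 times at each of the 9 SOAs, shuffled per block."""
    trials: list[TrialSpec] = []

    practice_cells = [
        (c, d, soa) for soa in SOAS_MS for c in CONGRUENCIES for d in DIRECTIONS
    ]
    rng = _block_rng(seed, 0)
    rng.shuffle(practice_cells)
    for i, (c, d, soa) in enumerate(practice_cells, start=1):
        trials.append(
            TrialSpec(EXP1, 1, i, c, d, soa_ms=soa, is_practice=True)
        )

    for b in range(1, EXP1_N_BLOCKS + 1):
        cells = [
            (c, d, soa)
            for soa in SOAS_MS
            for c in CONGRUENCIES
            for d in DIRECTIONS
            for _ in range(3)
        ]
        rng = _block_rng(seed, b)
        rng.shuffle(cells)
        for i, (c, d, soa) in enumerate(cells, start=1):
            trials.append(TrialSpec(EXP1, b + 1, i, c, d, soa_ms=soa))
    return trials


def build_exp2(variant: str, seed: int) -> list[TrialSpec]:
    """Schedule for the contrast-change experiments (variant "A" or "B").

    Practice: a 16-trial constant-contrast block, then a 36-trial dynamic
    block (18 trials at t=50 ms, 18 at t=67 ms; the extreme change times are
    withheld).  Experimental: 12 blocks of 80 trials; per block, each of the
    4 stimulus arrays appears 4 times at each of the 5 change-time levels.
    Array location is drawn per trial from the four diagonal offsets.
    """
    if variant not in ("A", "B"):
        raise ValueError(f"variant must be 'A' or 'B', got {variant!r}")
    experiment = EXP2A if variant == "A" else EXP2B
    trials: list[TrialSpec] = []
    configs = [(c, d) for c in CONGRUENCIES for d in DIRECTIONS]

    # practice block 1: constant contrast, 4 configurations x 4 repeats
    cells1 = [(c, d, None) for c, d in configs for _ in range(4)]
    rng = _block_rng(seed, 0)
    rng.shuffle(cells1)
    for i, (c, d, td) in enumerate(cells1, start=1):
        loc = OFFSET_LOCATIONS[rng.integers(4)]
        trials.append(
            TrialSpec(experiment, 1, i, c, d, t_delta_ms=td,
                      location=loc, is_practice=True)
        )

    # practice block 2: 18 trials each at the two middle change times
    cells2 = []
    for td in (50, 67):
        reps = [configs[i % 4] for i in range(18)]
        cells2.extend([(c, d, td) for c, d in reps])
    rng = _block_rng(seed, -1)
    rng.shuffle(cells2)
    for i, (c, d, td) in enumerate(cells2, start=1):
        loc = OFFSET_LOCATIONS[rng.integers(4)]
        trials.append(
            TrialSpec(experiment, 2, i, c, d, t_delta_ms=td,
                      location=loc, is_practice=True)
        )

    levels: tuple[Optional[int], ...] = T_DELTAS_MS + (None,)
    for b in range(1, EXP23_N_BLOCKS + 1):
        cells = [(c, d, td) for td in levels for c, d in configs for _ in range(4)]
        rng = _block_rng(seed, b)
        rng.shuffle(cells)
        for i, (c, d, td) in enumerate(cells, start=1):
            loc = OFFSET_LOCATIONS[rng.integers(4)]
            trials.append(
                TrialSpec(experiment, b + 2, i, c, d, t_delta_ms=td, location=loc)
            )
    return trials


def build_exp3(
    counterbalance: str, seed: int, balanced_locations: bool = False
) -> list[TrialSpec]:
    """Schedule for the location-uncertainty experiment.

    12 blocks of 80 trials alternate between fixed-location and
    variable-location conditions as three repetitions of the ABBA or BAAB
    pattern (A = fixed).  Variable-block locations are drawn per trial,
    uniformly over the four cardinal offsets by default, or exactly 20 per
    location per block when ``balanced_locations`` is set.
    """
    if counterbalance not in ("ABBA", "BAAB"):
        raise ValueError(f"counterbalance must be 'ABBA' or 'BAAB', got {counterbalance!r}")
    pattern = {"A": FIXED, "B": VARIABLE}
    block_conditions = [pattern[ch] for ch in counterbalance * 3]

    trials: list[TrialSpec] = []
    configs = [(c, d) for c in CONGRUENCIES for d in DIRECTIONS]
    for b, cond in enumerate(block_conditions, start=1):
        cells = [(c, d) for c, d in configs for _ in range(EXP23_TRIALS_PER_BLOCK // 4)]
        rng = _block_rng(seed, b)
        rng.shuffle(cells)
        if cond == FIXED:
            locs = [FIXED_CENTER] * EXP23_TRIALS_PER_BLOCK
        elif balanced_locations:
            locs = [OFFSET_LOCATIONS[i % 4] for i in range(EXP23_TRIALS_PER_BLOCK)]
            rng.shuffle(locs)
        else:
            locs = [OFFSET_LOCATIONS[k] for k in rng.integers(4, size=EXP23_TRIALS_PER_BLOCK)]
        for i, ((c, d), loc) in enumerate(zip(cells, locs), start=1):
            trials.append(
                TrialSpec(EXP3, b, i, c, d, location=loc, block_condition=cond)
            )
    return trials


def design_spec(experiment: str, counterbalance: str = NA, seed: int = 0) -> DesignSpec:
    if experiment == EXP1:
        return DesignSpec(EXP1, EXP1_N_BLOCKS, EXP1_TRIALS_PER_BLOCK, NA, seed)
    if experiment in (EXP2A, EXP2B):
        return DesignSpec(experiment, EXP23_N_BLOCKS, EXP23_TRIALS_PER_BLOCK, NA, seed)
    if experiment == EXP3:
        return DesignSpec(EXP3, EXP23_N_BLOCKS, EXP23_TRIALS_PER_BLOCK, counterbalance, seed)
    raise ValueError(f"unknown experiment {experiment!r}")


# ---------------------------------------------------------------------------
# stimulus geometry helpers

def location_offset_deg(experiment: str, location: str) -> tuple[float, float]:
    """(dx, dy) offset of an array center from fixation, in degrees.

    EXP2 uses diagonal displacements, EXP3 cardinal ones; both with a
    0.75 degree component.
    """
    if location == FIXED_CENTER:
        return (0.0, 0.0)
    idx = OFFSET_LOCATIONS.index(location)
    if experiment in (EXP2A, EXP2B):
        signs = [(1, 1), (1, -1), (-1, -1), (-1, 1)]
        sx, sy = signs[idx]
        return (sx * OFFSET_DEG, sy * OFFSET_DEG)
    if experiment == EXP3:
        dirs = [(0, 1), (1, 0), (0, -1), (-1, 0)]
        sx, sy = dirs[idx]
        return (sx * OFFSET_DEG, sy * OFFSET_DEG)
    raise ValueError(f"experiment {experiment!r} has no offset locations")


def eccentricity_deg(dx: float, dy: float) -> float:
    """Euclidean distance of an offset vector from fixation."""
    return math.hypot(dx, dy)


def geometric_mean(a: float, b: float) -> float:
    """Geometric mean of two positive values (used for the middle of a
    luminance ladder)."""
    if a <= 0 or b <= 0:
        raise ValueError("geometric mean requires positive inputs")
    return math.sqrt(a * b)
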