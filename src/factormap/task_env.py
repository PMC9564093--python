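"""Task environment: cue space, arena geometry, ground-truth mappings, curricula.

The task asks a learner to place a cursor inside a circular arena in
response to one of 25 symbolic cues (5 color levels x 5 shape levels).
Each cue deterministically signals a ground-truth point through one of two
factorized mappings:

* **grid** -- one cue dimension sets the horizontal coordinate, the other
  the vertical coordinate, on a 5x5 axis-parallel lattice;
* **polar** -- one cue dimension sets the radius (one of 5 concentric
  rings), the other the azimuth (one of 5 spokes), optionally rotated by a
  per-participant angle.

A session is 14 blocks of 25 trials.  The first 9 trials of a block query
the training cues (with feedback), the remaining 16 query the held-out
test cues (no feedback).  Curricula control which 9 cues are trained and
in what order:

* **aligned** -- training cues are one full row plus one full column of
  the cue lattice (one dimension varies at a time along each axis);
* **misaligned** -- training cues are the two diagonals (both dimensions
  vary on every step);
* **blocked** -- one training axis is queried on trials 1-4, the shared
  cue on trial 5, the other axis on trials 6-9, with the leading axis
  alternating across blocks;
* **interleaved** -- the 9 training cues appear in fully random order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "ARENA_RADIUS_PX",
    "N_BLOCKS",
    "N_TRAIN_TRIALS_PER_BLOCK",
    "N_TEST_TRIALS_PER_BLOCK",
    "CORRECT_RADIUS_PX",
    "Cue",
    "Arena",
    "MappingSpec",
    "CurriculumSpec",
    "TrialRecord",
    "all_cues",
    "make_mapping",
    "truth_location",
    "make_curriculum",
    "order_training_trials",
    "score_points",
    "is_correct",
    "make_schedule",
]

# ---------------------------------------------------------------------------
# Constants of the experimental design
# ---------------------------------------------------------------------------

ARENA_RADIUS_PX: float = 265.0
N_LEVELS: int = 5
N_BLOCKS: int = 14
N_TRAIN_TRIALS_PER_BLOCK: int = 9
N_TEST_TRIALS_PER_BLOCK: int = 16
CORRECT_RADIUS_PX: float = 60.0  # "correct" predicate used for exclusion

#: Default spacing between adjacent grid levels.  Levels sit at offsets
#: {-2,-1,0,1,2} * spacing, so corners are at radius 180*sqrt(2) ~ 254.6 px,
#: inside the 265 px arena (maximal separation subject to containment).
DEFAULT_GRID_SPACING: float = 90.0

#: Default ring radii: innermost nonzero so the 25 points stay distinct,
#: outermost inset from the arena wall.
DEFAULT_RING_RADII: tuple[float, ...] = (53.0, 106.0, 159.0, 212.0, 245.0)

#: Default spoke angles: 5 spokes spaced 72 degrees apart.
DEFAULT_SPOKE_ANGLES: tuple[float, ...] = tuple(
    2.0 * math.pi * k / 5 for k in range(5)
)


class Cue(NamedTuple):
    """One of the 25 symbolic cues, indexed by its two feature levels."""

    color_level: int
    shape_level: int


def all_cues() -> list[Cue]:
    """The full 5x5 cue lattice in row-major order."""
    return [Cue(c, s) for c in range(N_LEVELS) for s in range(N_LEVELS)]


@dataclass(frozen=True)
class Arena:
    """Circular response arena centered at the origin."""

    radius: float = ARENA_RADIUS_PX

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("arena radius must be positive")

    def contains(self, x: float, y: float) -> bool:
        return math.hypot(x, y) <= self.radius

    def clip(self, x: float, y: float) -> tuple[float, float]:
        """Project a point onto the closed disk (identity if inside)."""
        r = math.hypot(x, y)
        if r <= self.radius:
            return (x, y)
        f = self.radius / r
        return (x * f, y * f)


MappingKind = Literal["grid", "polar"]


@dataclass(frozen=True)
class MappingSpec:
    """Ground-truth cue-to-point mapping with per-participant randomizations.

    Spatial dimension 1 is the horizontal coordinate (grid) or the radius
    (polar); spatial dimension 2 is the vertical coordinate (grid) or the
    azimuth (polar).  ``color_drives`` records which spatial dimension the
    color feature controls (shape controls the other).  ``level_order``
    maps cue levels to spatial levels, one permutation per cue dimension.
    """

    kind: MappingKind
    color_drives: Literal["dim1", "dim2"] = "dim1"
    color_level_order: tuple[int, ...] = (0, 1, 2, 3, 4)
    shape_level_order: tuple[int, ...] = (0, 1, 2, 3, 4)
    polar_rotation: float = 0.0
    grid_spacing: float = DEFAULT_GRID_SPACING
    ring_radii: tuple[float, ...] = DEFAULT_RING_RADII
    spoke_angles: tuple[float, ...] = DEFAULT_SPOKE_ANGLES
    arena: Arena = field(default_factory=Arena)

    def __post_init__(self) -> None:
        if self.kind not in ("grid", "polar"):
            raise ValueError(f"unknown mapping kind {self.kind!r}")
        if sorted(self.color_level_order) != list(range(N_LEVELS)):
            raise ValueError("color_level_order must permute 0..4")
        if sorted(self.shape_level_order) != list(range(N_LEVELS)):
            raise ValueError("shape_level_order must permute 0..4")
        if self.kind == "polar":
            if len(self.ring_radii) != N_LEVELS or len(self.spoke_angles) != N_LEVELS:
                raise ValueError("polar mapping needs 5 ring radii and 5 spoke angles")
            if min(self.ring_radii) <= 0 or max(self.ring_radii) > self.arena.radius:
                raise ValueError("ring radii must lie in (0, arena radius]")

    def spatial_levels(self, cue: Cue) -> tuple[int, int]:
        """(dim1 level, dim2 level) of a cue after randomizations."""
        c = self.color_level_order[cue.color_level]
        s = self.shape_level_order[cue.shape_level]
        return (c, s) if self.color_drives == "dim1" else (s, c)

    def cue_at(self, dim1_level: int, dim2_level: int) -> Cue:
        """Inverse of :meth:`spatial_levels`."""
        inv_c = {v: k for k, v in enumerate(self.color_level_order)}
        inv_s = {v: k for k, v in enumerate(self.shape_level_order)}
        if self.color_drives == "dim1":
            return Cue(inv_c[dim1_level], inv_s[dim2_level])
        return Cue(inv_c[dim2_level], inv_s[dim1_level])


def make_mapping(
    kind: MappingKind,
    rng_seed: Optional[int] = None,
    *,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    ring_radii: Sequence[float] = DEFAULT_RING_RADII,
    spoke_angles: Sequence[float] = DEFAULT_SPOKE_ANGLES,
    arena: Optional[Arena] = None,
) -> MappingSpec:
    """Build a mapping, randomizing the per-participant degrees of freedom.

    With ``rng_seed=None`` the identity mapping is returned (color drives
    dimension 1, identity level orders, zero rotation); otherwise the
    dimension assignment and level orders are drawn uniformly, and for
    polar mappings the whole layout is rotated by a uniform random angle.
    """
    arena = arena or Arena()
    if rng_seed is None:
        return MappingSpec(
            kind=kind,
            grid_spacing=grid_spacing,
            ring_radii=tuple(ring_radii),
            spoke_angles=tuple(spoke_angles),
            arena=arena,
        )
    rng = np.random.default_rng(rng_seed)
    return MappingSpec(
        kind=kind,
        color_drives="dim1" if rng.integers(2) == 0 else "dim2",
        color_level_order=tuple(int(v) for v in rng.permutation(N_LEVELS)),
        shape_level_order=tuple(int(v) for v in rng.permutation(N_LEVELS)),
        polar_rotation=float(rng.uniform(0.0, 2.0 * math.pi)) if kind == "polar" else 0.0,
        grid_spacing=grid_spacing,
        ring_radii=tuple(ring_radii),
        spoke_angles=tuple(spoke_angles),
        arena=arena,
    )


def truth_location(mapping: MappingSpec, cue: Cue) -> tuple[float, float]:
    """Ground-truth arena point signaled by ``cue`` under ``mapping``."""
    d1, d2 = mapping.spatial_levels(cue)
    if mapping.kind == "grid":
        center = (N_LEVELS - 1) / 2.0
        return (
            (d1 - center) * mapping.grid_spacing,
            (d2 - center) * mapping.grid_spacing,
        )
    rho = mapping.ring_radii[d1]
    phi = mapping.spoke_angles[d2] + mapping.polar_rotation
    return (rho * math.cos(phi), rho * math.sin(phi))


# ---------------------------------------------------------------------------
# Curricula
# ---------------------------------------------------------------------------

Alignment = Literal["aligned", "misaligned"]
Ordering = Literal["blocked", "interleaved"]


@dataclass(frozen=True)
class CurriculumSpec:
    """Which 9 cues are trained, how they are ordered, and the axis split.

    ``axis_a``/``axis_b`` hold the four non-shared cues of each training
    axis (two cue-lattice lines for aligned curricula, the two diagonals
    for misaligned ones); ``overlap`` is the cue they share.
    """

    experiment: Literal[1, 2]
    mapping_kind: MappingKind
    alignment: Alignment
    ordering: Ordering
    train_cues: frozenset[Cue]
    test_cues: frozenset[Cue]
    axis_a: tuple[Cue, ...]
    axis_b: tuple[Cue, ...]
    overlap: Cue
    first_block_axis: Literal["a", "b"] = "a"

    def __post_init__(self) -> None:
        if len(self.train_cues) != 9 or len(self.test_cues) != 16:
            raise ValueError("curriculum must train 9 cues and test 16")
        if self.train_cues & self.test_cues:
            raise ValueError("train and test cue sets must be disjoint")
        if self.train_cues | self.test_cues != frozenset(all_cues()):
            raise ValueError("train and test cues must partition the 25 cues")


def make_curriculum(
    experiment: int,
    mapping_kind: MappingKind,
    alignment_or_ordering: str,
    rng_seed: Optional[int] = None,
    mapping: Optional[MappingSpec] = None,
) -> CurriculumSpec:
    """Construct a curriculum for one participant.

    Experiment 1 takes ``alignment_or_ordering`` in {"aligned",
    "misaligned"} and is always blocked; the aligned variant trains the
    central row and column of the rule space (central ring plus one spoke
    for polar mappings), the misaligned variant the two diagonals of the
    5x5 level lattice, whose locations form an X.  Experiment 2 is always
    aligned and takes ``alignment_or_ordering`` in {"blocked",
    "interleaved"}; its training row and column are drawn uniformly at
    random via ``rng_seed``.

    The lines are selected in spatial-level space and mapped back to cues
    through ``mapping`` (identity mapping assumed when omitted), so that
    e.g. "central row" is central on screen even when the per-participant
    level orders are shuffled.
    """
    if mapping is None:
        mapping = MappingSpec(kind=mapping_kind)
    elif mapping.kind != mapping_kind:
        raise ValueError("mapping.kind disagrees with mapping_kind")
    rng = np.random.default_rng(rng_seed)
    mid = (N_LEVELS - 1) // 2

    def axes_from_lines(l1: int, l2: int) -> tuple[list[Cue], list[Cue], Cue]:
        # axis_a varies spatial dim1 along the fixed dim2 line and vice versa
        overlap = mapping.cue_at(l1, l2)
        axis_a = [mapping.cue_at(d1, l2) for d1 in range(N_LEVELS) if d1 != l1]
        axis_b = [mapping.cue_at(l1, d2) for d2 in range(N_LEVELS) if d2 != l2]
        return axis_a, axis_b, overlap

    if experiment == 1:
        if alignment_or_ordering not in ("aligned", "misaligned"):
            raise ValueError(
                "experiment 1 takes alignment 'aligned' or 'misaligned', "
                f"got {alignment_or_ordering!r}"
            )
        alignment: Alignment = alignment_or_ordering  # type: ignore[assignment]
        ordering: Ordering = "blocked"
        if alignment == "aligned":
            axis_a, axis_b, overlap = axes_from_lines(mid, mid)
        else:
            # The two diagonals of the level lattice, sharing the central cue.
            overlap = mapping.cue_at(mid, mid)
            axis_a = [mapping.cue_at(i, i) for i in range(N_LEVELS) if i != mid]
            axis_b = [
                mapping.cue_at(i, N_LEVELS - 1 - i) for i in range(N_LEVELS) if i != mid
            ]
    elif experiment == 2:
        if alignment_or_ordering not in ("blocked", "interleaved"):
            raise ValueError(
                "experiment 2 takes ordering 'blocked' or 'interleaved', "
                f"got {alignment_or_ordering!r}"
            )
        alignment = "aligned"
        ordering = alignment_or_ordering  # type: ignore[assignment]
        l1 = int(rng.integers(N_LEVELS))
        l2 = int(rng.integers(N_LEVELS))
        axis_a, axis_b, overlap = axes_from_lines(l1, l2)
    else:
        raise ValueError(f"experiment must be 1 or 2, got {experiment!r}")

    train = frozenset(axis_a) | frozenset(axis_b) | {overlap}
    test = frozenset(all_cues()) - train
    return CurriculumSpec(
        experiment=experiment,  # type: ignore[arg-type]
        mapping_kind=mapping_kind,
        alignment=alignment,
        ordering=ordering,
        train_cues=train,
        test_cues=test,
        axis_a=tuple(axis_a),
        axis_b=tuple(axis_b),
        overlap=overlap,
        first_block_axis="a" if rng.integers(2) == 0 else "b",
    )


def order_training_trials(
    curriculum: CurriculumSpec, block: int, rng_seed: Optional[int] = None
) -> list[Cue]:
    """Order of the 9 training cues in one block.

    Blocked: trials 1-4 query one axis (shuffled within the axis), trial 5
    the shared cue, trials 6-9 the other axis; the leading axis alternates
    with block parity starting from the curriculum's randomized
    first-block axis.  Interleaved: a uniform permutation of all 9.
    """
    if not 1 <= block <= N_BLOCKS:
        raise ValueError(f"block must be in 1..{N_BLOCKS}, got {block}")
    rng = np.random.default_rng(rng_seed)
    if curriculum.ordering == "interleaved":
        cues = list(curriculum.train_cues)
        cues.sort()
        return [cues[i] for i in rng.permutation(len(cues))]
    a_first = (curriculum.first_block_axis == "a") == (block % 2 == 1)
    first, second = (
        (curriculum.axis_a, curriculum.axis_b)
        if a_first
        else (curriculum.axis_b, curriculum.axis_a)
    )
    first = [first[i] for i in rng.permutation(4)]
    second = [second[i] for i in rng.permutation(4)]
    return first + [curriculum.overlap] + second


def score_points(distance: float) -> int:
    """Points awarded for a response at the given distance from truth.

    Half-open bands: 5 for d in [0, 20), 2 for [20, 40), 1 for [40, 60),
    0 otherwise.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance < 20:
        return 5
    if distance < 40:
        return 2
    if distance < 60:
        return 1
    return 0


def is_correct(distance: float) -> bool:
    """Accuracy predicate used for exclusion: within 60 px of truth."""
    return 0 <= distance < CORRECT_RADIUS_PX


# ---------------------------------------------------------------------------
# Trial records and schedules
# ---------------------------------------------------------------------------

Phase = Literal["train", "test"]


@dataclass
class TrialRecord:
    """One trial of one participant or agent.

    ``response`` may be ``None`` only for ingested real data (timeouts);
    simulated agents and synthetic participants always respond.
    """

    participant_id: str
    block: int
    trial_in_block: int
    phase: Phase
    cue: Cue
    truth: tuple[float, float]
    response: Optional[tuple[float, float]] = None
    points: Optional[int] = None

    def with_response(self, x: float, y: float) -> "TrialRecord":
        d = math.hypot(x - self.truth[0], y - self.truth[1])
        return replace(self, response=(x, y), points=score_points(d))


def make_schedule(
    curriculum: CurriculumSpec,
    mapping: MappingSpec,
    rng_seed: Optional[int] = None,
    participant_id: str = "p0",
) -> list[list[TrialRecord]]:
    """14 blocks of 25 trial templates (responses unfilled).

    Training order follows :func:`order_training_trials`; the 16 test cues
    are independently and uniformly permuted in every block.
    """
    rng = np.random.default_rng(rng_seed)
    test_cues = sorted(curriculum.test_cues)
    blocks: list[list[TrialRecord]] = []
    for block in range(1, N_BLOCKS + 1):
        train_order = order_training_trials(
            curriculum, block, rng_seed=int(rng.integers(2**31))
        )
        test_order = [test_cues[i] for i in rng.permutation(len(test_cues))]
        records = []
        for t, cue in enumerate(train_order + test_order, start=1):
            phase: Phase = "train" if t <= N_TRAIN_TRIALS_PER_BLOCK else "test"
            records.append(
                TrialRecord(
                    participant_id=participant_id,
                    block=block,
                    trial_in_block=t,
                    phase=phase,
                    cue=cue,
                    truth=truth_location(mapping, cue),
                )
            )
        blocks.append(records)
    return blocks
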