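"""Response-density models on the arena disk and the log-likelihood ratio.

Generalization is scored by comparing the likelihood of test responses
under two (or three) response policies, each a proper probability density
over the circular arena:

* **random** -- uniform over the disk;
* **bilateral** -- a narrow Gaussian centered on the ground-truth point,
  defined in Cartesian coordinates for grid mappings and as a product of
  a radial Gaussian and a wrapped angular Gaussian for polar mappings;
* **unilateral** -- correct on one spatial dimension only: a Gaussian
  ridge over the truth's row/column (grid) or ring/spoke (polar), uniform
  over the other dimension.

All densities are normalized numerically on a shared square lattice
clipped to the disk, so truncation at the arena wall and the polar
parameterization are handled uniformly and likelihood comparisons across
models use identical support.  The headline statistic is the summed
log-likelihood ratio (LLR) of the bilateral over the random model;
LLR > 0 is evidence of generalization, and a participant or agent is a
*generalizer* when its mean per-block test LLR over blocks 8-14 (the
second half of the session) is positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .task_env import (
    Arena,
    MappingSpec,
    N_BLOCKS,
    TrialRecord,
)

__all__ = [
    "DEFAULT_SIGMA_PX",
    "DEFAULT_LATTICE_STEP_PX",
    "MAX_ANGULAR_SIGMA_RAD",
    "DiskDensity",
    "LlrSummary",
    "density_random",
    "density_bilateral",
    "density_unilateral",
    "angular_sigma",
    "wrap_angle",
    "llr",
    "llr_from_records",
    "classify_generalizer",
]

logger = logging.getLogger(__name__)

#: Default response-noise width, matching the narrow full-reward radius.
DEFAULT_SIGMA_PX: float = 20.0

#: Lattice step used for numerical normalization over the disk.
DEFAULT_LATTICE_STEP_PX: float = 2.0

#: Cap on the angular dispersion used by polar densities.
MAX_ANGULAR_SIGMA_RAD: float = 0.3

UnilateralDim = Literal["dim1", "dim2"]


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Map angular residuals to (-pi, pi]."""
    return -((-np.asarray(a) + math.pi) % (2.0 * math.pi) - math.pi)


def angular_sigma(sigma: float, rho_truth: float) -> float:
    """Angular dispersion equivalent to ``sigma`` px at radius ``rho_truth``.

    The arc-length-equivalent width ``sigma / rho`` is capped at
    :data:`MAX_ANGULAR_SIGMA_RAD` so the wrapped Gaussian stays narrow.
    """
    if rho_truth <= sigma:
        return MAX_ANGULAR_SIGMA_RAD
    return min(sigma / rho_truth, MAX_ANGULAR_SIGMA_RAD)


@lru_cache(maxsize=8)
def _disk_lattice(radius: float, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian coordinates of lattice points inside the closed disk."""
    g = np.arange(-radius, radius + step / 2, step)
    xx, yy = np.meshgrid(g, g)
    inside = xx**2 + yy**2 <= radius**2
    return xx[inside].copy(), yy[inside].copy()


@dataclass(frozen=True)
class DiskDensity:
    """A proper probability density over the arena disk.

    The density is ``exp(log_kernel(x, y)) / Z`` with ``Z`` the lattice
    sum of the kernel times the cell area, so the lattice integral of the
    density is exactly 1.
    """

    kind: Literal["random", "unilateral", "bilateral"]
    mapping_kind: Literal["grid", "polar"]
    truth: Optional[tuple[float, float]] = None
    unilateral_dim: Optional[UnilateralDim] = None
    sigma: float = DEFAULT_SIGMA_PX
    sigma_phi: Optional[float] = None
    arena: Arena = field(default_factory=Arena)
    lattice_step: float = DEFAULT_LATTICE_STEP_PX

    def __post_init__(self) -> None:
        if self.kind != "random" and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kind != "random" and self.truth is None:
            raise ValueError(f"{self.kind} density needs a truth point")
        if self.kind == "unilateral" and self.unilateral_dim not in ("dim1", "dim2"):
            raise ValueError("unilateral density needs unilateral_dim")

    # -- kernel ------------------------------------------------------------
    def log_kernel(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "random":
            return np.zeros(np.broadcast(x, y).shape)
        tx, ty = self.truth  # type: ignore[misc]
        if self.mapping_kind == "grid":
            lx = -((x - tx) ** 2) / (2 * self.sigma**2)
            ly = -((y - ty) ** 2) / (2 * self.sigma**2)
            if self.kind == "bilateral":
                return lx + ly
            return lx if self.unilateral_dim == "dim1" else ly
        # polar: dim1 = radius, dim2 = angle
        rho_t = math.hypot(tx, ty)
        phi_t = math.atan2(ty, tx)
        s_phi = self.sigma_phi if self.sigma_phi is not None else angular_sigma(
            self.sigma, rho_t
        )
        rho = np.hypot(x, y)
        phi = np.arctan2(y, x)
        lr = -((rho - rho_t) ** 2) / (2 * self.sigma**2)
        lp = -(np.asarray(wrap_angle(phi - phi_t)) ** 2) / (2 * s_phi**2)
        if self.kind == "bilateral":
            return lr + lp
        return lr if self.unilateral_dim == "dim1" else lp

    @property
    def log_norm(self) -> float:
        """log of the lattice normalization constant (cached)."""
        return _log_norm_cached(self)

    # -- evaluation --------------------------------------------------------
    def logpdf(self, x: np.ndarray | float, y: np.ndarray | float) -> np.ndarray:
        """Log-density at arbitrary points inside the disk (per px^2)."""
        return self.log_kernel(np.asarray(x), np.asarray(y)) - self.log_norm

    def lattice_pmf(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, cell probability) over the disk lattice; sums to 1."""
        xx, yy = _disk_lattice(self.arena.radius, self.lattice_step)
        p = np.exp(self.log_kernel(xx, yy) - self.log_norm) * self.lattice_step**2
        return xx, yy, p


@lru_cache(maxsize=4096)
def _log_norm_cached(density: DiskDensity) -> float:
    xx, yy = _disk_lattice(density.arena.radius, density.lattice_step)
    lk = density.log_kernel(xx, yy)
    m = float(np.max(lk))
    return m + math.log(float(np.sum(np.exp(lk - m))) * density.lattice_step**2)


def density_random(
    arena: Optional[Arena] = None,
    *,
    mapping_kind: Literal["grid", "polar"] = "grid",
    lattice_step: float = DEFAULT_LATTICE_STEP_PX,
) -> DiskDensity:
    """Uniform density over the disk (constant 1 / (pi R^2) up to lattice error)."""
    return DiskDensity(
        kind="random",
        mapping_kind=mapping_kind,
        arena=arena or Arena(),
        lattice_step=lattice_step,
    )


def density_bilateral(
    mapping: MappingSpec,
    truth: tuple[float, float],
    sigma: float = DEFAULT_SIGMA_PX,
    *,
    lattice_step: float = DEFAULT_LATTICE_STEP_PX,
) -> DiskDensity:
    """Narrow Gaussian centered on the truth, in the mapping's coordinates."""
    return DiskDensity(
        kind="bilateral",
        mapping_kind=mapping.kind,
        truth=truth,
        sigma=sigma,
        arena=mapping.arena,
        lattice_step=lattice_step,
    )


def density_unilateral(
    mapping: MappingSpec,
    truth: tuple[float, float],
    dim: UnilateralDim,
    sigma: float = DEFAULT_SIGMA_PX,
    *,
    lattice_step: float = DEFAULT_LATTICE_STEP_PX,
) -> DiskDensity:
    """Gaussian ridge correct on one spatial dimension, uniform on the other."""
    return DiskDensity(
        kind="unilateral",
        mapping_kind=mapping.kind,
        truth=truth,
        unilateral_dim=dim,
        sigma=sigma,
        arena=mapping.arena,
        lattice_step=lattice_step,
    )


# ---------------------------------------------------------------------------
# Log-likelihood ratio
# ---------------------------------------------------------------------------

SECOND_HALF_BLOCKS = tuple(range(8, N_BLOCKS + 1))


@dataclass
class LlrSummary:
    """Per-trial, per-block and second-half summed bilateral-vs-random LLR."""

    per_trial_logratio: np.ndarray
    per_block_llr: np.ndarray  # length 14, indexed by block-1
    mean_second_half: float
    is_generalizer: bool


def _clamp_to_disk(
    responses: np.ndarray, arena: Arena
) -> np.ndarray:
    r = np.hypot(responses[:, 0], responses[:, 1])
    outside = r > arena.radius
    if np.any(outside):
        logger.warning(
            "%d response(s) outside the arena clamped to the boundary",
            int(np.sum(outside)),
        )
        f = arena.radius / r[outside]
        responses = responses.copy()
        responses[outside] *= f[:, None]
    return responses


def llr(
    responses: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    mapping: MappingSpec,
    sigma: float = DEFAULT_SIGMA_PX,
    *,
    blocks: Optional[Sequence[int]] = None,
    lattice_step: float = DEFAULT_LATTICE_STEP_PX,
) -> LlrSummary:
    """Summed log-likelihood ratio of responses, bilateral vs random.

    ``responses`` is a sequence of (response point, truth point) pairs;
    ``blocks`` gives the 1-based block index of each trial (defaults to
    16 trials per block in order).  Responses outside the disk are
    clamped to the boundary with a logged warning.
    """
    n = len(responses)
    if n == 0:
        return LlrSummary(
            per_trial_logratio=np.zeros(0),
            per_block_llr=np.zeros(N_BLOCKS),
            mean_second_half=0.0,
            is_generalizer=False,
        )
    resp = np.asarray([r for r, _ in responses], dtype=float)
    truths = [t for _, t in responses]
    resp = _clamp_to_disk(resp, mapping.arena)
    if blocks is None:
        per_block = max(1, n // N_BLOCKS)
        blocks = [min(N_BLOCKS, i // per_block + 1) for i in range(n)]
    blocks = np.asarray(blocks, dtype=int)

    rnd = density_random(mapping.arena, mapping_kind=mapping.kind, lattice_step=lattice_step)
    log_rnd = rnd.logpdf(resp[:, 0], resp[:, 1])
    log_bi = np.empty(n)
    cache: dict[tuple[float, float], DiskDensity] = {}
    for i, t in enumerate(truths):
        d = cache.get(t)
        if d is None:
            d = density_bilateral(mapping, t, sigma, lattice_step=lattice_step)
            cache[t] = d
        log_bi[i] = d.logpdf(resp[i, 0], resp[i, 1])
    per_trial = log_bi - log_rnd
    per_block_llr = np.zeros(N_BLOCKS)
    for b in range(1, N_BLOCKS + 1):
        per_block_llr[b - 1] = per_trial[blocks == b].sum()
    mean_second_half = float(
        np.mean([per_block_llr[b - 1] for b in SECOND_HALF_BLOCKS])
    )
    return LlrSummary(
        per_trial_logratio=per_trial,
        per_block_llr=per_block_llr,
        mean_second_half=mean_second_half,
        is_generalizer=mean_second_half > 0,
    )


def llr_from_records(
    records: Iterable[TrialRecord],
    mapping: MappingSpec,
    sigma: float = DEFAULT_SIGMA_PX,
    *,
    phase: Literal["train", "test"] = "test",
    lattice_step: float = DEFAULT_LATTICE_STEP_PX,
) -> LlrSummary:
    """LLR summary over the responded trials of one phase of a trial log."""
    sel = [r for r in records if r.phase == phase and r.response is not None]
    return llr(
        [(r.response, r.truth) for r in sel],  # type: ignore[misc]
        mapping,
        sigma,
        blocks=[r.block for r in sel],
        lattice_step=lattice_step,
    )


def classify_generalizer(summary: LlrSummary) -> bool:
    """True iff mean per-block LLR over blocks 8-14 is positive."""
    if len(summary.per_block_llr) < N_BLOCKS:
        raise ValueError("generalizer classification needs all 14 blocks")
    return bool(
        np.mean([summary.per_block_llr[b - 1] for b in SECOND_HALF_BLOCKS]) > 0
    )
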