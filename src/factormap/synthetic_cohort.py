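"""Synthetic participants with known ground-truth response policies.

Every analysis stage in this package can be exercised without any
external data: a synthetic participant follows a known per-block policy
schedule (random, unilateral, or bilateral, in ascending order) and
samples each test response from the corresponding disk density of
:mod:`factormap.response_models`.  Training responses follow a logistic
accuracy ramp -- mostly random in block 1, bilateral-with-noise
afterwards -- which is only there to make training accuracies realistic
for the exclusion rule; it plays no role in the generalization analyses.

Sampling is by exact rejection: Cartesian Gaussians are proposed
directly and rejected outside the disk, while polar-coordinate kernels
are proposed in (rho, phi) and accepted with probability rho / R, which
cancels the polar Jacobian so the samples follow the same Cartesian
kernel the densities are normalized with.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .response_models import (
    DEFAULT_SIGMA_PX,
    DiskDensity,
    angular_sigma,
    density_bilateral,
    density_random,
    density_unilateral,
    wrap_angle,
)
from .task_env import (
    CurriculumSpec,
    MappingSpec,
    N_BLOCKS,
    TrialRecord,
    make_curriculum,
    make_mapping,
    make_schedule,
)

__all__ = [
    "Stage",
    "SyntheticPolicySpec",
    "sample_density",
    "stage_density",
    "simulate_participant",
    "simulate_cohort",
]

Stage = Literal["random", "unilateral", "bilateral"]
STAGE_ORDER: dict[str, int] = {"random": 0, "unilateral": 1, "bilateral": 2}


# ---------------------------------------------------------------------------
# Exact samplers for the disk densities
# ---------------------------------------------------------------------------

def sample_density(
    density: DiskDensity, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` points from a disk density by exact rejection sampling."""
    R = density.arena.radius
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(64, 2 * (n - got))
        if density.kind == "random":
            x = rng.uniform(-R, R, m)
            y = rng.uniform(-R, R, m)
            keep = x**2 + y**2 <= R**2
        elif density.mapping_kind == "grid":
            tx, ty = density.truth  # type: ignore[misc]
            if density.kind == "bilateral":
                x = rng.normal(tx, density.sigma, m)
                y = rng.normal(ty, density.sigma, m)
            elif density.unilateral_dim == "dim1":
                x = rng.normal(tx, density.sigma, m)
                y = rng.uniform(-R, R, m)
            else:
                x = rng.uniform(-R, R, m)
                y = rng.normal(ty, density.sigma, m)
            keep = x**2 + y**2 <= R**2
        else:  # polar kernels: propose in (rho, phi), accept w.p. rho / R
            tx, ty = density.truth  # type: ignore[misc]
            rho_t = math.hypot(tx, ty)
            phi_t = math.atan2(ty, tx)
            s_phi = (
                density.sigma_phi
                if density.sigma_phi is not None
                else angular_sigma(density.sigma, rho_t)
            )
            if density.kind == "bilateral":
                rho = rng.normal(rho_t, density.sigma, m)
                phi = phi_t + rng.normal(0.0, s_phi, m)
            elif density.unilateral_dim == "dim1":
                rho = rng.normal(rho_t, density.sigma, m)
                phi = rng.uniform(-math.pi, math.pi, m)
            else:
                rho = rng.uniform(0.0, R, m)
                phi = phi_t + rng.normal(0.0, s_phi, m)
            keep = (
                (rho > 0)
                & (rho <= R)
                & (np.abs(wrap_angle(phi - phi_t)) <= math.pi)  # single-wrap kernel
                & (rng.uniform(0.0, 1.0, m) <= rho / R)
            )
            x = rho * np.cos(phi)
            y = rho * np.sin(phi)
        accepted = np.column_stack([x[keep], y[keep]])
        take = min(n - got, len(accepted))
        out[got : got + take] = accepted[:take]
        got += take
    return out


def stage_density(
    stage: Stage,
    mapping: MappingSpec,
    truth: tuple[float, float],
    sigma: float = DEFAULT_SIGMA_PX,
    unilateral_dim: Literal["dim1", "dim2"] = "dim1",
) -> DiskDensity:
    """The response density of one policy stage for one cue's truth."""
    if stage == "random":
        return density_random(mapping.arena, mapping_kind=mapping.kind)
    if stage == "bilateral":
        return density_bilateral(mapping, truth, sigma)
    return density_unilateral(mapping, truth, unilateral_dim, sigma)


# ---------------------------------------------------------------------------
# Synthetic participants
# ---------------------------------------------------------------------------

def _default_schedule() -> tuple[Stage, ...]:
    return ("random",) * 3 + ("unilateral",) * 5 + ("bilateral",) * 6


@dataclass(frozen=True)
class SyntheticPolicySpec:
    """Ground-truth generative description of one synthetic participant.

    ``stage_schedule`` assigns one policy stage to each of the 14 blocks
    and must be non-decreasing in the order random < unilateral <
    bilateral.  ``train_ramp`` is (asymptote, midpoint block, rate) of
    the logistic probability that a training response is on-target
    (bilateral with ``train_sigma``) rather than random.
    """

    participant_id: str = "sim0"
    experiment: Literal[1, 2] = 1
    mapping_kind: Literal["grid", "polar"] = "grid"
    condition: str = "aligned"
    stage_schedule: tuple[Stage, ...] = field(default_factory=_default_schedule)
    unilateral_dim: Literal["dim1", "dim2"] = "dim1"
    response_sigma: float = DEFAULT_SIGMA_PX
    train_sigma: float = DEFAULT_SIGMA_PX
    train_ramp: tuple[float, float, float] = (0.97, 1.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_schedule) != N_BLOCKS:
            raise ValueError(f"stage_schedule must cover all {N_BLOCKS} blocks")
        orders = [STAGE_ORDER[s] for s in self.stage_schedule]
        if any(b < a for a, b in zip(orders, orders[1:])):
            raise ValueError("stage_schedule must be monotone non-decreasing")
        if self.response_sigma <= 0 or self.train_sigma <= 0:
            raise ValueError("sigmas must be positive")

    def p_train_on_target(self, block: int) -> float:
        asym, mid, rate = self.train_ramp
        return asym / (1.0 + math.exp(-(block - mid) / rate))


def simulate_participant(
    spec: SyntheticPolicySpec,
) -> tuple[MappingSpec, CurriculumSpec, list[TrialRecord]]:
    """Simulate one participant's full 14-block trial log."""
    ss = np.random.SeedSequence(spec.seed)
    s_map, s_cur, s_sched, s_resp = (int(v >> np.uint32(1)) for v in ss.generate_state(4))
    mapping = make_mapping(spec.mapping_kind, s_map)
    curriculum = make_curriculum(
        spec.experiment, spec.mapping_kind, spec.condition, s_cur, mapping=mapping
    )
    schedule = make_schedule(
        curriculum, mapping, s_sched, participant_id=spec.participant_id
    )
    rng = np.random.default_rng(s_resp)

    records: list[TrialRecord] = []
    cache: dict[tuple, DiskDensity] = {}

    def density_for(stage: Stage, truth: tuple[float, float], sigma: float) -> DiskDensity:
        key = (stage, truth, sigma)
        if key not in cache:
            cache[key] = stage_density(
                stage, mapping, truth, sigma, spec.unilateral_dim
            )
        return cache[key]

    for block_records in schedule:
        block = block_records[0].block
        stage = spec.stage_schedule[block - 1]
        p_on = spec.p_train_on_target(block)
        for trial in block_records:
            if trial.phase == "train":
                on_target = rng.uniform() < p_on
                d = density_for(
                    "bilateral" if on_target else "random",
                    trial.truth,
                    spec.train_sigma,
                )
            else:
                d = density_for(stage, trial.truth, spec.response_sigma)
            (x, y), = sample_density(d, 1, rng)
            records.append(trial.with_response(float(x), float(y)))
    return mapping, curriculum, records


def simulate_cohort(
    n: int,
    seed: int,
    spec_template: Optional[SyntheticPolicySpec] = None,
    spec_overrides: Optional[Sequence[dict]] = None,
) -> tuple[list[tuple[MappingSpec, CurriculumSpec, list[TrialRecord]]], list[dict]]:
    """Simulate ``n`` participants and return their logs plus a manifest.

    Each participant gets an independent seed spawned from ``seed``.
    ``spec_overrides`` (one dict per participant, recycled if shorter)
    can vary any :class:`SyntheticPolicySpec` field across the cohort.
    The manifest records every true policy parameter for recovery
    scoring.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    template = spec_template or SyntheticPolicySpec()
    ss = np.random.SeedSequence(seed)
    cohort = []
    manifest = []
    for i, child in enumerate(ss.spawn(n)):
        overrides = dict(
            spec_overrides[i % len(spec_overrides)] if spec_overrides else {}
        )
        fields = asdict(template)
        fields.update(overrides)
        fields["participant_id"] = overrides.get("participant_id", f"sim{i}")
        fields["seed"] = int(child.generate_state(1)[0] >> np.uint32(1))
        fields["stage_schedule"] = tuple(fields["stage_schedule"])
        fields["train_ramp"] = tuple(fields["train_ramp"])
        spec = SyntheticPolicySpec(**fields)
        cohort.append(simulate_participant(spec))
        manifest.append(asdict(spec))
    return cohort, manifest
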