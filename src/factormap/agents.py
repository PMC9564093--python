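"""Learning agents: a vanilla effector network and a Hebbian gating network.

Both agents are linear read-outs from a two-hot cue encoding (5 color
slots + 5 shape slots) onto four spatial *effectors* -- horizontal
translation, vertical translation, expansion and rotation -- which are
composed into a screen position:

    p = R(phi) @ (trans_x + rho, trans_y)

where ``R`` is the 2-D rotation about the arena center.  The effector
basis is redundant: a grid solution uses the two translations with
``rho = phi = 0`` while a polar solution uses expansion and rotation with
zero translation.  Which basis the network commits to is what decides
whether it generalizes compositionally.

The **vanilla** network trains its feedforward weights ``W`` by
stochastic gradient descent on the squared screen-position error.  The
**Hebbian gating** network multiplies ``W`` elementwise by a binary gate
``g_tau(U)`` obtained by thresholding separately learned Hebbian weights
``U``.  On every feedback trial, ``U`` is updated from the coincidence of
*change* between inputs and outputs relative to the previous trials of
the same block: a gate is excited when its input feature and output
effector change together and depressed whenever its input changes at all
(*preactivated depression*), with an exponential recency discount
``lambda`` over the within-block history.  A connection whose input and
output always change together converges to ``U = 0.5``; one whose input
changes while the output stays put decays to 0.  Gates therefore open
only between cue features and effectors that covary in time, which under
an axis-aligned blocked curriculum singles out the ground-truth
factorized mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Optional, Sequence, Union

import numpy as np

from .task_env import (
    ARENA_RADIUS_PX,
    Arena,
    Cue,
    CurriculumSpec,
    MappingSpec,
    TrialRecord,
    make_curriculum,
    make_mapping,
    make_schedule,
)

__all__ = [
    "EffectorVector",
    "AgentHyperparams",
    "VanillaNetState",
    "HebbGateState",
    "encode_cue",
    "effector_to_point",
    "point_to_effector_targets",
    "forward",
    "sgd_step",
    "hebb_update",
    "run_agent",
    "run_condition",
]

N_INPUTS = 10
N_EFFECTORS = 4


class EffectorVector(NamedTuple):
    """Physical effector coordinates (px, px, px, radians)."""

    trans_x: float
    trans_y: float
    rho: float
    phi: float


def encode_cue(cue: Cue) -> np.ndarray:
    """Two-hot encoding: one of 5 color slots and one of 5 shape slots."""
    x = np.zeros(N_INPUTS)
    x[cue.color_level] = 1.0
    x[5 + cue.shape_level] = 1.0
    return x


def effector_to_point(e: Union[EffectorVector, Sequence[float]]) -> tuple[float, float]:
    """Compose the four effectors into a screen position."""
    tx, ty, rho, phi = e
    c, s = math.cos(phi), math.sin(phi)
    vx, vy = tx + rho, ty
    return (c * vx - s * vy, s * vx + c * vy)


def point_to_effector_targets(p: tuple[float, float]) -> EffectorVector:
    """Redundant 4-coordinate description of a feedback point.

    Used as the output signal ``z`` in the Hebbian surprise computation;
    the angle at the exact arena center is defined as 0 by convention.
    """
    x, y = p
    rho = math.hypot(x, y)
    phi = math.atan2(y, x) if rho > 0 else 0.0
    return EffectorVector(x, y, rho, phi)


@dataclass(frozen=True)
class AgentHyperparams:
    """Shared agent hyperparameters (one set for all conditions).

    ``output_scale`` converts unit-free network activations into physical
    effector coordinates (px for the translations and expansion, radians
    for rotation), so all weights live on a comparable O(1) scale and a
    single SGD rate works for every effector.  The loss is the squared
    screen-position error in units of the arena radius.

    ``w_init_sd`` is per effector: the larger rotation init gives every
    agent idiosyncratic per-cue rotation offsets, which a linear network
    can fit through during training but which break additive composition
    on held-out cue combinations.  ``u_init`` starts just below ``tau``
    (the network begins fully gated) so that a few consistent
    co-change events suffice to open a gate while the Hebbian fixed
    points U* = q / (1 + q) -- q the co-change probability of the
    connection -- still decide which gates stay open: q = 1 channels
    settle at 0.5 (open), channels whose output changes on only ~2/3 of
    input changes settle near 0.40 (at threshold), and rarer coincidence
    decays shut.
    """

    sgd_rate: float = 0.06
    steps_per_trial: int = 3
    tau: float = 0.40
    alpha_u: float = 0.2
    lam: float = 0.5
    w_init_sd: tuple[float, float, float, float] = (0.35, 0.35, 0.35, 0.2)
    u_init: float = 0.39
    dz_eps: float = 1e-6
    output_scale: tuple[float, float, float, float] = (
        ARENA_RADIUS_PX,
        ARENA_RADIUS_PX,
        ARENA_RADIUS_PX,
        1.0,
    )

    def __post_init__(self) -> None:
        if not 0 < self.tau < 0.5:
            raise ValueError("tau must lie in (0, 0.5)")
        if not 0 <= self.u_init < self.tau:
            raise ValueError("u_init must lie in [0, tau): the net starts fully gated")
        if not 0 <= self.alpha_u <= 1:
            raise ValueError("alpha_u must lie in [0, 1]")
        if not 0 < self.lam <= 1:
            raise ValueError("lambda must lie in (0, 1]")


@dataclass
class VanillaNetState:
    """Linear effector network trained by plain SGD."""

    W: np.ndarray  # (4, 10), unit-free activations
    hp: AgentHyperparams = field(default_factory=AgentHyperparams)

    @classmethod
    def init(
        cls, rng: np.random.Generator, hp: Optional[AgentHyperparams] = None
    ) -> "VanillaNetState":
        hp = hp or AgentHyperparams()
        sd = np.asarray(hp.w_init_sd)[:, None]
        return cls(W=rng.normal(0.0, 1.0, size=(N_EFFECTORS, N_INPUTS)) * sd, hp=hp)


@dataclass
class HebbGateState:
    """Vanilla network plus Hebbian gate weights ``U`` in [0, 1].

    ``history`` holds the (input, target-effector) pairs of the feedback
    trials seen so far in the current block; it is cleared at every block
    boundary while ``U`` persists across blocks.
    """

    W: np.ndarray  # (4, 10)
    U: np.ndarray  # (4, 10), entries in [0, 1]
    hp: AgentHyperparams = field(default_factory=AgentHyperparams)
    history: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @classmethod
    def init(
        cls, rng: np.random.Generator, hp: Optional[AgentHyperparams] = None
    ) -> "HebbGateState":
        hp = hp or AgentHyperparams()
        sd = np.asarray(hp.w_init_sd)[:, None]
        return cls(
            W=rng.normal(0.0, 1.0, size=(N_EFFECTORS, N_INPUTS)) * sd,
            U=np.full((N_EFFECTORS, N_INPUTS), hp.u_init, dtype=float),
            hp=hp,
        )

    def gate(self) -> np.ndarray:
        """Binary gate mask g_tau(U): 1 where U > tau."""
        return (self.U > self.hp.tau).astype(float)

    def reset_block(self) -> None:
        self.history.clear()


AgentState = Union[VanillaNetState, HebbGateState]


def _activations(state: AgentState, x: np.ndarray) -> np.ndarray:
    if isinstance(state, HebbGateState):
        return (state.W * state.gate()) @ x
    return state.W @ x


def forward(state: AgentState, x: np.ndarray) -> EffectorVector:
    """Forward pass: gated (or plain) linear map scaled to physical units."""
    z = _activations(state, x)
    e = z * np.asarray(state.hp.output_scale)
    return EffectorVector(*e)


def _position_and_jacobian(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Screen position and its 2x4 Jacobian w.r.t. the physical effectors."""
    tx, ty, rho, phi = e
    c, s = math.cos(phi), math.sin(phi)
    v1, v2 = tx + rho, ty
    p = np.array([c * v1 - s * v2, s * v1 + c * v2])
    J = np.array(
        [
            [c, -s, c, -s * v1 - c * v2],
            [s, c, s, c * v1 - s * v2],
        ]
    )
    return p, J


def sgd_step(
    state: AgentState, x: np.ndarray, feedback: tuple[float, float]
) -> AgentState:
    """One trial's SGD update of ``W`` toward the feedback position.

    Performs ``steps_per_trial`` gradient steps on the squared position
    error (in arena-radius units).  For the Hebbian agent, gradients flow
    only through open gates: closed-gate entries of ``W`` are untouched.
    """
    hp = state.hp
    scale = np.asarray(hp.output_scale)
    target = np.asarray(feedback, dtype=float)
    gate = state.gate() if isinstance(state, HebbGateState) else None
    W = state.W.copy()
    r2 = ARENA_RADIUS_PX**2
    for _ in range(hp.steps_per_trial):
        z = (W * gate) @ x if gate is not None else W @ x
        e = z * scale
        p, J = _position_and_jacobian(e)
        # dL/dz with L = |p - target|^2 / R^2
        g = (2.0 / r2) * (J.T @ (p - target)) * scale
        dW = np.outer(g, x)
        if gate is not None:
            dW *= gate
        W -= hp.sgd_rate * dW
    return replace(state, W=W)


def hebb_update(
    state: HebbGateState, x_t: np.ndarray, z_t: Union[EffectorVector, Sequence[float]]
) -> HebbGateState:
    """Hebbian gate update from one feedback trial.

    ``z_t`` is the feedback location in effector coordinates (from
    :func:`point_to_effector_targets`).  Against every earlier feedback
    trial ``i`` of the current block, compute the input-change vector
    ``dx = |x_t - x_i|`` and the output-change indicator
    ``dz = 1(|z_t - z_i| > eps)``; the per-pair update is excitation
    where input and output changed together minus preactivated depression
    wherever the input changed:

        M_i = (dz outer dx) * (1 - U) - (1 outer dx) * U

    Pairs are combined with normalized recency weights
    ``lambda^(t-i) / sum_j lambda^(t-j)`` and scaled by ``alpha_u``.
    Every entry of ``U`` provably stays in [0, 1] (each per-pair term
    lies in [-U, 1-U] and the weights form a convex combination).  The
    trial is appended to the block history afterwards.  On the first
    feedback trial of a block there is nothing to compare against and
    ``U`` is unchanged.
    """
    z_t = np.asarray(z_t, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    U = state.U
    hist = state.history
    if hist:
        n = len(hist)
        weights = np.array([state.hp.lam ** (n + 1 - (i + 1)) for i in range(n)])
        weights /= weights.sum()
        M = np.zeros_like(U)
        for w_i, (x_i, z_i) in zip(weights, hist):
            dx = np.abs(x_t - x_i)
            dz = (np.abs(z_t - z_i) > state.hp.dz_eps).astype(float)
            M += w_i * (np.outer(dz, dx) * (1.0 - U) - np.outer(np.ones(N_EFFECTORS), dx) * U)
        U = U + state.hp.alpha_u * M
    new = replace(state, U=U)
    new.history = hist + [(x_t, z_t)]
    return new


def run_agent(
    agent_kind: Literal["vanilla", "hebbian"],
    schedule: Sequence[Sequence[TrialRecord]],
    mapping: MappingSpec,
    hyperparams: Optional[AgentHyperparams] = None,
    rng_seed: Optional[int] = None,
) -> list[TrialRecord]:
    """Train and evaluate one agent on a 14-block schedule.

    Training trials: forward pass, record the (disk-clipped) response,
    Hebbian gate update (hebbian agent only), then SGD on the feedback
    location.  Test trials: forward pass and record only -- no updates.
    The Hebbian within-block history is reset at each block boundary;
    identical seeds reproduce identical records.
    """
    rng = np.random.default_rng(rng_seed)
    hp = hyperparams or AgentHyperparams()
    state: AgentState
    if agent_kind == "vanilla":
        state = VanillaNetState.init(rng, hp)
    elif agent_kind == "hebbian":
        state = HebbGateState.init(rng, hp)
    else:
        raise ValueError(f"unknown agent kind {agent_kind!r}")

    arena = mapping.arena
    out: list[TrialRecord] = []
    for block in schedule:
        if isinstance(state, HebbGateState):
            state.reset_block()
        for trial in block:
            x = encode_cue(trial.cue)
            p = effector_to_point(forward(state, x))
            px, py = arena.clip(*p)
            out.append(trial.with_response(px, py))
            if trial.phase == "train":
                if isinstance(state, HebbGateState):
                    z = point_to_effector_targets(trial.truth)
                    state = hebb_update(state, x, z)
                state = sgd_step(state, x, trial.truth)
    return out


def run_condition(
    agent_kind: Literal["vanilla", "hebbian"],
    experiment: int,
    mapping_kind: Literal["grid", "polar"],
    condition: str,
    n_agents: int,
    seed: int,
    hyperparams: Optional[AgentHyperparams] = None,
    arena: Optional[Arena] = None,
) -> list[tuple[MappingSpec, CurriculumSpec, list[TrialRecord]]]:
    """Run a cohort of agents in one experimental condition.

    Each agent gets its own participant-level randomizations (mapping,
    curriculum, trial orders, weight init) derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    runs = []
    for i, child in enumerate(ss.spawn(n_agents)):
        s1, s2, s3, s4 = child.generate_state(4) >> np.uint32(1)  # keep < 2**31
        mapping = make_mapping(mapping_kind, int(s1), arena=arena)
        curriculum = make_curriculum(
            experiment, mapping_kind, condition, int(s2), mapping=mapping
        )
        schedule = make_schedule(
            curriculum, mapping, int(s3), participant_id=f"{agent_kind}-{i}"
        )
        records = run_agent(agent_kind, schedule, mapping, hyperparams, int(s4))
        runs.append((mapping, curriculum, records))
    return runs
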