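"""Agents: encodings, effector geometry, SGD, and Hebbian gating."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from factormap.agents import (
    AgentHyperparams,
    HebbGateState,
    VanillaNetState,
    effector_to_point,
    encode_cue,
    forward,
    hebb_update,
    point_to_effector_targets,
    run_agent,
    sgd_step,
)
from factormap.task_env import Cue, all_cues


class TestEncoding:
    def test_two_hot_positions(self):
        x = encode_cue(Cue(0, 0))
        assert x[0] == 1 and x[5] == 1 and x.sum() == 2

    @pytest.mark.parametrize("cue", [Cue(0, 4), Cue(3, 1), Cue(4, 4)])
    def test_every_encoding_sums_to_two(self, cue):
        x = encode_cue(cue)
        assert x.sum() == 2 and set(np.unique(x)) == {0.0, 1.0}

    def test_shared_color_shares_exactly_one_slot(self):
        a, b = encode_cue(Cue(2, 0)), encode_cue(Cue(2, 3))
        assert int((a * b).sum()) == 1


class TestEffectorGeometry:
    @pytest.mark.parametrize(
        "e,point",
        [
            ((0, 0, 0, 0), (0.0, 0.0)),
            ((100, 50, 0, 0), (100.0, 50.0)),
            ((0, 0, 212, math.pi / 2), (0.0, 212.0)),
        ],
    )
    def test_effector_composition(self, e, point):
        assert effector_to_point(e) == pytest.approx(point, abs=1e-9)

    @pytest.mark.parametrize(
        "p,targets",
        [
            ((0, 0), (0, 0, 0, 0)),
            ((212, 0), (212, 0, 212, 0)),
            ((-90, 0), (-90, 0, 90, math.pi)),
        ],
    )
    def test_point_to_effector_targets(self, p, targets):
        assert tuple(point_to_effector_targets(p)) == pytest.approx(targets)

    @given(
        x=st.floats(-250, 250),
        y=st.floats(-250, 250),
    )
    @settings(max_examples=50, deadline=None)
    def test_effector_targets_recompose_to_the_point(self, x, y):
        e = point_to_effector_targets((x, y))
        px, py = effector_to_point((e.trans_x, e.trans_y, 0.0, 0.0))
        assert (px, py) == pytest.approx((x, y), abs=1e-9)
        px, py = effector_to_point((0.0, 0.0, e.rho, e.phi))
        assert (px, py) == pytest.approx((x, y), abs=1e-9)


def _hebb_state(hp=None, u=None):
    hp = hp or AgentHyperparams()
    state = HebbGateState.init(np.random.default_rng(0), hp)
    if u is not None:
        state.U = np.full_like(state.U, u)
    return state


class TestForward:
    def test_zero_weights_give_zero_output(self):
        s = VanillaNetState.init(np.random.default_rng(0))
        s.W[:] = 0.0
        assert tuple(forward(s, encode_cue(Cue(1, 1)))) == (0, 0, 0, 0)

    def test_closed_gates_silence_any_weights(self):
        s = _hebb_state(u=0.0)
        s.W[:] = 7.0
        assert tuple(forward(s, encode_cue(Cue(3, 2)))) == (0, 0, 0, 0)

    def test_open_gates_match_vanilla_forward(self):
        hp = AgentHyperparams(tau=0.3, u_init=0.0)
        h = _hebb_state(hp, u=1.0)
        v = VanillaNetState(W=h.W.copy(), hp=hp)
        x = encode_cue(Cue(4, 0))
        assert tuple(forward(h, x)) == pytest.approx(tuple(forward(v, x)), abs=0)

    def test_gate_monotonicity_raising_tau_never_opens_gates(self):
        state = _hebb_state()
        state.U = np.random.default_rng(3).uniform(0, 0.5, state.U.shape)
        low = HebbGateState(W=state.W, U=state.U, hp=AgentHyperparams(tau=0.2, u_init=0.1))
        high = HebbGateState(W=state.W, U=state.U, hp=AgentHyperparams(tau=0.45, u_init=0.1))
        assert np.all(high.gate() <= low.gate())


class TestSgdStep:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        hp = AgentHyperparams(sgd_rate=0.0)
        s = VanillaNetState.init(np.random.default_rng(0), hp)
        W0 = s.W.copy()
        s = sgd_step(s, encode_cue(Cue(0, 0)), (100.0, -50.0))
        assert np.array_equal(s.W, W0)

    def test_closed_gate_entries_receive_exactly_zero_update(self):
        s = _hebb_state(u=0.0)
        s.U[0, 0] = 0.9  # open a single gate
        W0 = s.W.copy()
        s2 = sgd_step(s, encode_cue(Cue(0, 0)), (50.0, 0.0))
        changed = s2.W != W0
        assert changed[0, 0]
        changed[0, 0] = False
        assert not changed.any()

    def test_repeated_steps_on_one_trial_do_not_increase_loss(self):
        hp = AgentHyperparams(sgd_rate=0.01, steps_per_trial=1)
        s = _hebb_state(hp, u=0.0)
        s.U[0, 0] = 0.9
        x = encode_cue(Cue(0, 0))
        target = (120.0, 0.0)

        def loss(state):
            p = effector_to_point(forward(state, x))
            return (p[0] - target[0]) ** 2 + (p[1] - target[1]) ** 2

        losses = [loss(s)]
        for _ in range(50):
            s = sgd_step(s, x, target)
            losses.append(loss(s))
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))
        assert losses[-1] < losses[0]


class TestHebbUpdate:
    def test_first_coincidence_from_zero_rises_by_alpha(self):
        hp = AgentHyperparams(alpha_u=0.1, u_init=0.0)
        s = _hebb_state(hp, u=0.0)
        x0 = encode_cue(Cue(0, 2))
        s = hebb_update(s, x0, point_to_effector_targets((-180.0, 0.0)))
        assert np.array_equal(s.U, np.zeros_like(s.U))  # first trial: no comparison
        x1 = encode_cue(Cue(1, 2))
        s = hebb_update(s, x1, point_to_effector_targets((-90.0, 0.0)))
        # color changed (slots 0 and 1) and trans_x changed: excitation = alpha * 1
        assert s.U[0, 0] == pytest.approx(0.1)
        assert s.U[0, 1] == pytest.approx(0.1)
        # trans_y unchanged on this row: pure preactivated depression from 0 stays 0
        assert s.U[1, 0] == 0.0
        # shape slots unchanged: no update at all
        assert np.all(s.U[:, 5:] == 0.0)

    def test_identical_consecutive_inputs_leave_u_unchanged(self):
        s = _hebb_state(u=0.25)
        x = encode_cue(Cue(2, 2))
        s = hebb_update(s, x, point_to_effector_targets((0.0, 0.0)))
        u_before = s.U.copy()
        s = hebb_update(s, x, point_to_effector_targets((50.0, 50.0)))
        assert np.array_equal(s.U, u_before)

    def test_consistent_cochange_converges_to_half(self):
        hp = AgentHyperparams(alpha_u=0.2, u_init=0.0)
        s = _hebb_state(hp, u=0.0)
        rng = np.random.default_rng(0)
        xs = [encode_cue(Cue(i % 5, (i + 1) % 5)) for i in range(60)]
        for i, x in enumerate(xs):
            z = point_to_effector_targets((rng.uniform(-200, 200), rng.uniform(-200, 200)))
            s = hebb_update(s, x, z)
            if (i + 1) % 9 == 0:
                s.reset_block()
        # every input and output changes on every comparison -> fixed point 1/2
        active = s.U[np.abs(s.U) > 1e-12]
        assert np.all(np.abs(active - 0.5) < 0.1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_u_stays_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        hp = AgentHyperparams(alpha_u=float(rng.uniform(0.05, 1.0)), u_init=float(rng.uniform(0, 0.39)))
        s = HebbGateState.init(rng, hp)
        cues = all_cues()
        for t in range(40):
            cue = cues[rng.integers(25)]
            z = point_to_effector_targets((rng.uniform(-260, 260), rng.uniform(-100, 100)))
            s = hebb_update(s, encode_cue(cue), z)
            if t % 9 == 8:
                s.reset_block()
            assert np.all(s.U >= 0.0) and np.all(s.U <= 1.0)


class TestRunAgent:
    def test_same_seed_gives_identical_records(self, aligned_schedule, grid_mapping):
        _, schedule = aligned_schedule
        a = run_agent("hebbian", schedule, grid_mapping, rng_seed=9)
        b = run_agent("hebbian", schedule, grid_mapping, rng_seed=9)
        assert [(t.response, t.points) for t in a] == [(t.response, t.points) for t in b]

    def test_frozen_gates_pin_responses_at_center(self, aligned_schedule, grid_mapping):
        _, schedule = aligned_schedule
        hp = AgentHyperparams(alpha_u=0.0, u_init=0.0)
        recs = run_agent("hebbian", schedule, grid_mapping, hp, rng_seed=0)
        assert all(t.response == (0.0, 0.0) for t in recs)

    def test_all_responses_inside_arena(self, aligned_schedule, grid_mapping):
        _, schedule = aligned_schedule
        for kind in ("vanilla", "hebbian"):
            recs = run_agent(kind, schedule, grid_mapping, rng_seed=2)
            assert all(
                math.hypot(*t.response) <= grid_mapping.arena.radius + 1e-9 for t in recs
            )
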