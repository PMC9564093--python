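"""Policy-sequence fitting, RFX-BMS, matched cohorts, inflection points."""

import numpy as np
import pytest

from factormap.policy_fit import (
    ADMISSIBLE_STAGE_SETS,
    build_matched_cohort,
    crossval_inflection,
    delta_llr,
    fit_all_models,
    fit_policy_sequence,
    rfx_bms,
    unilateral_attribution,
)
from factormap.response_models import llr_from_records
from factormap.synthetic_cohort import SyntheticPolicySpec, simulate_participant
from factormap.task_env import TrialRecord


def simulate(schedule, seed=0, sigma=10.0, dim="dim1", mapping_kind="grid"):
    spec = SyntheticPolicySpec(
        stage_schedule=tuple(schedule),
        unilateral_dim=dim,
        response_sigma=sigma,
        mapping_kind=mapping_kind,
        seed=seed,
    )
    return simulate_participant(spec)


class TestFitPolicySequence:
    def test_pure_random_data_prefers_single_random_stage(self):
        mapping, _, recs = simulate(["random"] * 14, seed=3, sigma=20.0)
        fits = fit_all_models(recs, mapping, sigma=20.0)
        best = max(fits.values(), key=lambda m: m.evidence)
        assert best.stages == ("random",)

    def test_bilateral_model_dominates_on_its_own_data(self):
        mapping, _, recs = simulate(["bilateral"] * 14, seed=4, sigma=20.0)
        fits = fit_all_models(recs, mapping, sigma=20.0)
        assert fits[("bilateral",)].loglik > fits[("random",)].loglik

    def test_switch_points_recovered_on_low_noise_data(self):
        mapping, _, recs = simulate(
            ["random"] * 3 + ["unilateral"] * 5 + ["bilateral"] * 6, seed=5
        )
        fit = fit_policy_sequence(
            recs, mapping, ("random", "unilateral", "bilateral"), sigma=10.0
        )
        assert fit.switch_blocks == (4, 9)
        assert fit.unilateral_dim == "dim1"

    def test_adding_a_stage_never_decreases_loglik(self):
        mapping, _, recs = simulate(["random"] * 7 + ["bilateral"] * 7, seed=6)
        fits = fit_all_models(recs, mapping, sigma=10.0)
        assert fits[("random", "bilateral")].loglik >= fits[("random",)].loglik
        assert (
            fits[("random", "unilateral", "bilateral")].loglik
            >= fits[("random", "bilateral")].loglik
        )

    def test_bic_penalty_counts_free_parameters(self):
        mapping, _, recs = simulate(["random"] * 14, seed=7)
        fits = fit_all_models(recs, mapping, sigma=10.0)
        n = 224
        for stages, fit in fits.items():
            k = (len(stages) - 1) + (1 if "unilateral" in stages else 0)
            assert fit.n_free_params == k
            assert fit.evidence == pytest.approx(fit.loglik - 0.5 * k * np.log(n))

    def test_inadmissible_stage_set_rejected(self, grid_mapping):
        recs = [
            TrialRecord("p", b, t, "test", None, (0.0, 0.0), (0.0, 0.0), 0)
            for b in range(1, 15)
            for t in range(10, 12)
        ]
        with pytest.raises(ValueError):
            fit_policy_sequence(recs, grid_mapping, ("bilateral", "random"))

    def test_block_stages_expand_switches(self):
        mapping, _, recs = simulate(["random"] * 4 + ["bilateral"] * 10, seed=8)
        fit = fit_policy_sequence(recs, mapping, ("random", "bilateral"), sigma=10.0)
        stages = fit.block_stages()
        assert len(stages) == 14
        assert stages[: fit.switch_blocks[0] - 1] == ("random",) * (fit.switch_blocks[0] - 1)


class TestRfxBms:
    def test_identical_evidences_give_uniform_frequencies(self):
        r = rfx_bms(np.zeros((12, 2)))
        assert r.expected_frequencies == pytest.approx([0.5, 0.5], abs=1e-6)
        assert r.posterior_probabilities.sum(axis=1) == pytest.approx(np.ones(12))

    @pytest.mark.parametrize("n", [5, 10, 40])
    def test_decisive_margin_matches_dirichlet_closed_form(self, n):
        lme = np.zeros((n, 2))
        lme[:, 0] = 100.0
        r = rfx_bms(lme)
        assert r.expected_frequencies[0] == pytest.approx((n + 1) / (n + 2), abs=1e-6)

    def test_participant_order_is_exchangeable(self, rng):
        lme = rng.normal(size=(20, 3))
        a = rfx_bms(lme)
        perm = rng.permutation(20)
        b = rfx_bms(lme[perm])
        assert a.expected_frequencies == pytest.approx(b.expected_frequencies, abs=1e-9)

    def test_non_finite_evidence_names_offender(self):
        lme = np.zeros((3, 2))
        lme[1, 1] = np.nan
        with pytest.raises(ValueError, match="participant 1"):
            rfx_bms(lme)


class TestUnilateralAttribution:
    def test_attribution_follows_best_model(self):
        mapping, _, recs = simulate(
            ["random"] * 3 + ["unilateral"] * 5 + ["bilateral"] * 6, seed=9
        )
        assert unilateral_attribution(fit_all_models(recs, mapping, sigma=10.0))
        mapping, _, recs = simulate(["random"] * 4 + ["bilateral"] * 10, seed=10)
        assert not unilateral_attribution(fit_all_models(recs, mapping, sigma=10.0))

    def test_ties_break_toward_fewer_parameters(self):
        from factormap.policy_fit import PolicySequenceModel

        a = PolicySequenceModel(("random",), (), None, -10.0, 0, -5.0)
        b = PolicySequenceModel(("random", "unilateral"), (8,), "dim1", -10.0, 2, -5.0)
        assert not unilateral_attribution({a.stages: a, b.stages: b})


class TestMatchedCohort:
    def test_matched_cohort_tracks_block_llr(self):
        cohort = [
            simulate(["random"] * 4 + ["bilateral"] * 10, seed=s) for s in (11, 12)
        ]
        matched = build_matched_cohort(cohort, sigma=10.0, rng_seed=0)
        for (mapping, _, orig), (_, _, match) in zip(cohort, matched):
            lo = llr_from_records(orig, mapping, 10.0).per_block_llr
            lm = llr_from_records(match, mapping, 10.0).per_block_llr
            # same sign of evidence per half, and correlated trajectories
            assert np.corrcoef(lo, lm)[0, 1] > 0.8

    def test_matched_cohort_rarely_attributed_unilateral(self):
        cohort = [
            simulate(["random"] * 4 + ["bilateral"] * 10, seed=s, sigma=20.0)
            for s in range(6)
        ]
        matched = build_matched_cohort(cohort, sigma=20.0, rng_seed=1)
        attr = [unilateral_attribution(fit_all_models(r, m, 20.0)) for m, _, r in matched]
        assert sum(attr) <= 1


class TestCrossvalInflection:
    def _constructed_records(self, switch1, switch2, lo=5.0, hi=120.0):
        # per-dimension error steps down at different trials; noiseless
        records = []
        i = 0
        for b in range(1, 15):
            for t in range(10, 26):
                i += 1
                e1 = lo if i >= switch1 else hi
                e2 = lo if i >= switch2 else hi
                records.append(
                    TrialRecord("p", b, t, "test", None, (0.0, 0.0), (e1, e2), 0)
                )
        return records

    def test_step_difference_recovered(self, grid_mapping):
        recs = self._constructed_records(50, 120)
        res = crossval_inflection(recs, grid_mapping)
        assert res.cv_difference == pytest.approx(70.0, abs=5.0)

    def test_identical_trajectories_give_near_zero_difference(self, grid_mapping):
        recs = self._constructed_records(80, 80)
        res = crossval_inflection(recs, grid_mapping)
        assert abs(res.cv_difference) < 5.0

    def test_flat_error_flags_degenerate(self, grid_mapping):
        recs = self._constructed_records(1, 1)  # both constant low after trial 1
        res = crossval_inflection(recs, grid_mapping)
        assert res.degenerate

    def test_fold_labels_symmetric(self, grid_mapping):
        recs = self._constructed_records(40, 150)
        res = crossval_inflection(recs, grid_mapping)
        assert res.early_dim_per_fold == (0, 0)

    def test_matched_cohort_cv_difference_centered_on_zero(self):
        # random-bilateral control cohorts have no unilateral stage, so the
        # cross-validated late-minus-early midpoint difference has no
        # consistent sign and its median sits near zero
        cohort = [
            simulate(["random"] * 4 + ["bilateral"] * 10, seed=100 + s, sigma=20.0)
            for s in range(8)
        ]
        matched = build_matched_cohort(cohort, sigma=20.0, rng_seed=2)
        diffs = [crossval_inflection(r, m).cv_difference for m, _, r in matched]
        assert abs(float(np.median(diffs))) < 25.0  # trials, out of 224


class TestDeltaLlr:
    def test_constant_series_give_zero_changes(self):
        tr, te = delta_llr([5.0] * 14, [2.0] * 14)
        assert not tr.any() and not te.any()

    def test_linear_series_give_constant_slope(self):
        series = np.arange(14) * 3.0
        tr, _ = delta_llr(series, series)
        assert tr == pytest.approx(np.full(13, 3.0))

    def test_telescoping_sum(self, rng):
        s = rng.normal(size=14)
        tr, _ = delta_llr(s, s)
        assert tr.sum() == pytest.approx(s[-1] - s[0])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            delta_llr([1.0] * 13, [1.0] * 14)
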