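"""Stagewise policy fits, Bayesian model selection, and switch-point analysis.

A participant's test responses are modeled as a sequence of policy
*stages* -- random, unilateral, bilateral -- with transitions allowed
only in ascending order of the number of dimensions learned and only at
block boundaries.  Seven stage sets are admissible: {rnd}, {uni}, {bi},
{rnd,uni}, {rnd,bi}, {uni,bi} and {rnd,uni,bi}.  For a given stage set,
the fit is an exhaustive search over all monotone block-to-stage
assignments (and, where a unilateral stage exists, over which spatial
dimension it has learned); model evidence is approximated by -BIC/2.

Population-level comparisons use random-effects Bayesian model selection
(variational Dirichlet scheme): per-participant log evidences are turned
into posterior model probabilities and expected population frequencies.

Two further diagnostics probe whether a unilateral stage is genuinely
present in behavior: a *matched cohort* whose per-block performance
equals the real cohort's but whose policy is constrained to mixtures of
random and bilateral responding (so any unilateral attribution in it is
a false positive), and a cross-validated comparison of per-dimension
sigmoidal error-curve inflection points (one fold orders the dimensions
early/late, the other measures the difference).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import digamma, logsumexp

from .response_models import (
    DEFAULT_SIGMA_PX,
    DiskDensity,
    LlrSummary,
    llr_from_records,
    wrap_angle,
)
from .synthetic_cohort import sample_density, stage_density
from .task_env import (
    CurriculumSpec,
    MappingSpec,
    N_BLOCKS,
    TrialRecord,
)

__all__ = [
    "ADMISSIBLE_STAGE_SETS",
    "PolicySequenceModel",
    "BmsResult",
    "InflectionResult",
    "fit_policy_sequence",
    "fit_all_models",
    "rfx_bms",
    "unilateral_attribution",
    "build_matched_cohort",
    "crossval_inflection",
    "delta_llr",
]

logger = logging.getLogger(__name__)

Stage = Literal["random", "unilateral", "bilateral"]
STAGE_ORDER: dict[str, int] = {"random": 0, "unilateral": 1, "bilateral": 2}

#: The seven admissible stage sets: four with a unilateral stage, three without.
ADMISSIBLE_STAGE_SETS: tuple[tuple[Stage, ...], ...] = (
    ("random",),
    ("unilateral",),
    ("bilateral",),
    ("random", "unilateral"),
    ("random", "bilateral"),
    ("unilateral", "bilateral"),
    ("random", "unilateral", "bilateral"),
)


@dataclass(frozen=True)
class PolicySequenceModel:
    """A fitted stage schedule with its likelihood and approximate evidence."""

    stages: tuple[Stage, ...]
    switch_blocks: tuple[int, ...]  # first block of each stage after the first
    unilateral_dim: Optional[Literal["dim1", "dim2"]]
    loglik: float
    n_free_params: int
    evidence: float

    @property
    def has_unilateral(self) -> bool:
        return "unilateral" in self.stages

    def block_stages(self) -> tuple[Stage, ...]:
        """Per-block stage assignment implied by the switch blocks."""
        bounds = (1,) + self.switch_blocks + (N_BLOCKS + 1,)
        out: list[Stage] = []
        for stage, lo, hi in zip(self.stages, bounds, bounds[1:]):
            out.extend([stage] * (hi - lo))
        return tuple(out)


def _test_records(records: Iterable[TrialRecord]) -> list[TrialRecord]:
    sel = [r for r in records if r.phase == "test" and r.response is not None]
    if not sel:
        raise ValueError("no responded test trials to fit")
    return sel


def _per_block_stage_logliks(
    records: Sequence[TrialRecord],
    mapping: MappingSpec,
    sigma: float,
) -> dict[tuple[Stage, Optional[str]], np.ndarray]:
    """Log-likelihood of each block's responses under each stage variant."""
    variants: list[tuple[Stage, Optional[str]]] = [
        ("random", None),
        ("unilateral", "dim1"),
        ("unilateral", "dim2"),
        ("bilateral", None),
    ]
    out = {v: np.zeros(N_BLOCKS) for v in variants}
    cache: dict[tuple, DiskDensity] = {}
    for r in records:
        for stage, dim in variants:
            key = (stage, dim, r.truth)
            d = cache.get(key)
            if d is None:
                d = stage_density(stage, mapping, r.truth, sigma, dim or "dim1")
                cache[key] = d
            out[(stage, dim)][r.block - 1] += float(
                d.logpdf(r.response[0], r.response[1])  # type: ignore[index]
            )
    return out


def _assignments(n_stages: int) -> Iterable[tuple[int, ...]]:
    """All non-decreasing stage-transition block tuples in 1..14.

    Equal or leading switch indices let earlier stages occupy zero
    blocks, so larger stage sets nest the smaller ones; the final stage
    always covers at least one block.
    """
    if n_stages == 1:
        yield ()
    else:
        for combo in itertools.combinations_with_replacement(
            range(1, N_BLOCKS + 1), n_stages - 1
        ):
            yield combo


def fit_policy_sequence(
    records: Iterable[TrialRecord],
    mapping: MappingSpec,
    stage_set: Sequence[Stage],
    sigma: float = DEFAULT_SIGMA_PX,
    *,
    _block_logliks: Optional[dict] = None,
) -> PolicySequenceModel:
    """Maximum-likelihood monotone stage assignment for one stage set.

    Evidence is -BIC/2 with the free-parameter count equal to the number
    of switch points plus one if a unilateral dimension is fitted (sigma
    is fixed, not fitted).
    """
    stages = tuple(stage_set)
    if stages not in ADMISSIBLE_STAGE_SETS:
        raise ValueError(f"inadmissible stage set {stages!r}")
    records = _test_records(records)
    n_obs = len(records)
    bl = _block_logliks or _per_block_stage_logliks(records, mapping, sigma)

    dims: list[Optional[str]] = ["dim1", "dim2"] if "unilateral" in stages else [None]
    best: Optional[tuple[float, tuple[int, ...], Optional[str]]] = None
    for dim in dims:
        per_stage = {
            s: bl[(s, dim if s == "unilateral" else None)] for s in stages
        }
        cum = {s: np.concatenate([[0.0], np.cumsum(per_stage[s])]) for s in stages}
        for switches in _assignments(len(stages)):
            bounds = (1,) + switches + (N_BLOCKS + 1,)
            ll = sum(
                cum[s][hi - 1] - cum[s][lo - 1]
                for s, lo, hi in zip(stages, bounds, bounds[1:])
            )
            if best is None or ll > best[0]:
                best = (ll, switches, dim)
    assert best is not None
    ll, switches, dim = best
    k = len(switches) + (1 if "unilateral" in stages else 0)
    return PolicySequenceModel(
        stages=stages,
        switch_blocks=switches,
        unilateral_dim=dim,  # type: ignore[arg-type]
        loglik=float(ll),
        n_free_params=k,
        evidence=float(ll) - 0.5 * k * math.log(n_obs),
    )


def fit_all_models(
    records: Iterable[TrialRecord],
    mapping: MappingSpec,
    sigma: float = DEFAULT_SIGMA_PX,
    stage_sets: Sequence[tuple[Stage, ...]] = ADMISSIBLE_STAGE_SETS,
) -> dict[tuple[Stage, ...], PolicySequenceModel]:
    """Fit every admissible stage set, sharing the per-block likelihoods."""
    records = _test_records(records)
    bl = _per_block_stage_logliks(records, mapping, sigma)
    return {
        ss: fit_policy_sequence(records, mapping, ss, sigma, _block_logliks=bl)
        for ss in stage_sets
    }


# ---------------------------------------------------------------------------
# Random-effects Bayesian model selection
# ---------------------------------------------------------------------------

@dataclass
class BmsResult:
    """Variational Dirichlet estimate of population model frequencies."""

    dirichlet_alpha: np.ndarray  # (K,)
    expected_frequencies: np.ndarray  # (K,), sums to 1
    posterior_probabilities: np.ndarray  # (N, K), rows sum to 1


def rfx_bms(
    evidences: np.ndarray,
    prior_alpha: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BmsResult:
    """Random-effects BMS over a participants x models log-evidence array."""
    lme = np.asarray(evidences, dtype=float)
    if lme.ndim != 2:
        raise ValueError("evidences must be a participants x models array")
    if not np.all(np.isfinite(lme)):
        n, k = np.argwhere(~np.isfinite(lme))[0]
        raise ValueError(f"non-finite evidence for participant {n}, model {k}")
    n, K = lme.shape
    alpha0 = np.full(K, prior_alpha)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        log_u = lme + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    return BmsResult(
        dirichlet_alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        posterior_probabilities=g,
    )


def unilateral_attribution(
    fits: dict[tuple[Stage, ...], PolicySequenceModel]
) -> bool:
    """True iff the best-evidence model includes a unilateral stage.

    Ties are broken toward the model with fewer free parameters, then
    lexicographically by stage names.
    """
    best = min(
        fits.values(),
        key=lambda m: (-m.evidence, m.n_free_params, m.stages),
    )
    return best.has_unilateral


# ---------------------------------------------------------------------------
# Matched random-bilateral cohort
# ---------------------------------------------------------------------------

def _expected_trial_llr(
    density: DiskDensity, bilateral: DiskDensity, random_d: DiskDensity
) -> float:
    """E under ``density`` of the per-trial bilateral-vs-random log ratio."""
    xx, yy, p = density.lattice_pmf()
    lr = bilateral.logpdf(xx, yy) - random_d.logpdf(xx, yy)
    return float(np.sum(p * lr))


def build_matched_cohort(
    cohort: Sequence[tuple[MappingSpec, CurriculumSpec, Sequence[TrialRecord]]],
    sigma: float = DEFAULT_SIGMA_PX,
    rng_seed: int = 0,
) -> list[tuple[MappingSpec, CurriculumSpec, list[TrialRecord]]]:
    """Simulated cohort matched block by block on LLR, constrained to rnd-bi.

    For each participant and block, the mixture weight ``w`` on the
    bilateral component is chosen so that the expected per-block LLR of
    responses drawn from ``w * bilateral + (1 - w) * random`` equals the
    observed block LLR (the expectation is linear in ``w``, so the root
    is closed-form); each test response is then resampled from the
    fitted mixture on the participant's own trial schedule.  Observed
    LLRs above the pure-bilateral expectation clamp ``w`` to 1.
    """
    rng = np.random.default_rng(rng_seed)
    out = []
    exp_cache: dict[tuple, tuple[float, float]] = {}
    for mapping, curriculum, records in cohort:
        summary = llr_from_records(records, mapping, sigma)
        matched: list[TrialRecord] = []
        test_by_block: dict[int, list[TrialRecord]] = {}
        for r in records:
            if r.phase == "test":
                test_by_block.setdefault(r.block, []).append(r)
        for r in records:
            if r.phase == "train":
                matched.append(r)
        rnd_d = stage_density("random", mapping, (0.0, 0.0), sigma)
        for block, trials in test_by_block.items():
            e_bi = e_rnd = 0.0
            for t in trials:
                key = (mapping.kind, mapping.polar_rotation, t.truth, sigma)
                if key not in exp_cache:
                    bi_d = stage_density("bilateral", mapping, t.truth, sigma)
                    exp_cache[key] = (
                        _expected_trial_llr(bi_d, bi_d, rnd_d),
                        _expected_trial_llr(rnd_d, bi_d, rnd_d),
                    )
                eb, er = exp_cache[key]
                e_bi += eb
                e_rnd += er
            target = float(summary.per_block_llr[block - 1])
            if target > e_bi:
                logger.info(
                    "block %d LLR %.1f above pure-bilateral expectation %.1f; w=1",
                    block,
                    target,
                    e_bi,
                )
            w = float(np.clip((target - e_rnd) / (e_bi - e_rnd), 0.0, 1.0))
            for t in trials:
                if rng.uniform() < w:
                    d = stage_density("bilateral", mapping, t.truth, sigma)
                else:
                    d = rnd_d
                (x, y), = sample_density(d, 1, rng)
                matched.append(t.with_response(float(x), float(y)))
        matched.sort(key=lambda r: (r.block, r.trial_in_block))
        out.append((mapping, curriculum, matched))
    return out


# ---------------------------------------------------------------------------
# Cross-validated inflection points
# ---------------------------------------------------------------------------

@dataclass
class InflectionResult:
    """Cross-validated difference in per-dimension sigmoid midpoints."""

    cv_difference: float  # late-minus-early midpoint, in trials
    per_fold_t0: tuple[tuple[float, float], ...]  # (dim1, dim2) per fold
    early_dim_per_fold: tuple[int, ...]  # 0 or 1, labels from the other fold
    degenerate: bool


def _sigmoid(t: np.ndarray, lo: float, hi: float, t0: float, k: float) -> np.ndarray:
    a = np.clip((t - t0) / k, -500.0, 500.0)
    return lo + (hi - lo) / (1.0 + np.exp(a))


def _fit_sigmoid(t: np.ndarray, err: np.ndarray) -> tuple[float, bool]:
    """Best-fitting descending-sigmoid midpoint, multi-start least squares."""
    span = float(t.max() - t.min()) or 1.0
    mid = float(t.min() + span / 2.0)
    scale = float(np.std(err))
    if scale < 1e-9:
        return mid, True
    lo0, hi0 = float(np.percentile(err, 10)), float(np.percentile(err, 90))
    best: Optional[tuple[float, np.ndarray]] = None
    for q in (0.1, 0.3, 0.5, 0.7, 0.9):
        p0 = np.array([lo0, max(hi0, lo0 + scale), t.min() + q * span, span / 10.0])
        try:
            res = least_squares(
                lambda p: _sigmoid(t, *p) - err,
                p0,
                bounds=(
                    [0.0, 0.0, float(t.min()), 1e-2],
                    [np.inf, np.inf, float(t.max()), span],
                ),
            )
        except ValueError:
            continue
        if best is None or res.cost < best[0]:
            best = (res.cost, res.x)
    if best is None:
        return mid, True
    lo, hi, t0, _k = best[1]
    if abs(hi - lo) < 1e-6 * max(1.0, scale):
        return mid, True
    return float(t0), False


def _dimension_errors(
    records: Sequence[TrialRecord], mapping: MappingSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(trial index, dim1 error, dim2 error) over test trials in time order."""
    sel = _test_records(records)
    sel.sort(key=lambda r: (r.block, r.trial_in_block))
    t = np.arange(1, len(sel) + 1, dtype=float)
    e1 = np.empty(len(sel))
    e2 = np.empty(len(sel))
    for i, r in enumerate(sel):
        rx, ry = r.response  # type: ignore[misc]
        tx, ty = r.truth
        if mapping.kind == "grid":
            e1[i] = abs(rx - tx)
            e2[i] = abs(ry - ty)
        else:
            e1[i] = abs(math.hypot(rx, ry) - math.hypot(tx, ty))
            e2[i] = abs(
                float(wrap_angle(math.atan2(ry, rx) - math.atan2(ty, tx)))
            )
    return t, e1, e2


def crossval_inflection(
    records: Iterable[TrialRecord], mapping: MappingSpec
) -> InflectionResult:
    """Cross-validated late-minus-early difference in error inflection points.

    Odd test trials order the two spatial dimensions by their fitted
    sigmoid midpoints; even trials measure the midpoint difference under
    those labels.  The procedure is repeated with the folds swapped and
    the two outcomes averaged.
    """
    t, e1, e2 = _dimension_errors(list(records), mapping)
    folds = (t % 2 == 1, t % 2 == 0)  # odd trials, even trials
    fits = []
    degenerate = False
    for mask in folds:
        t0_1, d1 = _fit_sigmoid(t[mask], e1[mask])
        t0_2, d2 = _fit_sigmoid(t[mask], e2[mask])
        degenerate |= d1 or d2
        fits.append((t0_1, t0_2))
    diffs = []
    early_dims = []
    for label_fold, measure_fold in ((0, 1), (1, 0)):
        early = 0 if fits[label_fold][0] <= fits[label_fold][1] else 1
        late = 1 - early
        diffs.append(fits[measure_fold][late] - fits[measure_fold][early])
        early_dims.append(early)
    return InflectionResult(
        cv_difference=float(np.mean(diffs)),
        per_fold_t0=tuple(fits),
        early_dim_per_fold=tuple(early_dims),
        degenerate=degenerate,
    )


def delta_llr(
    per_block_train: Sequence[float], per_block_test: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Block-to-block change in LLR for the training and test series."""
    tr = np.asarray(per_block_train, dtype=float)
    te = np.asarray(per_block_test, dtype=float)
    if len(tr) != N_BLOCKS or len(te) != N_BLOCKS:
        raise ValueError(f"both series must have {N_BLOCKS} blocks")
    return np.diff(tr), np.diff(te)
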