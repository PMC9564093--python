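# Methods

This note documents the models implemented in `factormap`, the
parameter choices that matter, the synthetic-data assumptions, and the
numerical details a user re-running or extending the analyses should
know.

## Task geometry

The arena is a disk of radius R = 265 px centered at the origin. The
25 cues (5 color × 5 shape levels) map deterministically to arena
points. The exact pixel geometry of the target layout is a package
choice:

- **Grid**: levels sit at offsets {−2,−1,0,1,2} × 90 px on each axis,
  the largest evenly spaced 5×5 lattice whose corners (≈254.6 px from
  center) stay inside the arena.
- **Polar**: ring radii (53, 106, 159, 212, 245) px — innermost nonzero
  so all 25 points are distinct, outermost inset from the wall — and 5
  spokes 72° apart, plus a per-participant uniform rotation of the whole
  layout.

Per participant, the assignment of cue dimension to spatial dimension,
the order of levels along each dimension, the first-queried training
axis, and the polar rotation are all randomized from one
participant-level seed. Curricula are defined in *rule space* (which
spatial row/column or ring/spoke is trained) and mapped back to cues
through these randomizations, so "central row and column" and "the two
diagonals forming an X" refer to what is on screen.

Points per feedback trial use half-open distance bands — 5 in [0, 20),
2 in [20, 40), 1 in [40, 60), else 0 — making the scoring total and
non-overlapping at the band edges. The accuracy predicate used for
exclusion is distance < 60 px.

## Response densities and the LLR

All response models are proper densities on the disk, normalized
numerically on a shared 2 px square lattice clipped to the disk. A
single normalization scheme handles boundary truncation and the polar
parameterization uniformly, and gives all models identical support, so
likelihood ratios are fair. Lattice sums reproduce the closed-form
Gaussian normalization to better than 0.1 % when the truth is ≥ 4σ from
the wall, and every density integrates to 1 ± 1e−6 on the lattice.

- **random**: uniform, log-density ≈ −ln(πR²) = −12.304 per response.
- **bilateral**: grid — isotropic Cartesian Gaussian (default
  σ = 20 px, the full-reward radius) centered on the truth; polar — the
  product of a radial Gaussian (σ px) and a wrapped angular Gaussian
  whose width is the arc-equivalent σ/ρ_truth capped at 0.3 rad. The
  polar kernel is defined directly in (ρ, φ) product form on the
  Cartesian lattice, without a Jacobian factor, and renormalized.
- **unilateral**: a ridge correct on one dimension only — Gaussian in x
  (or y) and uniform in the other for grid; Gaussian in ρ with uniform
  angle (a ring) or wrapped Gaussian in φ with uniform radius (a spoke)
  for polar.

Angular residuals are wrapped to (−π, π]. σ is fixed and shared across
models and trials by default (it can be varied per call); fitting σ per
participant is deliberately not part of the default pipeline.

The LLR of a response set is the sum over responses of
log p_bilateral − log p_random. Per-block LLRs sum the trials of the
block; a **generalizer** has mean per-block test LLR > 0 over blocks
8–14. Responses outside the disk (possible only in ingested real data)
are clamped to the boundary with a logged warning.

## Agents

Both agents read a two-hot cue encoding x ∈ {0,1}¹⁰ through a 4×10
weight matrix onto four effectors composed as
p = R(φ)·(trans_x + ρ, trans_y). Network activations are unit-free and
scaled to physical units by a fixed diagonal (R, R, R, 1): translations
and expansion in units of the arena radius, rotation in radians. This
keeps all weights O(1) so a single SGD rate serves all effectors. The
training loss is the squared screen-position error in arena-radius
units; gradients are exact through the rotation.

Shared defaults (one set for every condition and both agents):

| parameter | value | role |
|---|---|---|
| sgd_rate | 0.06 | SGD step on the normalized loss |
| steps_per_trial | 3 | gradient steps per feedback trial |
| w_init_sd | (0.35, 0.35, 0.35, 0.2) | per-effector init SD |
| output scale | (265, 265, 265, 1) | activation → px / rad |
| τ | 0.40 | gating threshold |
| α_U | 0.2 | Hebbian rate |
| λ | 0.5 | recency discount over block history |
| U init | 0.39 | starting Hebbian weight (fully gated) |
| ε_Δz | 1e−6 | output-change tolerance (float guard) |

The **Hebbian update** compares the current feedback trial against each
earlier feedback trial of the same block: Δx is the elementwise input
change, Δz the per-effector indicator of output change, where the
output signal is the feedback location expressed in all four effector
coordinates (so surprise is computable from veridical signals alone;
the angle of the exact center is defined as 0). The per-pair update is
excitation (Δz ⊗ Δx)·(1−U) minus preactivated depression
(1 ⊗ Δx)·U, oriented output×input to match the 4×10 weight shape;
pairs combine with normalized weights λ^(t−i)/Σλ^(t−j) and scale α_U.
Each per-pair term lies in [−U, 1−U] and the weights form a convex
combination, so U stays in [0, 1] without clipping. A connection whose
output changes on a fraction q of its input changes has fixed point
U* = q/(1+q): consistent co-change (q = 1) settles at 0.5, above τ;
intermittent co-change (q ≈ 2/3, e.g. the expansion/rotation channels
along a central training axis) settles near 0.40, at the threshold; and
rarer coincidence decays shut. Starting U at 0.39 — still below τ, so
the network begins fully gated — means a few consistent co-change
events open a gate within the first block, while the fixed-point
structure still decides which gates *stay* open. Gradients flow only
through open gates; U persists across blocks while the comparison
history resets at block boundaries.

Why the phenomena emerge:

- **Vanilla networks train but do not compose.** The effector basis is
  redundant, and the rotation output is deliberately slow (scale 1
  versus 265): each network keeps idiosyncratic random per-cue rotation
  offsets from its init. Training can fit the 9 trained cues exactly
  *through* those offsets (translations absorb them linearly), but at
  test the rotation of a summed translation by a summed angle is not
  additive, so composed responses land far from the truth.
- **Hebbian networks under aligned blocked curricula** open exactly the
  color→one-translation, shape→other-translation gates (the rotation
  and expansion channels co-change only intermittently along a central
  axis and stay shut), zeroing the rotation noise and yielding a clean
  factorized solution — at the package defaults the end-of-run open-gate
  set matches the ground-truth factorization in essentially all seeds.
- **Misaligned curricula** change both cue features and several
  effectors on every comparison, opening cross-dimension (and rotation)
  gates, which exposes the init noise and destroys composition.
- **Interleaved curricula** mix the axes in time, so cross-dimension
  channels see co-change on roughly half their comparisons and flicker
  around threshold, intermittently exposing untrained weights that
  blocked curricula keep gated.

Curriculum-ordering comparisons (aligned vs misaligned, blocked vs
interleaved) are evaluated on summed test LLR over blocks 8–14 — the
same window that defines generalizers — because the orderings are
properties of the settled gate configuration; early blocks mostly
reflect shared gate-opening transients. Cohorts in compared conditions
share per-agent seed streams, so the comparisons are paired.

## Policy-sequence fitting

Test responses are fit by stage sequences over {random, unilateral,
bilateral} with transitions in ascending order only and only at block
boundaries (16 test trials per block cannot identify within-block
switches). The seven admissible stage sets are the three without a
unilateral stage and the four with one. The fit is an exhaustive search
over non-decreasing switch indices in 1..14 (equal or leading indices
let earlier stages occupy zero blocks, so larger sets nest smaller
ones) and, where applicable, over the unilateral dimension. Evidence is
−BIC/2 with free parameters = number of switch indices + 1 if a
unilateral dimension is fit; σ is fixed, not fitted. Ties in evidence
break toward fewer parameters, then lexicographically.

**RFX-BMS** follows the standard variational Dirichlet scheme: uniform
prior concentration 1, iterate responsibilities ∝ exp(log evidence +
digamma terms) and concentration updates to a 1e−6 tolerance. Under a
decisive margin for one model in all N participants the expected
frequency is (N+1)/(N+2), the Dirichlet posterior mean.

**Matched cohorts**: for each participant and block, the expected
per-block LLR of a w·bilateral + (1−w)·random mixture is linear in w,
so the w matching the observed block LLR is closed-form (clamped to
[0, 1]; observations above the pure-bilateral expectation clamp to 1
with a log note); responses are then resampled from the mixture on the
participant's own trial schedule. Any unilateral attribution in such a
cohort is by construction a false positive.

**Inflection points**: per-dimension error magnitudes (|Δx|, |Δy| for
grid; |Δρ| and wrapped |Δφ| for polar) over the 224 test trials are fit
with a descending 4-parameter sigmoid by multi-start least squares (5
starts over the midpoint range, k > 0 enforced, bounds on all
parameters). Odd trials order the dimensions early/late, even trials
measure the midpoint difference under those labels; folds are then
swapped and the outcomes averaged. Flat error trajectories set the
midpoint to the center of the trial range and raise a degeneracy flag.

## Synthetic cohorts

Synthetic participants exist so every pipeline stage is testable with
known ground truth. Each follows a monotone per-block stage schedule
and samples test responses from the corresponding disk density by exact
rejection sampling (polar kernels are proposed in (ρ, φ) and accepted
with probability ρ/R, cancelling the Jacobian). Training responses
follow a logistic accuracy ramp — asymptote 0.97, midpoint block 1.5,
rate 0.5, i.e. mostly random in block 1 and on-target
(bilateral-with-noise) from block 2 — which exists only to make
training accuracies realistic for the exclusion rule. One master seed
spawns independent per-participant streams; a manifest records every
generative parameter for recovery scoring.

What the generator does *not* emulate: reaction times, motor noise
beyond isotropic Gaussian scatter, within-block learning inside a
stage, lapses at test, or any cue-specific difficulty. Passing
recovery tests therefore shows the pipeline recovers the generative
families it assumes, not that human data satisfy those assumptions.

## Cohort statistics

Generalizer-count comparisons use the uncorrected Pearson 2×2
chi-square (df = 1): the uncorrected statistic reproduces the reference
values exactly, the Yates-corrected one does not. Bootstrap tests on
cohort mean LLR differences are one-sided with 10,000 resamples by
default, seeded. Exclusion of low training performers is per condition
at 3 scaled MADs (b = 1.4826) below the median of second-half training
accuracy; it is one-sided, and a zero MAD (common when accuracies
saturate) falls back to excluding only participants below both the
median and an absolute 0.5 floor, with a loud log message — the rule is
otherwise undefined in that regime.

## Known limitations

- Agent LLR *magnitudes* are not calibrated to any reference cohort;
  only the qualitative pattern (training success, composition failure,
  curriculum orderings, gate convergence) is a supported claim.
- The Hebbian polar conditions open translation gates alongside the
  correct ring/spoke channels (translations genuinely co-vary with
  everything on a curved layout), so polar Hebbian agents generalize
  poorly in absolute terms; the curriculum orderings still hold.
- The blocked-vs-interleaved effect is small relative to seed noise;
  comparisons should use ≥ 50 paired seeds.
- Stage switches are restricted to block boundaries, and model evidence
  uses the BIC approximation throughout.
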