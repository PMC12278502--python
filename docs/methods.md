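# Methods

## The optimization problem

`glycobo` optimizes glycosylation reaction conditions for two objectives at
once — isolated yield (%) and anomeric selectivity (%) — treating the
reaction as a black box. The search domain is a ten-parameter mixed space:
donor anomeric configuration (α/β), lithium salt identity (7 salts) and
loading (0.5–5 eq), acid catalyst (none/acetic/formic/oxalic/TFA),
acceptor equivalents (0.8–3), concentration (0.03–0.31 M), Et₂O and MeCN
fractions of a ternary Et₂O/MeCN/DCM solvent system, molecular sieves
(none/3 Å/4 Å/5 Å) and temperature (0 or 25 °C). The two solvent fractions
obey `part_et2o + part_mecn ≤ 1`; the DCM balance is an eleventh, derived
parameter. The continuous bounds are not dictated by chemistry; they
envelope the validation campaign data with small margins and are the
package's own choice.

Categorical reagents are encoded as integers so a single numeric vector can
feed a Gaussian process: acids ascend in acidity (pKa 4.76 → 0.23, with
"none" reserved at 0), sieves ascend in pore size, the donor configuration
is α=0/β=1, and salts carry ranks 1–7 from a principal-component analysis
of anion descriptors (below). Continuous axes are min–max scaled to [0, 1].
Everything downstream treats ordinal axes as continuous; partial-dependence
curves over them are therefore smooth interpolations whose between-level
values carry no physical meaning.

## Salt encoding

`pca_rank_encode` standardizes a reagent-descriptor table to zero mean and
unit variance per column (making the ranks invariant to descriptor units),
takes PC1 scores from an SVD, orients the component so the anchor reagent
(LiI) ranks first, and returns the rank order 1..n. Ties on PC1 are an
error — the caller must add a discriminating descriptor — because a
deterministic bijection onto {1..n} is part of the contract.

The bundled table (`data/salt_descriptors_synthetic.csv`) is a **synthetic
reconstruction**: the descriptor set actually used for the published
ranking is not available. Its three columns (anion size, charge
delocalization, coordinating ability scores) are plausibility-ordered
proxies chosen so the PC1 ranking reproduces the four anchors the campaign
analysis fixes — LiI=1, LiBF₄=2, LiNTf₂=5, LiPF₆=6 — and places LiClO₄,
LiOTf, LiB(C₆F₅)₄ at 3, 4, 7 on the usual weakly-coordinating-anion scale.
Ranks 3, 4 and 7 should not be read as ground truth.

## Objectives and surrogates

The optimizer minimizes, so percentage objectives become losses by
`loss = 100 − value`; values above 100 (NMR integration error) are kept,
giving small negative losses. Each objective pair gets two independent
Gaussian-process surrogates over the encoded space: anisotropic Matérn 5/2
times a constant, plus a fitted white-noise term, `normalize_y`, and
marginal-likelihood hyperparameter optimization with a fixed restart count
and seed (refits on identical data are bit-reproducible). Length scales
are bounded to [0.05, 3] on the unit-scaled axes: beyond ~3 a Matérn axis
is indistinguishable from flat, and an unbounded fit tends to prune
weakly-informative axes (e.g. the ether fraction, whose effect is
partially aliased by the solvent constraint) out of the model entirely,
which would make parameter-trend analysis vacuous. A single homoscedastic
noise level is fitted; the campaign data contain no replicates that would
support more.

**Selectivity accounting.** The anomer ratio is a fraction of *product*.
For the β-objective the value is the printed β%; for the α-objective it is
`100 − β%` when the reaction produced anything, and 0 when the yield is 0 —
a failed reaction has no α-anomer either. (The alternative, α = 100 − 0 =
100 for failed reactions, would score complete failures as perfectly
α-selective; it inverts the salt trend in the α-selectivity analysis
because the essentially unreactive LiB(C₆F₅)₄ experiments all print a
ratio of 0.) Both readings give identical hypervolume analytics, since a
zero-yield point has zero area either way.

## Acquisition

The campaign loop is ask/tell with human deviation tolerated: `tell`
records whatever conditions were actually run, which need not match the
proposals. The first batch is 10 uniform random conditions (the solvent
pair by rejection sampling on the unit square, exactly uniform on the
constraint triangle, ~50% acceptance). Later batches hold 5 proposals;
each is independently flagged exploration with probability 0.25 (a
Bernoulli draw per experiment, so one batch can mix modes):

* **Exploitation** draws a 2000-candidate random pool, predicts both
  objective means, keeps the predicted non-dominated subset, and returns
  the member with the largest predicted gain in total hypervolume over the
  *observed* front, ties broken by the campaign RNG.
* **Exploration** returns the pool candidate minimizing the repulsive
  energy `E(x) = Σᵢ −log‖x − xᵢ‖` against all observed (and already
  proposed) points in the unit-scaled encoded cube. The −log kernel
  maximizes the product of distances to existing points; it is one
  admissible space-filling choice, is configurable, and is deliberately a
  pool argmin rather than a gradient method (the space is mostly discrete).

A dual campaign runs yield/β and yield/α optimizers side by side: each
batch takes 2 proposals from the β-optimizer and 3 from the α-optimizer,
both purely exploitative, and all 5 results are broadcast to both states.
The optimizers keep independent surrogates but identical observation sets.

## Hypervolume analytics

Both objectives live on the 100×100 percentage square with reference point
(0, 0): 100% hypervolume ⇔ 100% yield at 100% selectivity. A single
experiment's "contribution" is the plain rectangle area
`yield × selectivity / 100` — this is the quantity the campaign tables
print (verified numerically across all 75 rows), *not* the exclusive
marginal contribution, which is available separately as
`exclusive_contribution`. The total hypervolume of a set is the exact
union area by a descending sweep over yield; it is monotone under set
inclusion and equals the hypervolume of its Pareto front. Yields above
100 are used as-is. Integer comparisons against printed tables use
nearest-integer rounding, ties away from zero.

Recomputing the printed contribution columns from the printed yields and
ratios reproduces 64 of 75 integers exactly and 73 of 75 within ±1. The
±1 cases are the authors rounding from unrounded raw data; the two larger
deviations are a printing error in the dual campaign's α column, which
repeats the previous row's value at experiment 72 and lags one row behind
at 73 before re-synchronizing at 74.

## Partial dependence

`partial_dependence` averages the surrogate's prediction over a background
sample while one parameter sweeps its range, then back-transforms to the
percentage scale. The background defaults to the model's training
conditions — trends are inferred from the campaign's own data, not from a
uniform re-weighting of the space. Continuous parameters use a 25-point
grid; discrete parameters are evaluated at their registered levels only.
PDP is linear in the model and, averaged over the training background,
stays within the observed range up to posterior uncertainty. On the
75-experiment validation campaign the α-selectivity curve over the salt
axis is maximal at LiI (rank 1) and falls near-linearly with the PCA
integer, and the ether-fraction curve rises — the qualitative checks are
rank-level (Spearman), since the published curves carry no numbers.

## The virtual lab

Closed-loop behavior cannot be validated against the wet-lab campaign (it
is not replayable), so `virtual_lab` provides a synthetic response surface
encoding the qualitative structure the campaigns uncovered: LiI always
α-selective (β < 25%), LiBF₄/LiNTf₂ always β-selective (β > 55%), LiPF₆
flipping with sieves and solvent (β-selective with sieves present or MeCN
fraction > 0.35; α-selective without sieves in ether-rich solvent),
LiB(C₆F₅)₄ essentially unreactive, yield increasing with acid strength and
capped at ~60% without acid, plus small acceptor/concentration/sieve/
temperature terms. Latent additive trends are logistic-squashed into valid
ranges; observation noise is additive Gaussian with σ = 5% on both
objectives (chosen to reflect single-measurement NMR outcomes where
yields occasionally exceed 100%), with β clipped to [0, 100] and yield to
[0, 110]. The surface is smooth and low-interaction by construction; real
glycosylation outcomes are noisier, more rugged, and substrate-dependent,
so closed-loop wins here demonstrate that the machinery works, not that
the method will win on any particular chemistry.

`benchmark_optimizer` pairs the full loop against uniform random sampling
at the same budget and batch structure (default 55 experiments = 10 random
+ 9×5, 20 replicate seeds). Under these defaults the loop's median final
total hypervolume exceeds random sampling's (typically by ~3 percentage
points, winning ~18/20 replicates), and every convergence series is
monotone by construction.

## Numerical choices and degenerate inputs

* Constraint tolerance 1e-9; encode/decode round-trips are exact for
  labels and ≤1e-9 (measured ~4e-16) for continuous values.
* Fewer than 2 observations cannot fit a GP; the error instructs to use
  random sampling. Duplicate observations are legal (the noise term
  absorbs them); duplicate `tell`s are recorded twice by design.
* Weak dominance deduplicates coincident Pareto points, keeping the
  first seen.
* Empty point sets have hypervolume 0 by convention.
* Exploitation with constant surrogates degenerates gracefully: the whole
  pool is non-dominated and the tie-break picks randomly.
* All randomness flows through explicit `numpy` Generators; identical
  state + seed reproduces identical batches bit-for-bit.

## Known limitations

* Reaction time is not a variable (the lab practice of running longer for
  full conversion is invisible to the optimizer), and there is no unit
  conversion, cost-awareness, or asynchronous asking.
* Ordinal parameters ride a continuous kernel; a categorical (e.g.
  Hamming) kernel might fit the salt axis better but would forfeit the
  integer-trend reading of the partial-dependence analysis.
* The bundled descriptor table is a reconstruction anchored at four salts;
  analyses that depend on the ranks of LiClO₄/LiOTf/LiB(C₆F₅)₄ inherit
  that uncertainty.
* The 2-D sweep does not generalize to ≥3 objectives.
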