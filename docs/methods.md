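# Methods

## Problem setting

A qualitative AP-MS dataset is a list of purifications, each a bait protein
plus the duplicate-free set of preys it retrieved (the bait itself is never
counted among its preys — its presence is structural, not evidence). The
target is the network of *direct* physical contacts. Two noise processes
stand between the data and that target: non-specific contaminants that
co-purify with many unrelated baits, and indirect co-complex partners that
are genuinely associated with the bait but touch it only through
intermediates. The package separates the two concerns: phase I scores
association strength from co-occurrence, phase II removes the
path-mediated (indirect) part of the association matrix.

## Sufficient statistics

All four scores are functions of one pass over the data (`scoring.compute_counts`):

| symbol | meaning |
|---|---|
| `N` | number of purifications |
| `b_i` | purifications where i is bait |
| `occ_i` | purifications containing i in any role |
| `r_i` | purifications containing i as a prey |
| `s_ij` | purifications with bait i retrieving prey j (directed) |
| `m_ij` | purifications with both i and j as preys (bait is neither) |
| `k_ij` | purifications containing both i and j in any role |
| `T` | total prey slots, `Σ_k size_k` |

The candidate universe is every pair with `k_ij ≥ 1` (matrix model: both
bait–prey and prey–prey co-occurrence create candidates). All scores are
symmetric in the unordered pair; ranking is by descending score with
lexicographic tie-break, so ranks are deterministic everywhere.

## Scores

**Socioaffinity (SA).** Observed over expected co-retrieval under a
random-assortment null in which prey slots are filled proportionally to
each protein's prey frequency `f_j = r_j/T`:
`E[s_ij] = f_j · Σ_{k: bait=i} size_k` for the spoke terms and
`E[m_ij] = f_i f_j · Σ_k size_k(size_k−1)` for the matrix term. A term
whose observed count is zero contributes zero rather than −∞: SA measures
positive co-retrieval evidence, and treating absence as infinitely
negative would let a single empty cell dominate the sum. (PE, below, is
the score with a principled absence term.)

**Purification enrichment (PE).** For each purification with bait i, the
partner j contributes `ln(r/f̃_j)` if present and `ln((1−r)/(1−f̃_j))` if
absent, where `r` is the assumed retrieval probability of a true
interactor (default 0.5) and `f̃_j = (r_j + pseudo/|proteins|)/(T + pseudo)`
is the pseudocount-smoothed background frequency (default pseudocount 20).
Prey–prey evidence adds `m_ij · ln(r/(f̃_i f̃_j S̄))` with `S̄` the mean
number of ordered prey pairs per purification. Defaults are explicit,
documented choices — the upstream tools' exact internal defaults are not
recoverable, so correctness here is defined by these formulas and their
oracles, not bit-compatibility with any legacy implementation.

**Dice coefficient (DC).** `2 k_ij/(occ_i + occ_j)` over purification
membership; in (0, 1].

**Hart.** `−log10 P(X ≥ k_ij)` with `X ~ Hypergeometric(N, occ_i, occ_j)`
(scipy's survival function; p-values clamped at 1e-300 before the log).
The tail is symmetric under swapping the two proteins' roles.

## Refinement operators

The scored network is embedded as a dense symmetric matrix over the
lexicographically sorted protein universe, off-diagonal entries min–max
scaled into [0, 1] (absent pairs 0; if all scores are equal, present edges
map to 1).

**Network deconvolution.** Model: the observed matrix is the sum of all
walk contributions of the direct matrix, `G = S + S² + … = S(I−S)⁻¹`,
inverted in closed form by the shared-eigenvector map `λ → λ/(1+λ)`.
Before the map, eigenvalues are shrunk by
`m = max(λ⁺(1−β)/β, |λ⁻|(1+β)/β, 1)` so the output spectrum lies in
`[−β, β]` (default β = 0.99, matching the published tool's default; a
`force_no_scaling` flag gives the exact series inverse for matrices whose
direct spectrum is already inside (−1, 1) — this is the path the
closed-form recovery tests exercise). An `alpha < 1` option keeps only the
top fraction of off-diagonal magnitudes first (default 1: keep all). The
output is re-symmetrized and its diagonal zeroed.

**Silencing.** `S = (G − I + D((G−I)G))·G⁻¹` with `D(·)` the diagonal
extractor, applied to a unit-diagonal G; output symmetrized, diagonal
zeroed, and off-diagonal *magnitudes* used as scores (the transform's sign
is not interpretable as interaction strength). If G is numerically
singular, `G + ε I` is inverted instead (default ε = 1e-8·trace/n).

**Spectral conditioning for the silencer (pipeline step).** The silencing
closed form is derived for correlation matrices — the identity plus a
perturbation — and inverts G. A min–max embedded score network offers no
positive-definiteness guarantee; on realistic data G is indefinite
(smallest eigenvalue ≈ −1.3 on the reference simulation) and G⁻¹ is
dominated by the noise subspace, which empirically floods the top of the
refined ranking with contaminant pairs. The pipeline therefore rescales
the off-diagonal block `A = G − I` to spectral radius 0.5 whenever it
exceeds that bound (`refine.condition_correlation`), which keeps G
positive definite with condition number ≤ 3 while preserving A's ranking
information (a positive scalar rescale). The `silence()` operator itself
is left untouched — its algebraic identities (identity input → zero
output; 2-node fixed point) hold exactly as stated — and deconvolution
needs no analogous step because its eigenvalue shrinkage plays that role.
The radius 0.5 is a conditioning margin, not a tuned constant; 0.9 (bare
positive definiteness) behaves similarly but leaves G ill-conditioned.

By default the refined matrix is re-ranked over exactly the initial
network's candidate pairs, so initial and filtered rankings are compared
on the same universe.

## Evaluation

The hit curve walks the canonical ranking and counts cumulative reference
hits at each depth 1..x_max (default 10,000, the conventional reporting
depth for genome-scale AP-MS networks; deeper than the network is
truncated with a log message). The normalized AUC is the trapezoidal area
under the curve anchored at (0,0), divided by `x_max · y_max`, with 0
returned for an all-miss curve; each curve is normalized by its own
`y_max`. Identities used as test anchors: the all-hit diagonal curve
scores exactly 0.5, and the value never leaves [0, 1]. Top-k overlap
between methods is reported as exact Venn cells over every subset of the
compared networks.

## Simulator

`simulate` builds a stated world: `n_complexes` protein complexes (default
10) with sizes uniform on 3–6, each wired by a uniform random-attachment
spanning tree plus each remaining pair independently with probability 0.3
— so every complex is connected, and its non-adjacent member pairs are the
ground-truth *indirect* pairs. A pool of 50 contaminant proteins carries
Zipf(s = 1) stickiness weights, echoing the empirical pattern that a few
proteins recur across a large fraction of purifications. Each of the 300
purifications picks a bait uniformly among complex members and retrieves
each direct neighbor with `p_direct = 0.8`, each indirect co-complex
partner with `p_indirect = 0.4`, and `Poisson(2)` Zipf-weighted
contaminant picks. One seeded generator drives the whole run, so datasets
are bit-reproducible.

What the simulator does **not** emulate: protein abundance and
spectral counts, bait-specific tagging efficiency, correlated contaminant
co-occurrence beyond frequency, complex overlap/moonlighting, and the
marginal statistics of any particular published dataset. A green test on
simulator output therefore establishes mechanism-level behavior (e.g.
indirect-pair demotion), not performance on real purification data.

## Known limitations: refinement under heavy contaminant noise

With contaminants switched off (`contaminant_rate = 0`), every one of the
eight scorer × refiner combinations improves both the mean rank and the
top-|direct| precision of true direct edges over ten seeds — the
indirect-removal mechanism does exactly its job, and the suite asserts
this. At the reference configuration (rate 2.0, pool 50) the picture is
mixed: PE and Hart initial networks still improve on average under both
operators, but SA+ND and DC under both operators lose a few direct edges
from the top ranks. The dense block of moderate min–max weights that a
compressed score scale (DC's (0,1]; SA's long negative tail mapped
mid-scale) assigns to contaminant pairs acts as a strong noise subspace
that the spectral operators partially mix into the signal. This mirrors
published experience with these operators on real purification data,
where the deconvolution step helps most scorers but shows no-improvement
cases precisely for socioaffinity-ranked networks. The strict acceptance
benchmark encoding "all eight combinations improve and no seed loses more
than 0.02 precision" is additionally finer than the measurement
granularity at this scale (one direct edge ≈ 1/44 ≈ 0.023 precision) and
is left red by design rather than weakened.

## Numerical choices

- Scores are exact floating-point expressions of integer counts; no
  sampling anywhere in scoring.
- Eigendecomposition uses the symmetric path (`numpy.linalg.eigh`);
  refined matrices are re-symmetrized as `(S + Sᵀ)/2` to absorb drift.
- Degenerate inputs: a dataset with no preys at all is a scoring error for
  SA (its null is undefined at T = 0); PE clips smoothed frequencies into
  `[1e-300, 1 − 1e-12]` so both log terms stay finite; Hart clamps
  underflowing p-values at 1e-300.
- Ties in ranking are broken lexicographically by (min-id, max-id); the
  min–max embedding maps an all-equal network to weight 1.
- Serialization uses `repr(float)` round-trip precision; reports are
  sorted-key JSON without timestamps, so identical configurations produce
  byte-identical artifacts.
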