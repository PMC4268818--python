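# Methods

## Model

States are the elements of a finite abelian group
`G = Z_{r_1} × ... × Z_{r_q}` of order `d = Π r_k`, enumerated as residue
tuples in lexicographic order with the identity `(0,...,0)` first.  This
enumeration is the package-wide convention: it fixes every matrix
row/column order, makes the character table literally the Kronecker
product of the cyclic-factor Fourier matrices, and matches the standard
listing of `Z₂×Z₂` used for the K3ST model.  A substitution channel is a
non-identity element `σ`, with rate `α^σ ≥ 0`; the generator
`Q = −λ·1 + Σ α^σ K_σ` is doubly stochastic, so the stationary
distribution is uniform and is the only root distribution used anywhere
(non-uniform roots are out of scope).

Edge "lengths" are dimensionless: the time parameter is absorbed into
the per-edge rates, so a `RateSpec` carries one nonnegative number per
edge subset per channel and no separate branch-length field.  Branch
lengths present in Newick input are ignored with a warning.

Trees are rooted at taxon `n` and edges labelled by the subset of leaves
in `{1..n−1}` separated from taxon `n` by the edge.  The pendant edge at
taxon `n` carries the subset `{1..n−1}` and is treated as an ordinary
edge: under a uniform stationary root its rate is identifiable, and the
subset indexing accommodates it naturally.  Multifurcating trees are
accepted (the subset construction is topology-agnostic), and arbitrary
subset lists — split systems that fit no tree — are accepted behind an
explicit `network=True` flag; tree-compatibility (laminarity) is the
default requirement because it is the common case and catches typos.

## Evaluation of the pattern tensor

The tensor is evaluated in the character basis, where every edge
generator is diagonal with entries `χ(Σ_{j∈e} μ_j, σ)`: one elementwise
exponential over the `d^n` grid per model, at
`O(|edges|·(d−1)·d^n)` cost, followed by one inverse axiswise
transform.  Transforms are applied axis by axis (`n` multiplications by
a `d×d` matrix), never by materializing the `d^n × d^n` Kronecker
matrix.  A single code path covers all radices; for `d = 2` the axiswise
multiply *is* the fast Walsh–Hadamard transform up to constant factors,
so no separate butterfly implementation is kept — at the orders this
package targets (`d ≤ ~12`, `n ≤ ~10`) the dense-per-axis constant is
irrelevant and one path is easier to trust.

Two independent oracles guard this evaluation: classical post-order
pruning with `expm(Q_e)` per edge (`oracle_tree_tensor`, tree-only,
never touches the spectral machinery), and the dense exponential of the
full `d^n × d^n` generator (kept to tensors of a few thousand entries,
used in tests).

## The inversion and its numerical choices

The forward map factors as: character transform → support collapse →
exponential-with-`e^{−λ}` scaling; the inverse composes the reverse
steps.  Numerical decisions, in pipeline order:

- **Support check** (`collapse`): entries off the support (symbol sums
  ≠ identity) are provably zero for a valid model tensor; by default any
  such entry above `1e−8` in magnitude raises a model-violation error.
  Empirical frequency tensors carry multinomial noise of order
  `1/√N` on those components, so inversion of count data passes
  `vanish_tol=None`, which silently drops them — exactly the projection
  the classical method performs implicitly by indexing observed spectra
  by splits.
- **Logarithm** (`log_step`): principal branch, elementwise.  Components
  with magnitude ≤ `1e−12` raise a saturation error (rates too large or
  degenerate data); components within 2% of the negative real axis
  trigger a branch-ambiguity warning — for large rates some `η_u` can
  leave the principal strip (`|Im| ≥ π`) and the inversion is then
  genuinely not injective, so the package detects and warns rather than
  attempting branch correction.
- **Linear step** (`recover`): by default matrix-free — one inverse
  axiswise transform of `θ` over the `(d,)^{n−1}` grid, then a gather at
  the index strings with symbol `σ` on the positions of `e` (the
  `e^c : ∅ : ... : e : ... : ∅` rows); a dense path multiplies by
  explicit `G_σ` matrices (`conj(F_σ)ᵀ/d^{n−1}`) and exists because it
  mirrors the rectangular-matrix formulation and is directly testable
  against it.  Dense `F/G` construction refuses above a `10⁸`-entry
  memory guard and points at the matrix-free path.
- **λ recovery**: λ is *not* an input on the inverse direction.
  `(G_σ θ)_∅ = −λ` for every channel because the empty row of `G_σ`
  annihilates all nonempty-subset columns, so the unknown shift in
  `η = θ + λ` drops out of every rate coordinate and lands in the empty
  one.  Channel estimates are compared (tolerance `1e−6`) and averaged.
- **Reality**: real pattern data gives transforms with conjugate-pair
  symmetry, so recovered rates are real up to rounding; imaginary parts
  below `1e−9` (relative to the spectrum's scale) are discarded, larger
  ones raise — they indicate log-branch failure or corrupted input.
  Negative recovered rates on empirical input are *flagged*, never
  rejected or clipped: they are the expected signature of data that is
  not exactly tree/model consistent.

Row/column conventions: spectral vectors are stored on the
`(d,)^{n−1}` grid whose C-order flattening is the lexicographic order of
state strings (leaf 1 most significant); subsets are ordered by binary
value with bit `i−1` for leaf `i`, empty set first.  Ground sets are
1-based.

One presentational point: some classical write-ups insert a factor ½
into the binary `η_u` and a `1/2^{n−1}` into `(h^{(n−1)})²`; direct
computation gives `h² = 2·1`, and the factorless `η = Fα` is the form
consistent with round-trip inversion, so that is what is implemented
(validated against the pruning oracle and the classical
`γ̂ = H⁻¹ln(Hŝ)` formula evaluated from first principles).  Likewise the
normalized inverse character table `(1/d)·conj(f)ᵀ` is used throughout;
tables sometimes print the unnormalized matrix.

## Synthetic data

`make_fixture` draws a uniform-random binary topology by sequential
attachment (each new leaf subdivides a uniformly chosen edge) and
independent rates uniform on `(0, max_rate]` per edge per channel, with
`max_rate = 0.2` by default — a moderate per-channel substitution load
that keeps every spectral component well away from zero across the
group menu (up to `d = 6`, `n = 6`) while still spanning two orders of
magnitude of rate sizes.  `simulate_patterns` is a single seeded
multinomial draw with the tensor entries as cell probabilities.

What this emulates — and does not: simulated data is exactly i.i.d.,
exactly stationary, homogeneous across sites and exactly group-based.
Passing tests therefore certify the *algebra* (the conjugation is the
identity on model data, and its statistical behaviour under pure
multinomial noise matches the delta method); they say nothing about
rate heterogeneity, non-stationarity, alignment error, or model
misspecification in real alignments, where recovered spectra routinely
contain negative components and should be read as exploratory
quantities, not branch lengths.

## Standard errors

For inverted empirical spectra, `recovery_standard_errors` propagates
multinomial noise to first order: each rate is a smooth function of the
pattern frequencies with gradient `w`, computed by chaining the linear
recovery row through `diag(1/𝒫)` and the character transform
(matrix-free), giving `Var ≈ (Σ p w² − (Σ p w)²)/N`.  At 10⁶ sites on a
four-taxon K3ST model the empirical coverage of ±3 SE intervals is
≈99% — the delta method is accurate there because the rates are nearly
linear in the frequencies at that noise level.

## Problem sizes

Default tests and the acceptance script run the group menu
`Z₂, Z₃, Z₄, Z₅, Z₂×Z₂, Z₂×Z₃` at `n = 3..5` leaves (`n = 6` for `Z₂`),
50 fixtures per combination, 200 pruning-oracle comparisons, and 40
million-site simulation replicates — tensor sizes up to `6⁵ = 7776`,
chosen as the scale at which every algebraic identity can be checked
exhaustively in seconds.  The implementation itself handles `n ≈ 10` at
`d = 4` (a few million tensor entries) without the dense F/G matrices.

## Known limitations

- Inversion requires abelian groups; the type system only constructs
  cyclic-factor products, so non-abelian models are out of scope rather
  than rejected at run time.
- Saturated components (`𝒫_u ≈ 0`) and branch-cut crossings make the
  log step undefined/ambiguous; the package errors or warns, it does
  not attempt analytic continuation.
- The optional pseudocount for zero-count patterns restores
  invertibility of the arithmetic but voids the exactness guarantees;
  it is warned about loudly.
- No closest-tree projection, likelihood framework, or split-network
  visualisation: the deliverable is the exact conjugation and its
  immediate statistical calibration.
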