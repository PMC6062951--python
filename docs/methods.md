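# Methods

## Model class

A biochemical network is described in the complex formalism. Compounds
`x_1..x_m` combine into *complexes* (the left- and right-hand sides of
reactions), encoded by a non-negative integer matrix `Z` (compounds ×
complexes). Each reaction converts one substrate complex into one product
complex, encoded by a linkage matrix `B` (complexes × reactions) with a
single −1 (substrate) and +1 (product) per column. Internal fluxes take the
generalised mass-action form

    v_j(x) = k_j d_j(x) Π_i x_i^Z[i, S_j]

with `S_j` the substrate complex of reaction `j`, `k_j ≥ 0` a rate
constant, and `d_j` an optional state-dependent modifier (only the constant
`mass_action` modifier ships; the registry accepts others). Boundary terms
are constant inflows and first-order outflows attached to complexes. The
dynamics are `dx/dt = Z B v(x) + Z v_b(x)`.

The power-product form equals `exp(Z_S^T ln x)` on the positive orthant and
extends continuously to zero concentrations (`0^0 = 1`, `0^positive = 0`),
which matters because initial values of zero are legitimate inputs.

## Reduction by steady-state elimination

Given a user-chosen *important set* `M_I` of compounds (the ones the model
exists to predict), every complex containing none of them is *eligible* for
reduction. Reducing a complex removes its dynamics: the compound behind it
is placed in quasi-steady state, its net production set to zero, and its
concentration becomes the algebraic function of the remaining states
solving that balance. For the linear mass-action networks used throughout,
this is exactly the Schur complement (Kron reduction) of the complex-graph
Laplacian, and the eliminated concentrations converge to the full model's
steady-state values — the reduction pins the eliminated complexes to the
full model's steady state in the limit, while preserving the transient
balance relations. Reductions commute, so the `2^c` subsets of the `c`
eligible complexes enumerate all reduced models; the empty subset is the
full model and reproduces it identically.

Supported structure: each reduced complex must be a single compound with
unit stoichiometry appearing in no other complex (true of the targeted
model family). Anything else — multi-compound complexes, shared compounds —
is rejected with an explicit error rather than silently approximated.
Because the balance system is then linear in the eliminated concentrations,
each right-hand-side evaluation costs one extra model evaluation plus a
c×c solve. A singular balance (an eliminated compound with no consumption
route) is an error.

A greedy baseline reduces one complex at a time, always the one minimising
the symmetric error to the full model, and stops before the first step
whose best error exceeds a user threshold (ties: lowest complex index).

## Comparing models

Two models sharing `M_I` are compared by the time-averaged relative error

    I_T(x_r, x_f) = 1/(T n(M_I)) Σ_{i∈M_I} ∫_0^T |1 − x_ir(t)/x_if(t)| dt

symmetrised as `E_T = (I_T(a,b) + I_T(b,a))/2`. `E_T` is evaluated by
composite trapezoidal quadrature on the shared uniform trajectory grid
(default 1000 points; doubling the grid moves values by < 1e−4 on the
bundled example). Denominators are floored at `ε = 1e−12`, which only
protects the `t = 0` edge case of a zero initial value: important compounds
are assumed positive on `(0, T]`.

### The evaluation horizon T

`T` trades off two failure modes: too short and the error ignores part of
the transient; too long and the time average degenerates to the bare
steady-state difference, washing out the dynamics. The default policy fixes
`T` once per analysis as the earliest time at which the *reference* full
model is within 1% (per compound, relative to its steady-state level) of
its steady state, and shares that `T` across all parameter sets and
reductions so errors are comparable. All `E_T` values scale roughly like
`1/T` once the transient is covered, so reported error magnitudes are only
meaningful together with the declared `T` (the resolved value is written
into every run's `config.json`). For the bundled example `T ≈ 17.8`.

## Parameter uncertainty

Parameters (rate constants and boundary parameters; not initial values) are
sampled independently log-normally around the reference set, in either of
two parameterizations:

* `log_sd` — log-mean `ln(ref)`, log-sd = `spread` (spread on the log
  scale; the bundled example uses 0.1);
* `natural_cv` — natural-scale mean `ref` and sd `ref/s` for a scaling
  divisor `s`, via the exact moment matching `σ² = ln(1 + 1/s²)`,
  `µ = ln(ref) − σ²/2` (typical sweeps use s ∈ {3, 5, 10, 20, 50, 100}).

Both are first-class because uncertainty specifications arrive in both
conventions. Parameters with reference value exactly zero stay zero in
every draw. Sampling is reproducible under a seed; a sweep plan derives one
seed per spread from a master seed (`seed + index`).

## Clustering and scoring

All `n·2^c` models (every sampled parameter set under every reduction, each
reduction using its own parameter set's full steady state) are clustered
agglomeratively with single linkage on `E_T` (inter-cluster distance =
minimum pairwise error; SciPy's implementation, cross-checked in the test
suite against a brute-force O(N³) agglomerator). Each model's *dendrogram
position* is its leaf index under a canonical left-to-right traversal: at
every merge the child cluster created earlier sits left (leaves count as
created first, ordered by label). Leaf ordering in a dendrogram is not
unique; this rule is fixed and documented, and block separations — the
findings that matter — are invariant to it.

A reduction's score is the two-sample Kolmogorov–Smirnov statistic between
its `n` leaf positions and the full model's `n` positions: 0 means the
reduction is distributed through the dendrogram exactly like the full model
under the parameter uncertainty, 1 means complete separation. The score is
the statistic itself; no p-value is computed. Reductions scoring below
`α = 0.2` (default) are *consistent*; the *best model* is the consistent
reduction with the most eliminated complexes (ties: lowest score, then
lexicographically smallest bitmask). The full model scores 0 by definition.

For large candidate sets a two-stage mode runs a pilot (default 100 sets)
over all `2^c` reductions, keeps reductions scoring below a prefilter
threshold (default 0.5, the full model always retained), and re-runs the
survivors with a larger, freshly seeded sample. A resource guard refuses
single-stage runs beyond `n·2^c = 10 000` models. The all-pairs matrix is
the computational bottleneck (O(n²4^c) trajectory comparisons); it is
evaluated in vectorised row blocks, and the per-set simulations can be
distributed over workers with results independent of evaluation order.

## Synthetic networks

`generate_fixture_network(n_compounds, n_branches, seed)` emulates the
targeted model family: single-compound complexes, a constant inflow into a
source, a first-order outflow from a sink, a main conversion chain and
parallel single-compound side routes, rate constants and initial values
drawn uniformly from [0.1, 1), `M_I` = {source, sink}. All consumption
rates are positive, so the induced linear system is asymptotically stable
and a steady state exists — the generator cannot produce the divergent or
oscillatory regimes where the method's steady-state assumption fails, and
passing tests therefore say nothing about such models. Real networks with
nonlinear kinetics, conservation laws, or multi-compound complexes are
accepted by the pipeline only insofar as the reduction-structure
restrictions above hold.

## Numerical choices

* Integration: LSODA (stiffness-switching), rtol 1e−8 / atol 1e−10; error
  integrals at the 0.01 scale need trajectory error well below that.
  States are clipped at zero inside the right-hand side to absorb solver
  undershoot.
* Steady states: integrate in doubling windows (starting at 10 time units,
  hard cap 1e6) until `max|dx/dt| < 1e−8 (1 + max x)`; failure to converge
  is an error, since the method is undefined for models without a reached
  steady state.
* Determinism: same configuration and seed give bit-identical score
  tables; single-linkage ties are resolved by SciPy's deterministic
  implementation, and exact ties have measure zero for sampled parameters.
* Degenerate inputs: `c = 0` yields a single-row score table (score 0);
  empty position samples, mismatched grids, non-finite dissimilarities and
  oversize enumerations (`c > 16`) are explicit errors. Trajectories with
  non-finite values are excluded from the matrix with a logged warning and
  recorded in the result.

## Known limitations

* The method presumes an asymptotically stable steady state reached from
  the given initial values; limit cycles or divergence are out of scope.
* `E_T` is undefined when an important compound's trajectory sits at zero
  over a sub-interval; the ε-floor then inflates the integrand and results
  should not be trusted.
* The KS score compares position *distributions*; with small `n` the
  statistic is coarse (multiples of 1/n), and near-separations can print
  as scores just below 1.
* Whether a reduction separates completely in the dendrogram depends on
  the sampled cloud's chaining distances relative to the reduction's error
  offset; near the crossover the score fluctuates between seeds, so
  scores should be read jointly over several seeds (the acceptance script
  reports medians).
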