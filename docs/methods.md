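# Methods

## The model

`rspqbd` studies the long-run behaviour of the Rock–Scissors–Paper (RSP)
game played repeatedly inside a single well-mixed population of `N`
boundedly rational individuals. The population composition at time `t` is
the count vector `n = (n_R, n_S, n_P)` with `n_R + n_S + n_P = N`. Because
`n_P` is redundant, the process lives on the two coordinates `(n_R, n_S)`;
ordering the `(N+1)(N+2)/2` compositions by level `l = n_R` and phase
`n_S` makes the process a finite, state-dependent (generalised)
quasi-birth-death chain: one imitation event moves a single individual
between two strategies, so the level changes by at most one and the
generator `Q` is block-tridiagonal (switches between S and P stay inside a
level; switches involving R cross levels).

### Payoffs

An individual playing strategy `i` receives the population-average payoff

    pi_i = (A n)_i / N,

where `A` is the 3×3 payoff matrix (row = own strategy). This is the
mean-field convention in which the opponent is drawn uniformly from the
whole population, the focal individual included; with the zero-diagonal
matrices used throughout it differs from the self-excluded convention
(`(A n - A_ii)/(N-1)`, selectable via `Game(self_play=False)`) only by the
constant factor `N/(N-1)` applied to every payoff. The include-self
convention is the package default because it is the one under which the
solved chain reproduces the reference limiting distribution to all four
printed decimals (see "Calibration" below).

### Transition rates

Individuals are inert (only one switch per short time interval), myopic
(they react to current payoffs only) and noisy (they mutate spontaneously).
The default rate kernel, `payoff_difference`, assigns the transition
`n -> n - e_i + e_k` the rate

    q(i -> k) = [pi_k - pi_i]_+ + epsilon        if n_i > 0,
    q(i -> k) = 0                                if n_i = 0,

with `[f]_+ = max(f, 0)`: switches flow only toward strategies with a
strictly higher average payoff, at a rate proportional to the advantage,
plus a state-independent noise floor `epsilon >= 0`. Note the rate is per
ordered strategy pair, not per switching individual; the number of
potential imitators does not scale it. A second kernel,
`prevalence_weighted`, implements the more common imitation scaling
`n_i ((n_k/N) [pi_k - pi_i]_+ + epsilon)`; it produces the same qualitative
regimes but a quantitatively different limiting distribution (and, unlike
the default kernel, makes monomorphic states absorbing at `epsilon = 0`).

With `epsilon > 0` the chain is irreducible (verified explicitly by a
strong-connectivity search before every solve, rather than assumed), so a
unique stationary = limiting distribution `pi` exists: `pi Q = 0`,
`sum(pi) = 1`. With `epsilon = 0` the default kernel can still leave a
monomorphic state — the payoff comparison is defined for hypothetical
players of unplayed strategies — while the prevalence-weighted kernel
cannot; in either case the `epsilon = 0` chain is generally reducible and
the solver refuses it, naming the recurrent classes.

### Payoff families

* `make_symmetric_general(delta)`: zero diagonal, winning payoff
  `1 + delta`, losing payoff `-1`, cyclically symmetric. `delta = 0` is the
  standard zero-sum game. Under replicator dynamics the barycentre
  `(1/3, 1/3, 1/3)` is asymptotically stable for `delta > 0`, neutrally
  stable (a family of closed orbits) at `delta = 0`, and unstable for
  `delta < 0` — the win/loss product criterion `(1+delta)^3 vs 1`.
* `make_asymmetric(gamma)`:

      A(gamma) = [[ 0,       -3,  6*gamma],
                  [ 2*gamma,  0, -6      ],
                  [-2,   3*gamma,  0     ]].

  This family was constructed to satisfy, simultaneously and for every
  `gamma > 0`: (i) against `p = (1/2, 1/3, 1/6)` all strategies earn the
  same payoff `gamma - 1`, so `p` is the interior fixed point independent
  of `gamma`; (ii) `det A = 36 (gamma^3 - 1)`, so the fixed point is a
  stable focus for `gamma > 1`, sits in a centre of closed orbits at
  `gamma = 1`, and is an unstable focus for `gamma < 1`; (iii) each simplex
  vertex is a saddle. Derivation: write the cyclic game with win entries
  `w = (6γ, 2γ, 3γ)t` and loss entries `l = (3, 6, 2)s` in the orientation
  used by the symmetric family; the equal-payoff conditions at `p`
  decouple into one equation per power of `gamma`, fixing the two
  direction vectors uniquely up to the scales `t, s`, which are set to 1
  to keep integer entries.

### Cyclic orientation

Within the ordering (R, S, P), each strategy is displaced by its cyclic
successor: S invades R, P invades S, R invades P (winning entries at
matrix positions (R,P), (S,R), (P,S)). The two possible orientations of
the cycle produce mirror-image limiting distributions; the chirally
asymmetric entries of the reference distribution (the state (7,5,8) being
more probable than (8,5,7) at `N = 20`, `delta = 5`) single out this
orientation. Strategy names are otherwise arbitrary labels.

## Calibration of the model conventions

The kernel form, the averaging convention and the matrix orientation are
not independently tunable knobs: they were fixed, once, by requiring the
solved `N = 20`, `delta = 5`, `epsilon = 0.01` chain to reproduce the
published per-state limiting probabilities (0.1461 / 0.0646 / 0.0325 /
0.0287 / 0.0122 / 0.0117 for the six cyclic state classes, and cumulative
mass 0.8876 above threshold 0.01) at all four printed decimals. The
alternatives fail decisively: the prevalence-weighted kernel gives 0.1290
for the leading state, requiring a role model (`n_k > 0`) for imitation
gives 0.0703, the mirrored orientation swaps the 0.0325/0.0287 pair, and
the self-excluded averaging is off by 4e-4. After this discrete model
selection no parameter was adjusted anywhere in the package.

## Solvers

* **Block Gauss–Seidel** (default): the balance equations `pi Q = 0`
  couple each level only to its neighbours. Per sweep, each level's
  subvector solves `x_l Q_{l,l} = -(x_{l-1} Q_{l-1,l} + x_{l+1} Q_{l+1,l})`
  with the small dense diagonal blocks LU-factorised once (each is
  strictly diagonally dominant for `epsilon > 0`, hence nonsingular).
  Sweeps alternate ascending/descending level order; the iterate is
  renormalised after every sweep to prevent drift. Initial guess: uniform.
  Stopping: `max |pi Q| <= tol` with `tol = 1e-11` by default; sweep budget
  100000, with non-convergence reported, never silently returned. The
  tolerance is one decade tighter than strictly needed for four-decimal
  state probabilities so that the iterative and direct routes agree
  entrywise to 1e-8 even on the largest, most slowly mixing grids
  (`N = 100`, `delta = 0`, 5151 states, ~450 sweeps, ~2 s).
* **Direct**: sparse LU of the transposed balance system with the last
  balance equation replaced by the normalisation row. Used as the
  independent cross-check; tiny negative round-off entries are clipped to
  zero before renormalising.

For `N <= 8` both routes are additionally validated in the test suite
against a dense null-space computation of `Q^T`.

## Monte-Carlo oracle

The Gillespie module simulates the identical chain exactly (tabulated
per-state rates, exponential holding times, categorical event choice,
`numpy` `default_rng` with a mandatory seed) and estimates the limiting
distribution by time-weighted occupancy after a burn-in of 10% of the
horizon, with batch-means standard errors over 20 equal-time batches. It
exists purely as an independent check on the analytic machinery — the
limiting distribution itself always comes from the solver. Horizons in the
tests (5e5 time units for the reference chain, ~7.8e5 events) were sized so
the batch-means standard error on every appreciable state is below 0.01;
batch-means errors on a quasi-cyclic chain are mildly optimistic, which the
multi-state comparisons absorb with a Bonferroni-style allowance.

## Replicator reference

The deterministic counterpart `dx_i = x_i((Ax)_i - x'Ax)` is used to
classify the interior fixed point: the Jacobian is evaluated analytically
in the chart `(x_R, x_S)` (the simplex tangent plane), and the verdict is
by the maximum real eigenvalue part with a neutrality tolerance of 1e-9 —
at the neutral parameter values the eigenvalues are purely imaginary
analytically, so the tolerance only guards floating point. Trajectories
use adaptive RK45 with `rtol = atol = 1e-9` and a renormalisation guard
(drift of the component sum beyond 1e-9 is projected back).

## Reporting conventions

High-probability listings round half away from zero to four decimals for
display, sort by descending probability with `(n_R, n_S)` lexicographic
tie-break, and accumulate the listed mass. Ternary heat-map grids place R
at the top vertex, S bottom left, P bottom right; the hue value is linear
in probability normalised to the run's maximum (a log variant exists for
inspecting tails). Colours of the bundled matplotlib rendering are
intentionally basic; the CSV grid is the primary artefact.

## Problem sizes and defaults

* Noise: `epsilon = 0.01` is the default, matching the reference
  experiments; it is large enough for comfortable irreducibility yet small
  enough not to wash out the replicator regimes at `N >= 10`.
* Grids exercised by the test suite: `N ∈ {10, 20, 100}` ×
  `delta ∈ {-0.5, 0, 1}` for the symmetric family and `N ∈ {20, 50}` ×
  `gamma ∈ {0.1, 0.3, 0.5, 0.8, 1, 2}` for the asymmetric family — the
  full experiment grids; the largest chain (5151 states) solves in ~2 s
  per route.

## Known limitations

* The model is well-mixed: no spatial or network structure, no discrete
  synchronous updating, and exactly three strategies.
* The `epsilon = 0` boundary behaviour differs qualitatively between the
  two kernels (see above); only the noisy chain has a meaningful limiting
  distribution.
* Batch-means standard errors understate Monte-Carlo uncertainty when the
  batch length is not much longer than the chain's oscillation period;
  occupancy comparisons should use generous horizons, as the tests do.
* The asymmetric family is one representative of the (infinitely many)
  matrix families with fixed point `(1/2, 1/3, 1/6)` and a stability flip
  at `gamma = 1`; conclusions that depend on its specific off-equilibrium
  payoff magnitudes (e.g. which simplex edge attracts mass for small
  `gamma`) are family-specific.
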