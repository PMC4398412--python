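# Methods

## Model and assumptions

The package implements a three-group variant of the Naming Game. Languages
are atoms — `E` (European lexifier), `A` (coarse-grained African substrate),
`C` (creole) — with no internal lexicon or grammar: the claim being tested is
demographic, namely that the relative sizes of the European, Mulatto and
Bozal populations largely decide whether a creole emerges. Group sizes are
constant (no births, deaths or slave imports), Europeans never change
language and never creolize, and the rules are:

1. **Pair draw.** An unordered pair of distinct agents uniformly at random.
   A pair of two Europeans is a structural no-op (neither can hear), so it
   is discarded and redrawn without advancing the interaction counter. A
   European in a mixed pair is always the Speaker; two non-Europeans get
   roles by fair coin.
2. **Segregation gate.** A drawn European–Bozal pair interacts with
   probability `ε`; otherwise the step is a *null step* that still advances
   the counter (the alternative — not counting null steps — only rescales
   time and is exposed as `epsilon_null_advances_time=False`; it is rejected
   for the one degenerate demography where no interaction could ever occur).
3. **Game.** The speaker utters a uniform draw from her repertoire. A hearer
   lacking the language learns it; a hearer having it communicates
   successfully — always for `E`/`C`, with probability `δ` for `A` — and on
   success both repertoires collapse to the uttered language.
4. **Creolization.** After every interaction the hearer takes part in, if
   her repertoire contains both `A` and `E` (i.e. `{A,E}` or `{A,E,C}`), it
   becomes `{C}` with probability `γ`. The check applies to the hearer only
   and regardless of whether the interaction changed anything (the stricter
   changed-only variant is available as `creolize_only_on_change=True`).
   Note that a successful exchange collapses the repertoire *before* the
   check, so creolization is fed mainly by learning events and failed
   `A`-exchanges.

The all-`E` configuration is absorbing: once no repertoire contains `A`, no
`C` can ever be created again, and once `C` is also extinct nothing can
change. The all-`C` configuration is *not* absorbing (Europeans keep
injecting `E`), so the "asymptotic state" is defined as a time average over
the final `tail_window_fraction` (default 10%) of a horizon of
`max_interactions_per_agent` (default 2000) × `(N_M+N_B)` interactions, with
early exit on all-`E` absorption; an early-absorbed run accounts the
remainder of its tail window as the frozen all-`E` state, so the average is
always over the full nominal window.

## Parameters

| name | meaning | default |
|---|---|---|
| `gamma` | creolization probability per qualifying interaction | 0.8 |
| `delta` | `A`–`A` intelligibility (averaged multilingualism) | 0.1 |
| `epsilon` | European–Bozal contact probability (segregation) | 0.06 |
| `dominance_threshold` | tail-averaged fraction defining dominance | 0.8 |
| `max_interactions_per_agent` | horizon per Mulatto/Bozal agent | 2000 |
| `tail_window_fraction` | averaging window at the end of the run | 0.1 |

`γ=0.8, δ=0.1, ε=0.06` with `N=10000` is the headline parameter set; the
stripe spans `ε ∈ {0.05, 0.06, 0.07}` because `ε` is the one parameter that
sensibly shifts the transition curve. The `δ`-dependence of `A`-dominance
(a shared substrate language) is out of scope; `δ` sweeps are only a coarse
proxy.

All probabilities are independent Bernoulli draws per event; there is no
persistent pairwise intelligibility structure. Fractions weight a
multilingual agent `1/|repertoire|` per language held (normalizes to 1; at
quasi-stationarity almost all agents are monolingual so the choice is
immaterial; a monolingual-only variant is behind `weighting="monolingual"`,
which falls back to split weighting in states with no monolingual agent to
stay well defined).

## Numerical design

- **Two implementations, one semantics.** The step-level Python functions
  are the definitional surface; `run()` uses a numba-jitted kernel over
  bit-mask repertoires (E=1, A=2, C=4) with incrementally maintained
  language-weight accumulators, giving ~10⁷ interactions/s. Their agreement
  is not assumed: the exact-chain module enumerates repertoire multisets
  (agents of a group with equal repertoires are exchangeable) and builds the
  exact one-step transition matrix under the same rule variants; tests check
  the Python layer against chain rows (single-step frequencies) and the
  kernel against chain absorption probabilities and expected fractions.
- **Exact chain numerics.** Rows must sum to 1 within 1e-12 (else an
  internal-consistency error); the absorbing all-`E` row is then pinned
  exactly. Finite-horizon quantities use binary-exponentiation of the
  transition matrix; the infinite-horizon absorption probability solves the
  fundamental-matrix system `(I-Q)h = r` directly, which is robust for
  near-absorbing chains. Enumeration is guarded at 10⁵ states.
- **Seeds.** One seeded generator per run; replicate `r` uses `seed + r`;
  grid cells and bisection evaluations get disjoint seed blocks derived from
  the base seed, so every result is bit-reproducible.
- **Counts from coordinates.** `point_to_counts` rounds half-up (`n_black`
  then `n_M`), keeps at least one European whenever `y < 1`, and errors on
  demographies with no Mulattos or Bozals. The paper-scale plane uses
  `N = 10000`; reduced-scale defaults are below.
- **Transition curve.** The curve is defined through replicate dominance
  *probability*, not a single run: `y*(x)` is where `p_creole` crosses 1/2,
  located by bisection to a `y_tolerance` after verifying the endpoints
  bracket the crossing; an `x` with no bracket (e.g. `x → 1`, where no
  Bozals exist and `p_creole ≡ 0`) is reported as NaN rather than
  extrapolated. Curves for different `ε` reuse the same seed blocks
  (common random numbers), which stabilizes the `ε`-ordering of nearby
  curves. Stripe lookups interpolate linearly between tabulated `x` and
  clamp to the nearest endpoint outside the range, with a warning.
- **Classifier.** The stripe boundaries are inclusive: a point on either
  curve is `uncertain`. County/parish rows are classified exactly like
  territories. Accuracy is computed over decided labelled records;
  uncertain ones are listed as borderline, ordered by distance to the mid
  curve.

## Synthetic census generator

`synthesize_census` emulates the schema and the empirically observed
clustering of historical census tables — creole territories at high Black
fraction `y`, non-creole ones at low `y` — by sampling points at least a
chosen margin above the upper / below the lower stripe curve, drawing totals
log-uniformly over ~10²·⁵–10⁶ and integerizing them; draws whose rounding
would cross the margin are rejected. It does **not** emulate real-data
features such as category mismatch between census labels and
creole-studies groups, within-territory heterogeneity, enumeration error, or
territories that genuinely sit inside the stripe. Passing the round-trip
tests therefore shows the projection/classification machinery is coherent,
not that historical tables are cleanly separable; real tables near the
transition will land in the uncertain band by design.

## Problem sizes used in the tests

Desk-scale settings keep the default suite and the acceptance script
self-contained: paper-scale single runs (`N = 10000`, 5 replicates) for the
two dominance checks; a 5×5 grid at `N = 2000` for the `A`-never-spreads
property; transition curves at `N = 1000` (9 replicates, tolerance 0.03)
for the `ε`-monotonicity check; a session stripe at `N = 600` for
classifier round trips; and 2000-replicate equivalence runs on populations
of ≤ 5 agents at a 15-interactions-per-agent horizon, where absorption
probabilities are far from 0/1 and hence informative. A full
`N = 10000` fine-grid stripe is the same code with a larger config and is
left to the user.

## Known limitations

- Languages are unstructured atoms; borrowing, partial restructuring and
  lexical gradience are summarized by the single probability `γ`.
- No population turnover: real plantation colonies had continuing slave
  imports and high mortality, which the constant-size model ignores.
- `A` is a single coarse-grained substrate; the regime where one African
  language is shared widely enough to spread is not modelled.
- Europeans never acquire the creole, an explicit simplification.
- The transition curve inherits Monte-Carlo noise at desk scale; stripe
  curves built with few replicates can locally touch or cross where the
  underlying curves are close.
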