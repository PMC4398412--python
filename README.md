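# creolang

An agent-based model of how contact languages — creoles in particular —
emerge from the demographic structure of colonial plantation societies, with
tools to map the demographic phase diagram and to classify census tables by
whether a creole is predicted to have emerged.

## Who this is for

Researchers in language dynamics, cultural evolution and quantitative
(socio)linguistics who want a reproducible implementation of a
Naming-Game-style model of creolization, and historians/creolists who want to
project census-style demographic tables onto the model's creole/no-creole
transition diagram.

## The model

A population of `N` agents is split into three groups whose sizes stay
constant: Europeans (`Eu`), Free Colored / Mulattos (`M`) and Bozal slaves
(`B`). Each agent carries a repertoire, a non-empty subset of three
coarse-grained languages: the European lexifier `E`, the African substrate
`A`, and the creole `C`. Initially Europeans and Mulattos speak `{E}` and
Bozals `{A}`; no one speaks `C`.

At each step an unordered pair of distinct agents is drawn uniformly and
plays a speaker/hearer game; the speaker utters a language drawn uniformly
from her repertoire:

- if the hearer lacks the uttered language she **learns** it (adds it to her
  repertoire);
- if she has it, communication **succeeds** — always for `E` or `C`, with
  probability `δ` for `A` (Bozals share no common African language, so mutual
  intelligibility is partial) — and on success both agents collapse their
  repertoires to the uttered language;
- afterwards, a hearer whose repertoire contains both `A` and `E` replaces it
  with `{C}` with probability `γ` (**creolization**: bilingual speakers can
  bootstrap a hybrid language).

The contact topology encodes segregation: Europeans only ever speak (they are
an immutable source of `E`), and a drawn European–Bozal pair interacts only
with probability `ε`, so for small `ε` Mulattos mediate between Europeans and
Bozals.

Writing `x = N_M/(N_M+N_B)` (Mulatto fraction of the Black population) and
`y = (N_M+N_B)/N` (Black fraction of the whole population), replicate
simulations define a sharp transition curve `y*(x)`: above it the creole `C`
comes to dominate the Mulatto+Bozal population (tail-averaged fraction above
80%), below it the lexifier `E` does, and `A` never spreads. Running the
curve at `ε = 0.05, 0.06, 0.07` yields an uncertainty stripe; census tables
projected into the `(x, y)` plane are classified as `creole_predicted`,
`no_creole_predicted` or `uncertain` depending on where they fall.

## Worked example

```bash
python examples/01_single_run.py
```

```
demography: 100 Europeans, 95 Mulattos, 1805 Bozals
tail-averaged fractions: f_E=0.006 f_A=0.000 f_C=0.994
dominant language: C  (absorbed to all-E: False)
```

A 95%-Black demography with few Mulattos sits deep in the creole region:
99.4% of the Mulatto+Bozal population ends up speaking the creole `C`
(time-averaged over the final 10% of the run), far above the 80% dominance
threshold; the substrate `A` has gone extinct. Deep in the European region
(few Blacks) the same dynamics instead absorbs into the all-`E` state.

The other examples build the exact-chain cross-check
(`02_exact_oracle.py`), a reduced-scale transition stripe with the
power-0.2 expanded x-axis plot (`03_phase_stripe.py`), and an end-to-end
census classification (`04_census_classification.py`).

A thin CLI wraps the same library calls:

```bash
creolang stripe --config config.yaml --out out/
creolang classify --out out/ census.csv out/stripe.csv
```

No historical census tables are bundled; the loader accepts CSVs with
columns `territory, n_white, n_free_colored, n_slave` (plus optional
`subdivision, year, creole_observed`, and common header aliases), and
`creolang make-fixtures` generates labelled synthetic tables.

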