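# hspscreen

Hansen-solubility-parameter (HSP) toolkit for food-contact materials:
estimate the HSP of an **insoluble, cross-linked polymer** from
solvent-swelling data, then screen **migration/permeation risk** against
food-component groups via Hansen distances (Ra) and the Relative Energy
Difference (RED).

It is aimed at packaging and materials scientists who want a fast,
reproducible first-pass compatibility screen — before committing to
migration cells, simulant studies or diffusion modelling.

## The method in brief

Every substance sits at (δd, δp, δhb) in MPa^1/2 (dispersion, polar,
hydrogen-bonding cohesion parameters). Compatibility is distance:

```
Ra² = 4 (δd1 − δd2)² + (δp1 − δp2)² + (δhb1 − δhb2)²
RED = Ra / Ro          # Ro: interaction radius of the polymer
```

RED < 1 → likely mutual affinity (migration/sorption risk); RED > 1 →
poor compatibility. For a cross-linked polymer the HSP triple cannot be
fitted from solubility, so `hspscreen` fits it from **swelling**: across a
solvent panel, % swelling should decrease linearly with Ra, and the
polymer's HSP is the point in the box [2.5, 40]³ maximizing the R² of that
(negative) linear relationship — found by a deterministic coarse-to-fine
grid search with boundary flags and plateau reporting, because this
objective is often nearly flat. Solvents that chemically alter the polymer
(hydrolysis by water, transesterification by alcohols) are flagged and
excluded from the fit. Ro defaults to the distance to the poorest swelling
solvent.

## Worked example

The package ships the reference experiment for cutin, a cross-linked plant
polyester: seven solvents, two independent repetitions, with water flagged
as hydrolyzing. Estimate cutin's HSP (also excluding the suspect alcohol):

```bash
hspscreen estimate \
    --swelling src/hspscreen/data/cutin_swelling.csv \
    --exclude isopropanol --out cutin.json
```

`cutin.json` then contains (abridged):

```json
{
  "mean_hsp": [19.675, 5.35, 2.55],
  "boundary_flags": [false, false, true],
  "repetitions": [
    {"hsp": [19.2, 5.7, 2.6],  "r_squared": 0.926, "slope_sign": "negative"},
    {"hsp": [20.15, 5.0, 2.5], "r_squared": 0.924, "slope_sign": "negative"}
  ],
  "swelling_summary": {"hexane": "16 ± 5.7", "chloroform": "184.5 ± 13.4", "...": "..."}
}
```

Read: the two repetitions agree near (19.7, 5.4, 2.5) MPa^1/2 with R² ≈
0.93, and the hydrogen-bonding component rests on the 2.5 lower bound
(`boundary_flags[2]`) — the panel does not identify δhb from below, so
treat that component as "≤ small", not as a confident estimate.

Now screen that polymer against the shipped food-component group database
(six groups with published mean ± sd HSPs), with Ro set by hexane, the
poorest swelling solvent:

```bash
hspscreen screen --polymer cutin --polymer-hsp 19.7,5.4,2.5 \
    --ro-solvent hexane \
    --db src/hspscreen/data/food_group_summaries.csv --format markdown
```

```
## Compatibility screen: cutin

Ro = 11.29 MPa^1/2, mode = summary_level, borderline band = ±0.05 around RED = 1

| group                  | Ra (MPa^1/2) | RED         | verdict            |
|------------------------|--------------|-------------|--------------------|
| carbohydrates          | 22.18 ± 1.98 | 1.96 ± 0.18 | poor compatibility |
| fats                   | 8.13 ± 1.21  | 0.72 ± 0.11 | high affinity      |
| amino_acids            | 14.67 ± 3.33 | 1.30 ± 0.30 | poor compatibility |
| vitamins               | 6.10 ± 1.37  | 0.54 ± 0.12 | high affinity      |
| polar_essential_oil    | 7.05 ± 1.75  | 0.62 ± 0.16 | high affinity      |
| nonpolar_essential_oil | 6.95 ± 0.75  | 0.61 ± 0.07 | high affinity      |
```

Read: cutin is expected to interact with fats, vitamins and essential-oil
components (RED < 1 — migration into fatty foods and sorption of aroma
compounds are plausible and worth quantifying), while highly polar
carbohydrates and amino acids are poor partners (RED > 1). The ±
uncertainties propagate the spread of each group's HSPs; where an error
bar crosses 1, individual members of the group may still interact.

Multi-polymer comparison (`hspscreen compare`) ranks candidate materials
per group, and `hspscreen simulate` / `recovery-study` generate synthetic
swelling experiments with known ground truth to validate the estimator
(median per-component recovery error ≈ 0.3–0.9 MPa^1/2 at the default
noise; see `docs/methods.md`).

## Layout

- `src/hspscreen/core.py` — Hansen-space geometry (Ra, RED, verdicts)
- `src/hspscreen/swelling.py` — swelling observations and summaries
- `src/hspscreen/estimation.py` — constrained R²-maximization fit
- `src/hspscreen/components.py` — food-component and polymer databases
- `src/hspscreen/screening.py` — Ra/RED screening, uncertainty, comparison
- `src/hspscreen/synthetic.py` — synthetic experiments, recovery studies
- `src/hspscreen/cli.py`, `report.py` — CLI and report rendering
- `src/hspscreen/data/` — shipped solvent table, cutin swelling fixture,
  food-group summaries, polymer records (and a documentation-only oil
  absorbance fixture)

`docs/methods.md` documents the model, its assumptions, numerical choices
and known limitations.
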