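# overflux

Analysis toolkit for **metabolite secretion and feedback inhibition in
anaerobic overflow metabolism**, built around the fermentation physiology of
the human gut symbiont *Bacteroides thetaiotaomicron*. The package starts
where quantified metabolomics ends — replicate concentration tables of spent
culture medium (mM) and OD600 growth curves — and answers four questions:

1. **Where does the secreted carbon go?** Secretion flux maps express each
   metabolite's endpoint concentration as a percent mole-carbon share,

   F(x) = 100 · c_x·C_x / Σᵢ cᵢ·Cᵢ,

   over a precursor network (pyruvate, acetyl-CoA, oxaloacetate/aspartate,
   succinyl-CoA, serine-cycle and purine nodes), with a glucose carbon
   balance that infers the CO₂ remainder.
2. **How strongly does exogenous acetate suppress secretion?** Against the
   additive null model x_null = x_init + A_sup (supplemented species) or
   x_init (all others), the fold variance x_var = x_obs/x_null − 1 measures
   the "missing" fraction of each metabolite; its OLS slope versus supplement
   concentration is the per-metabolite molar suppression coefficient.
3. **Which response mechanism explains the data?** Five scenarios —
   additive (a>0, b=0), balanced secretion/absorption, feedback inhibition
   without regulation (a<0, b=0), synergistic feedback with compensatory
   regulation (a<0, b<0), and positive upregulation (a>0, b>0) — are
   simulated as endpoint responses Δx = a·A + b·A² and discriminated by
   nested least squares with an F test and sign rules.
4. **What does a stoichiometric model predict?** A small self-contained
   FBA engine (linear programming over S·v = 0 with media-defined uptake
   bounds and a lexicographic minimum-total-flux tie-break) ships with a
   curated ~50-reaction central-carbon network and runs the 8-condition
   grid {high, low glucose} × {±acetate} × {±formate}, plus reaction
   knockouts.

A seeded synthetic-data generator reproduces the study design (acetate at
{0, 0.5, 1, 5, 10} mM, 5 biological × 5 technical replicates, multiplicative
noise) with known ground truth, so every stage is testable end to end.

## Worked example

```python
from overflux import NullModel, null_expectation, secretion_delta, fold_variance

model = NullModel("acetate", x_init=6.6, additive_supplement=True)
print(null_expectation(model, 10.0))        # 16.6
print(secretion_delta(10.81, 6.6))          # 4.21
print(fold_variance(10.81, model, 10.0))    # -0.3488
```

With a 6.6 mM acetate control, a 10 mM supplement should yield 16.60 mM if
secretion were simply additive; an observed endpoint of 10.81 mM is only a
4.21 mM increase, i.e. ~35 % of the expected acetate is missing — the
signature of feedback inhibition.

`examples/` holds one short script per capability; running
`python examples/05_fba_grid.py` prints

```
predicted biomass per condition:
  HG         0.4790
  HG+Fo      0.4790
  HG+Ac      0.4790
  HG+Ac+Fo   0.4790
  LG         0.0172
  ...
knockout ASNS: objective change 0.00e+00, max exchange-flux change 0.00e+00
knockout ASNL: objective change 0.00e+00, max exchange-flux change 0.00e+00
```

— at high glucose, supplementing acetate/formate leaves predicted biomass
unchanged (the supplements provide neither ATP nor assimilable carbon on
this network), and either asparagine-synthesis route can be deleted without
any effect on growth or exchange fluxes.

The pipeline runner wires the stages together from the shell:

```sh
overflux all --out run1 --seed 7      # synth -> fluxmap -> suppression ->
                                      # classify -> growth -> fba + manifest
```

Identical seeds produce byte-identical output bundles.

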