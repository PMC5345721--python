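# dosagegi

Quantitative analysis of dosage genetic interactions in yeast
overexpression screens, for geneticists working with galactose-inducible
kinase and transcription-factor (TF) alleles: fitness estimation from
plate-reader growth curves, toxicity classification, genetic-interaction
(GI) scoring of spot-dilution assays under a multiplicative null, primary
colony-array candidate calling, protein-feature association statistics,
and assembly of signed bipartite GI networks. A synthetic-data generator
with planted ground truth makes every stage testable end to end.

## The statistics at the core

**Fitness from growth curves.** With baseline culture density *B* (the
inoculation OD600, ~0.1) and *t<sub>k</sub>* the earliest time the culture
reaches *B*·2<sup>k</sup>, the doubling time is

> D = (t₅ − t₂) / 3,

the average doubling time between the second and fifth doubling — a
window inside exponential phase. Crossings are located by log-linear
interpolation, which is exact for exponential growth. Strain fitness is
normalized to wild type, *f* = D<sub>wt</sub> / D<sub>OE</sub>, and a
strain is **toxic** when *f* ≤ 0.7 (growth rate reduced by 30% or more).

**GI scoring from spot dilutions.** Each strain's semiquantitative
fitness is its number of viable spots out of the wild-type count (5
spots, from 15-fold serial dilutions). Under the multiplicative null the
double mutant is expected at the product of the single fitnesses:

> GI score = f<sub>observed</sub> − f<sub>A</sub>·f<sub>B</sub>,  Genetic Interaction Strength = 5 × GI score ∈ [−5, 5].

Negative scores are synthetic-dosage-lethal (SDL: kinase loss-of-function
× TF overexpression) or double-dosage-lethal (DDL: cyclin OE × TF OE)
interactions; positive scores are alleviating. All spot arithmetic is
exact rational arithmetic — no rounding.

**Feature statistics.** Toxic vs nontoxic groups are compared on total
disordered-region length, conserved linear-motif count and PPI count with
the Wilcoxon/Mann–Whitney rank-sum test (exact enumeration for small
groups, tie- and continuity-corrected normal approximation otherwise);
substrate enrichment among SDL hits uses the upper-tail hypergeometric
test with fold = (k/n) / (K/N).

## Worked example

The canonical spot-dilution calculation — wild type shows 5 viable spots,
the kinase single mutant 5, the TF OE single 4, the double mutant 1:

```python
from dosagegi.spots import SpotAssay, score_assay

rec = score_assay(SpotAssay("cdk-tf", "SDL", "inducing",
                            wt_spots=5, a_spots=5, b_spots=4, double_spots=1))
print(f"single fitness A = {rec.f_a}  B = {rec.f_b}")
print(f"expected double  = {rec.f_expected}")
print(f"observed double  = {rec.f_observed}")
print(f"GI score         = {rec.gi_score}   strength = {rec.strength}   sign = {rec.sign}")
```

prints

```
single fitness A = 1  B = 4/5
expected double  = 4/5
observed double  = 1/5
GI score         = -3/5   strength = -3   sign = negative
```

The double mutant is far sicker than the product expectation (0.2
observed vs 0.8 expected): a strong negative interaction, strength −3 on
the −5..5 scale.

A small simulated screen, from curves to fitness calls:

```python
import dosagegi as dg

cfg = dg.SimConfig(seed=42, n_kinases=6, n_tfs=24, wt_replicates=6,
                   n_sdl_queries=1, n_ddl_queries=1, gi_rate=0.15)
truth = dg.synthetic.simulate_ground_truth(cfg)
curves = dg.synthetic.simulate_growth_curves(cfg, truth)
table = dg.growth.fitness_table(curves)
print(table.head(5).to_string(index=False))
```

```
strain_id      d_min  fitness       sd  n  censored  toxic
   KIN000 167.592879 0.586622 0.013951  3     False   True
   KIN001 110.717684 0.887942 0.020200  3     False  False
   KIN002  97.142041 1.012147 0.026579  3     False  False
   KIN003  98.272407 1.000624 0.029516  3     False  False
   KIN004 144.597995 0.680163 0.022986  3     False   True
```

`d_min` is the per-strain doubling time in minutes, `fitness` its
wild-type-normalized value (KIN000 grows at 59% of the wild-type rate and
is called toxic). The same objects drive the full pipeline
(`dosagegi.pipeline.run_pipeline`): simulate 1536-format colony arrays,
normalize and collapse quadruplicates, call candidate pairs from
mutant/control size ratios, confirm them by simulated spot assays, and
assemble the signed bipartite network (`dosagegi.network`).

Everything is also exposed as a CLI:

```bash
dosagegi simulate --seed 42 outdir/
dosagegi fitness outdir/growth_curves.tsv fitness.tsv
dosagegi gi-score outdir/spot_assays.tsv gi.tsv
dosagegi network --format SIF gi.tsv net.sif
```

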