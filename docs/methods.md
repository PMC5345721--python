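# Methods

## Scope and data flow

The package mirrors the quantitative workflow of a yeast overexpression
genetics study: (1) OD600 timecourses → doubling time → wild-type-
normalized fitness → toxicity calls; (2) 1536-format colony arrays →
plate normalization → quadruplicate collapse → candidate GI calls;
(3) spot-dilution confirmation assays → GI scores under a multiplicative
null; (4) protein feature tables → toxic-vs-nontoxic rank-sum statistics
and substrate enrichment; (5) confirmed GI records → a signed bipartite
kinase/cyclin–TF network. A synthetic-data generator with planted ground
truth stands in for the raw screen data, so every stage is testable
without wet-lab input.

## Growth model and the doubling-time statistic

Simulated cultures follow logistic growth
OD(t) = K·OD₀·e^{rt} / (K + OD₀·(e^{rt} − 1)) with rate
r = ln2·f / T_wt for a strain of fitness f; early growth is exponential,
which is the regime the estimator uses. The estimator finds the earliest
crossings of B·2² and B·2⁵ above the baseline B (default: the first OD
reading; fixed-value and min-of-first-three policies are available) by
log-linear interpolation, exact in log space for exponentials, and
reports D = (t₅ − t₂)/3.

A useful property of the logistic model: crossing times scale as 1/r for
fixed (OD₀, K), so the ratio D_wt/D_OE recovers the true relative fitness
*exactly* on noiseless logistic curves regardless of carrying capacity.

Censoring: a strain that does not complete five doublings in the run gets
the same spacing statistic on its last completed doubling
(D = (t₄ − t₂)/2, or t₃ − t₂), and below three doublings a lower bound
D ≥ t_end − t₂; its fitness is an upper bound and is flagged, never
dropped. A strain that cannot even double twice is fully censored and
classified toxic (any strain at the 0.7 cutoff completes five doublings
within 24 h under the defaults). The toxicity boundary is inclusive:
fitness ≤ 0.7 is toxic ("reduced by 30% or more").

Key defaults (all `SimConfig` fields): sampling every 15 min for 24 h
from OD₀ = 0.1, triplicate strains, 40 wild-type reference replicates
pooled globally, Gaussian read noise sd 0.01 floored at 0. Wild-type
doubling 80 min and carrying capacity K = 8 density units: the OD scale
is blank- and linearity-corrected culture density, not raw single-path
OD, chosen so that the five-doubling threshold (B·2⁵ = 3.2 from
OD₀ = 0.1) is observable and a fitness-0.3 strain still completes five
doublings inside the 24-h horizon — the estimator's own applicability
condition. Replicates are aggregated by the mean, with the sd reported.

## Spot-dilution GI scoring

Fitness is spots/wt_spots (exact `Fraction`s); the null expectation is
the product of the single fitnesses; GI score = observed − expected;
strength = 5 × score. Sign threshold |score| ≥ 0.2 — one spot out of
five, the assay's resolution. Pairs whose *noninducing* control double
shows fitness < 0.6 are flagged uninterpretable rather than scored;
spot counts above wild type clamp fitness at 1 (an option retains raw
ratios for studying suppression). No rounding anywhere.

Quantization: with 5 scored spots, fitness is resolved in steps of 0.2.
A planted deviation that is a multiple of 0.2 is recovered exactly in the
noiseless limit; off-grid single fitnesses can leave up to ±0.2 (one
spot) of quantization in a null pair's score, which is why the sign
threshold equals the resolution.

## Primary screen processing

Plates are 32 × 48 with each strain pinned as a 2 × 2 quadruplicate; the
outer two rows/columns are border controls, excluded from statistics but
rescaled. Normalization divides by the median of non-border, non-empty
colonies. An optional row/column median polish (log scale, iterated to
convergence, cap 500 sweeps) removes smooth spatial gradients; it is
**off by default** because each array row carries a fixed set of strains,
so a polish cannot distinguish a spatial artifact from genuine
row-correlated strain composition — on simulated plates with a bimodal
fitness distribution it visibly distorted mutant/control ratios. Iterated
median polish can settle into a small limit cycle, so renormalization
with polish is a no-op only to ~1e-6 (exactly idempotent without).

Quadruplicates collapse by the median; a size-0 colony is a dead-colony
*observation* (an all-dead block collapses to 0, the strongest negative
signal), while strains present at fewer than 2 positions are flagged
missing; replicate CV > 0.5 flags jackpot colonies. Candidates are called
from the mutant/control size ratio, which under plate-median
normalization approximates 1 + gi/(f_A·f_B): negative when ratio ≤ 0.65,
positive when ≥ 1.5, ordered by |log2 ratio|. The 0.65 lower threshold is
chosen from the observation model: a deviation of −0.4 against near-wild-
type singles yields ratio ≈ 0.6, so a 0.5 threshold could never call it,
while 0.65 calls it with margin for quadruplicate noise; positives are
expressible only with headroom below the product null, which pushes their
ratio past 1.5. Every constant is a config knob. This stage is a
reproducible stand-in for by-eye candidate picking; its output feeds the
spot-confirmation stage, and only spot-confirmed pairs become network
edges.

## Feature statistics

Toxic vs nontoxic comparisons per protein class (kinase, TF; dual-
annotated genes count in both) use the Wilcoxon/Mann–Whitney rank-sum
test with midranks. The exact null — the distribution of the rank sum
over all C(n, n_a) labelings — is computed by integer dynamic programming
over doubled midranks whenever min(n) ≤ 10 and the arrangement count is
≤ 2·10⁶; otherwise a normal approximation with tie and continuity
corrections. Two-sided P = min(1, 2·min(lower, upper)). P-values are
reported raw per comparison; Benjamini–Hochberg across the three features
within a class is optional. Proteins with no annotated physical
interaction are excluded from the PPI comparison (never-tested is not
zero). Substrate enrichment is the upper-tail hypergeometric probability
of the observed overlap with fold = (k/n)/(K/N).

Feature distributions in the generator are gamma (disorder length, PPI
counts; non-negative, right-skewed) and Poisson (motif counts), with
group means configurable; the defaults are the observed toxic/nontoxic
means per class (e.g. kinase disorder 309 vs 218 aa). Gamma shapes
(3 for disorder, 2 for PPI) set realistic dispersion; only group means
and extrema are matched to observation, not higher moments.

## Ground truth and planted interactions

Single-mutant fitness is bimodal: toxic strains uniform on (0.12, 0.7) —
the floor keeps the second doubling observable within 24 h — and nontoxic
strains truncated-normal (0.97, 0.06) on (0.705, 1.1], since OE strains
rarely outgrow wild type by more than ~10%. Toxic fractions default to
the observed 20% (kinases) and 26% (TFs). Query alleles (kinase
loss-of-function for SDL, cyclin OE for DDL) grow like wild type at
screening doses. Interactions are planted per query × TF pair at rate
0.05, 80% negative, magnitudes {0.4, 0.6, 0.8} in fitness-deviation
units; a positive effect is planted only when fully expressible below
full viability (f_B + e ≤ 1), otherwise the pair carries none. Double
fitness is clamp(f_A·f_B + gi, 0, 1). Known-substrate labels are planted
with higher probability (0.35 vs 0.10 background) on negatively
interacting SDL pairs, emulating the enzyme–substrate enrichment the
screen is designed to detect.

All randomness derives from one seed plus fixed per-product stream tags,
so one seed fixes every output byte.

## What the generator does and does not emulate

It reproduces the sampling design (triplicates, 24 h × 15 min, ~40 wt
replicates, 5-spot dilutions, 1536 quadruplicate arrays), realistic noise
magnitudes, plate-level effects and optional smooth gradients, and the
statistical structure the analysis assumes (multiplicative null, bimodal
fitness, group-mean feature differences). It does not emulate lag phase,
diauxic shifts, condensation artifacts or pinning failures at plate
edges, image-analysis error in spot counting, batch effects across days,
or biological pleiotropy (a strain's growth, colony and spot phenotypes
derive from one latent fitness). Passing tests therefore demonstrate that
the estimators recover what the model plants at realistic noise — not
that real screens are free of the artifacts the generator omits.

## Numerical choices and degenerate inputs

Log-linear crossing interpolation falls back to linear when the bracketing
sample is nonpositive; ODs are floored at 1e-4 after blank correction;
the first upward crossing wins when noise causes multiple crossings, with
optional 3-point median pre-smoothing (off by default). Spot counts round
half-up (monotone in fitness, no banker's bias). Empty feature groups
warn and yield flagged undefined results; unscorable assays (wild type at
0 spots) and zero-control screen pairs are flagged, not dropped. Network
duplicates of equal sign merge by mean strength; opposite-sign duplicates
are conflicts, excluded with a report (an error in strict mode);
bipartiteness violations are always errors.

## Problem sizes

Default simulations run the full study scale (129 kinases, 239 TFs, nine
query screens) in seconds; the test suite uses the same scale for the
calibration checks and down-scaled screens (≤ 120 TFs, ≤ 4 queries) for
pipeline unit tests. Null calibration of the rank-sum test uses 1000
simulations at the study's 26/103 group split.

## Known limitations

* The censored-fitness upper bound is informative only down to about two
  completed doublings; slower strains are classified toxic by fiat
  (correct under the defaults, where any fitness-0.7 strain completes
  five doublings, but a very short horizon would overcall toxicity).
* The screen candidate stage cannot detect negative deviations smaller
  than ~0.35 against healthy singles, and positive interactions are
  structurally invisible when the product null is already near 1 — a
  property of dosage screens, not just of this implementation.
* The 5-spot readout cannot resolve effects below 0.2, and a null pair
  with off-grid singles can quantize to a spurious ±0.2 score; real
  confirmation practice (repeats, by-eye grading of spot size) is not
  modeled.
* The rank-sum normal approximation is accurate to a few percent of P at
  the study's group sizes but should not be trusted for extreme tails
  (P ≪ 1e-4) — use the exact mode where group sizes allow.
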