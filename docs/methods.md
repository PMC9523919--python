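# Methods

## Interaction model

A candidate genetic interaction is a (target, partner) pair in one tissue:
the target is perturbed (knocked out/down in a screen, or inhibited by a
drug), the partner conditions the effect through mutation. At least one
side must be a chromatin regulator (CR); gene identifiers are opaque,
case-sensitive symbols with no alias resolution.

Each screen carries an orientation flag declaring which direction of its
raw score means "more viable" (CERES-style essentiality scores are
LOW_IS_VIABLE and get negated; fitness/viability scores are HIGH_IS_VIABLE).
After orientation, the per-pair test within a tissue is a one-sided
Wilcoxon rank-sum of target scores, partner-mutant vs wild-type lines, run
in both directions: mutants lower ⇒ synthetic lethality (CSL), mutants
higher ⇒ synthetic viability (CSV). A mutation is "altering" when its class
is non-silent (missense, nonsense, frameshift, splice, other); the class
list is configurable to restrict stratifications to specific mutation
types.

Consensus across screens: pairs nominally significant (p < α = 0.05) in the
same direction in at least `min_support = 2` screens have their directional
p-values from **all** screens in which the pair was testable combined by
Fisher's method (−2 Σ ln pᵢ ~ χ²(2k)); records are kept at combined
p < 0.05. Combining over all testable screens rather than only the
supporting ones avoids selection bias in the combined statistic; this is a
deliberate choice where either reading is defensible. A pair significant as
CSL in one screen and CSV in another is emitted as a pair of conflict
records, never silently resolved.

Multiple-testing: the screen scan uses nominal p-values by design — tissue
panels are small and the discovery stage feeds several orthogonal
confirmation filters (consensus across screens, drug response, cohort
validation); BH adjustment is available via `crgi.stats.bh_adjust` for
users who want it per tissue.

## Thresholds and parameters

| parameter | default | meaning |
|---|---|---|
| α (per-screen, drug filter) | 0.05 | one-sided nominal significance |
| combined-p cutoff | 0.05 | Fisher consensus filter |
| min_support | 2 | screens that must agree directionally |
| min tissue lines | 4 | "more than three cell lines" per tissue |
| min group size | 3 | mutant and wild-type lines per test |
| cohort mutation frequency | > 0.10 | partner inclusion in cohort analyses |
| FDR (differential omics, pathways) | 0.1 | BH-adjusted cutoff |
| permutations (PPI null) | 1000 | with +1 pseudocount in the empirical p |

All thresholds are recorded in every stage manifest and overridable via the
YAML config.

## Statistical primitives

`crgi.stats` wraps the scientific-Python stack behind a fixed contract:

* rank-sum: exact distribution when the pooled sample is ≤ 12 with no ties
  (deterministic small-sample behaviour for oracle testing); otherwise the
  normal approximation with tie correction and continuity correction.
  Constant pooled input returns p = 1 with a degenerate flag.
* p-values always lie in (0, 1] and are floored at 1e-300 before log
  transforms; combining a single p returns it unchanged.
* Welch t (two-sided) flags the zero-within-variance case rather than
  emitting NaN; the 2×2 chi-square uses no continuity correction (df 1).
* Kaplan–Meier and the k-group log-rank test delegate to lifelines. At tied
  times, deaths are processed before censorings (the standard
  product-limit convention). A comparison with no events anywhere is
  degenerate with p = 1.

## Cohort conventions

Within partner-mutant patients, the target's median expression splits the
group; ties go to the low group (deterministic). The low-expression group
mimics drug inhibition of the target and is the reference everywhere: "up"
means higher in target-low patients. Differential testing runs two one-sided
rank-sum tests per feature with BH across features separately per
direction, mirroring directional up/down counts; a feature passing both
directions (possible only at very large FDR settings) is assigned to the
direction with the smaller raw p so the up/down sets partition. Expression,
methylation and accessibility matrices share this one generic operation.

Patient-level activation of an interaction requires partner mutation AND
target expression on the configured side of the cohort-wide median
(default: below). The expression side is configurable and the rule is
echoed into every survival report, since "activated pair" admits a
mutation-only reading. Burden groups: none (count 0), fewer (≤ median of
carrier counts; ties to fewer), more. Drug-target modules take the union of
partners sharing one target and tissue; CSL-style modules are split by
target expression among module-mutant patients, CSV-style modules compare
activated carriers against everyone else.

## Network analyses

"Indirect contact" in the PPI enrichment means a shortest path of exactly 2
(one shared neighbour); the maximum path length is configurable. Null
replicates draw the observed number of distinct gene pairs uniformly from
genes with ≥ 1 PPI edge, excluding self-pairs, and the empirical p carries
a +1 pseudocount so it is never 0 (floor 1/(N+1)). Degree distributions are
reported as tables; no power-law fit is attempted. The drug-pair similarity
universe is the set of partner genes appearing in the relevant network, not
the whole genome — the question asked is conditional on the map.

## What the generator emulates — and what it does not

`crgi.simulate` produces every input: screens with per-screen mutation
catalogs over a shared tissue-labelled cell-line panel, drug-response
matrices, drug→target and ATC maps, a PPI graph and pathway sets, and a
patient cohort (expression, methylation, mutations, survival, HRD/immune
scores).

Study conditions are the generator defaults: 20 CSL + 10 CSV pairs planted
at δ = 2σ viability shift, one tissue of 100 cell lines with partner
mutation rate 0.3 (≈30 mutant / 70 wild-type), three screens (one
LOW_IS_VIABLE, two HIGH_IS_VIABLE) with independent noise, drug shifts of
2σ, cohort of 200 patients with pairwise expression/methylation correlation
ρ = 0.8 on planted pairs, hazard ratio 2.5 for activated patients (CSL
protective, CSV deleterious), 20% censoring.

The hypothesis universe is a **designed 1:1 pairing**: pair *i* joins
target T*i* with partner P*i*, planted pairs first, plus 100 independent
null pairs by default. Cross-pairing every planted target with every other
mutated gene would contaminate the null hypotheses: with a shared mutation
truth, the chance imbalance of a bystander gene's mutant set against a
planted partner's mutant set persists across screens and masquerades as
consensus signal. That phenomenon is a genuine limitation of marginal
association tests on real data (see Limitations); the designed pairing
isolates the caller's operating characteristics from it. The null-universe
size (100) keeps expected chance consensus calls (~1 at the measured null
rate) small against the 30 planted pairs; large-sample null calibration is
done separately on 2,000 unplanted pairs.

Noise is Gaussian everywhere — the tests are rank-based, so the noise
family does not affect validity, and Gaussian shifts make power transparent.
Mutations are independent across genes (no mutual exclusivity), per-screen
catalogs share one truth optionally degraded by a flip rate (annotation
discordance between mutation resources), and survival is exponential with
independent censoring. Real data differ in ways the generator does not
model: lineage-specific expression programs, copy-number confounding of
dependency scores, correlated mutational processes, non-proportional
hazards. Passing tests demonstrate the pipeline's statistical behaviour
under its stated assumptions, not robustness to those real-data features.

## Determinism

Every generator derives its streams from the config seed via named
`SeedSequence` spawns, so bundles are byte-identical under a fixed config;
the permutation test takes an explicit seed; stage outputs contain no
timestamps. Rerunning any stage — or the whole pipeline — with the same
config and seed reproduces outputs byte for byte, and the stage manifests
record the config hash.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use the planted design above for
recovery (130 pairs, 100 lines, 3 screens), 2,000 null pairs at ≈15/35
lines for calibration, 400 + 100 replicates for log-rank calibration and
power, and 500 features (50 shifted) for differential recovery — sizes at
which the measured rates have usefully narrow binomial error while the full
run stays desk-scale.

## Known limitations

* Marginal per-pair testing cannot distinguish a true interaction from the
  shadow of a correlated mutation pattern (co-occurring or mutually
  exclusive mutations); the designed-pair simulations quantify error rates
  in the absence of that confounding only.
* The drug filter requires exact tissue-label agreement between screen and
  pharmacogenomic datasets (after any user-supplied mapping); no lineage
  vocabulary harmonisation is attempted.
* Exact rank-sum enumeration stops at pooled n = 12; beyond that the
  continuity-corrected normal approximation is used even for moderately
  small groups.
* Survival analysis is log-rank/KM only: no Cox modelling, covariate
  adjustment, stratification or competing risks.
* Dose–response fitting, CERES scoring, deconvolution, HRD computation and
  peak calling are out of scope; their outputs are consumed as inputs.
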