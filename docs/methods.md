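# Methods

## Subset models and pathway decomposition

The 14-assay AR battery is indexed A1..A14; a subset model is any subset of
size 2–14, named `"A"` + 14 binary digits with digit *i* marking assay A*i*
(position 1 is the leftmost character after the prefix — fixed here because
the nomenclature's worked example `A10000000001111` ↔ {A1, A11, A12, A13,
A14} pins it down). The integer mask of a model reads A1 as the most
significant bit, so enumeration in ascending mask order coincides with
lexicographic name order and is reproducible across runs. Both enumeration
conventions in circulation — 16,369 subsets of size ≥ 2 including the full
model, and 16,368 excluding it — are exposed through the `include_full`
flag rather than resolved one way.

Every model decomposes per mode by intersection with the full pathways:
agonist R1 = {A1..A11}, antagonist R2 = {A1..A6, A12..A14}. The two pathways
overlap exactly on the upstream receptor-binding / coregulator-recruitment /
nuclear-translocation block A1–A6.

## Scoring and qualification

Pathway AUC scores are binarized at a cutoff of 0.1; values **at or above**
the cutoff are active calls. Subset-model calls are tabulated against the
14-assay model's calls as reference: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), MCC with the zero-denominator case defined as 0,
balanced accuracy = (sens + spec)/2. Chemicals present in one call vector but
not the other raise an alignment error; intersection must be requested
explicitly via `align_calls`, because silently dropping chemicals changes the
counts the analysis reports.

Qualification uses strict comparison at full floating precision
(sensitivity > 0.95 and specificity > 0.85 by default): 0.952 qualifies,
0.95 exactly does not. An inclusive mode is available via
`QualificationCriteria(strict=False)`. Reported percentages are rounded
half-up (43.119… → 43.12%); internal computation always keeps full
precision.

## Battery optimization

Qualifying agonist × antagonist models are crossed in full (ordered pairs,
no deduplication — 109 × 537 = 58,533 in the motivating dataset). For each
pair the battery is the assay union; the optimizer reports the minimal union
size together with **all** pairs achieving it, sorted for presentation by
(Hamming distance asc, antagonist specificity desc, names) — ties are
reported, not broken, since distinct tied pairs are scientifically
interchangeable. Union/Hamming are computed on uint16 masks with a popcount
table so the cross product stays vectorized even when the qualifying sets
are large.

The constrained search enumerates all C(14, k) assay sets directly (≤ 3,432
at k = 7; no heuristic needed at this scale), keeps the sets hosting at least
one qualifying antagonist submodel, and maximizes the sensitivity of the best
contained agonist submodel, breaking ties by agonist specificity and then by
lexicographically smallest battery name. "Best-performing" is therefore
sensitivity-first with a specificity tiebreak — the natural reading for a
screening use case where false negatives dominate the cost — and is the one
deliberately open design choice in this module.

## Chemical clustering

Fingerprints are fixed-length binary vectors (default length 729, matching
the ToxPrint cardinality they emulate). Tanimoto distance
D = 1 − |a∧b|/|a∨b| is computed with scipy's `jaccard` metric; two all-zero
fingerprints have distance 0 (identical objects), an all-zero against a
non-empty fingerprint has distance 1. Ward linkage is applied directly to
the Tanimoto distance matrix in the D2 (squared-update) form — Tanimoto
distances are not Euclidean, so this is the standard approximation rather
than an exact minimum-variance criterion; any scipy linkage method can be
substituted via the `method` argument. The tree is cut at height 1.0 by
default; flat cluster ids are canonicalized by the smallest member id so the
partition is invariant to input order. New chemicals are assigned by
1-nearest-neighbor Tanimoto search with deterministic tie-breaking (lowest
cluster id, then lexicographic chemical id).

Cluster activity labels follow containment: a cluster is *both-effect* iff
it holds at least one agonist-positive and one antagonist-positive chemical
(possibly the same one), otherwise agonist-active / antagonist-active /
no-effect. Chemicals missing from a call vector are treated as inactive and
counted in `n_missing_calls` rather than dropped.

The volatility filter categorizes chemicals by Henry's-law constant
(atm·m³/mol) into high / moderate / slight / none and removes high and
moderate. The default cutoffs (1e−3, 1e−5, 1e−7) are **configurable
placeholders**, not regulatory values; users applying the filter to real
data must supply the cutoffs of their governing guidance. Chemicals with a
missing constant are retained and flagged.

## Multi-stage testing simulation

Scenario cost is counted in chemical-assay pairs, Σ chemicalsᵢ × assaysᵢ,
and compared as a percentage of every chemical through all 14 assays.
Overall sensitivity weights the per-mode sensitivities by active-call
prevalence (antagonist weight 0.9 by default, since ~90% of active calls are
antagonist calls).

The simulation treats the input's agonist designations as confirmed truth
and samples test outcomes at the configured rates. Defaults: stage 1 runs a
6-assay battery whose 3-assay agonist submodel has sensitivity 0.714 and
specificity 0.989; stage 2 runs 3 additional assays whose 6-assay agonist
submodel has sensitivity 0.96 and specificity 0.977; 1,000 runs. Per run:

1. Stage 1 detects round(sens₁·n_pos) true positives and
   round((1−spec₁)·n_neg) false positives, drawn without replacement
   (rounding is nearest integer, ties to even — this matters at small n and
   is therefore pinned down). A per-chemical Bernoulli mode is available.
2. The clusters containing any stage-1 positive — true *or* false — are
   selected; every chemical in a selected cluster is retested at stage-2
   rates. Within selected clusters the stage-2 call supersedes stage 1;
   outside them the stage-1 call stands (with exact-fraction sampling every
   stage-1-detected agonist's cluster is selected, so no detection is lost
   to this rule).
3. Detection sensitivity = detected true agonists / all true agonists (NaN
   when the input has no agonists); cost = stage1_size·N + stage2_size·n₂.

Antagonist detection is complete at stage 1 by design (its 5-assay submodel
already meets the criteria), so only agonist detection is simulated. Per-run
generators are spawned from the master seed (`numpy.random.SeedSequence`),
making results exactly reproducible for identical (inputs, seed, n_runs).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the chemistry or assay biology:

* **Classes**: antagonist-only / agonist-only / both / inactive at
  prevalences 0.131 / 0.009 / 0.003 (≈ 238 / 16 / 6 per 1,820 chemicals),
  drawn per chemical.
* **Hit calls**: broad actives fire each assay of their mode's pathway with
  probability 0.70; any chemical fires any assay at a false-positive rate of
  0.01. A configurable fraction of each single-mode class (0.30 antagonist,
  0.35 agonist) are *narrow* detectors firing only one signature assay
  (round-robin over A12–A14 for antagonists, A9/A11 for agonists), planting
  the indispensable-assay structure in which excluding any signature assay
  caps the mode's achievable sensitivity below the 95% criterion.
* **Surrogate AUC** = potency × (active pathway assays in the model /
  pathway assays in the model), 0 for an empty pathway. This is deliberately
  simple — downstream only consumes binarized AUCs and rankings — and is
  **not** the published network deconvolution model; it must not be used as
  a stand-in for it. Broad actives draw potency uniform on (0.2, 1.0),
  inactives below the call cutoff on (0, 0.095), so the full model
  binarizes correctly for noiseless inputs. Narrow detectors draw potency
  on (1.15, 1.45): with all evidence in a single assay their full-model
  pathway fraction is 1/11 (agonist) or 1/9 (antagonist), so potency must
  exceed 0.1 × pathway size for the full model to call them active.
* **Fingerprints**: per-cluster prototype bits (density 0.30 over 729 bits)
  XOR independent per-bit flips (ε = 0.02); 91 clusters (~20 chemicals
  each), with agonist-active chemicals confined to a designated 3% of
  clusters, mirroring the concentration of agonists in few structural
  clusters.
* **QSAR-like predictions** corrupt truth with sensitivity 0.90 and a
  false-positive rate of 0.05 — errors biased toward false positives, the
  conservative behaviour expected of a consensus QSAR overlay.
* **Henry's-law constants** are log-uniform over 10⁻⁹–10⁻¹ atm·m³/mol so
  the volatility filter always exercises all four categories.

What passing tests on this generator do show: the evaluation, qualification,
optimization, clustering and simulation machinery is correct against
independent oracles, and the workflow recovers planted structure
(indispensable assays, minimal batteries containing them, planted
partitions). What they do not show: anything about real assay noise
structure (no concentration-response curves, no correlated assay failures,
no cytotoxicity burst), real chemical similarity (bits are exchangeable and
carry no substructure semantics), or the numerical performance values of
real screening data.

## Problem sizes and numerical choices

The default end-to-end run evaluates 16,368 subset models × 1,820 chemicals
in both modes as one matrix pass (float32 AUC matrices; the confusion counts
for all models are two matrix-vector products), clusters 1,820 fingerprints
and runs the 1,000-run simulation in well under a minute on one CPU. The
20-seed planted-partition check uses 600 chemicals in 30 clusters (the same
noise geometry at ~20 chemicals per cluster) to keep the repeated
linkage runs cheap. The simulator's exhaustive-enumeration oracle uses a
20-chemical, 4-cluster instance where the stage-1 outcome space is small
enough to enumerate completely.

Degenerate inputs are handled explicitly rather than silently: empty
qualifying sets, exclusions that eliminate every model, zero-agonist
simulation inputs (sensitivity reported NaN), missing Henry's-law constants
(retained and flagged) and unclustered chemicals in the battery assignment
(flagged, given the conservative larger battery).

## Known limitations

* The surrogate AUC is a monotone pathway-activity fraction; it preserves
  binarized behaviour but not the geometry of real AUC scores, so
  continuous-AUC analyses (e.g. borderline-call studies) are out of reach.
* Ward on Tanimoto distances is an approximation (see above); for datasets
  where exactness matters, embed the fingerprints or use another linkage.
* The volatility cutoffs are placeholders (see above).
* The simulation models stage outcomes as exchangeable draws at fixed rates;
  it does not model per-chemical detectability correlation between stages.
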