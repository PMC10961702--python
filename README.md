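# arbattery

Optimal minimal in vitro assay batteries for androgen-receptor (AR)
prioritization, built from a comprehensive 14-assay pathway model.

## The problem

High-throughput screening programs need to prioritize thousands of chemicals
for potential AR agonism and antagonism, but running every chemical through a
full 14-assay pathway model is expensive. The 14 assays (indexed A1–A14)
cover receptor binding (A1–A3), coregulator recruitment (A4–A5), nuclear
translocation (A6, A12), and RNA/protein/proliferation readouts (A7–A11
agonist-specific; A13–A14 antagonist-specific). A *subset model* rebuilds the
AR model from a chosen subset, written `"A"` + 14 binary digits (digit *i* =
assay A*i*); there are 2¹⁴ − 15 = 16,369 subsets of size 2–14. Each subset
model decomposes into an agonist pathway (its assays among A1–A11) and an
antagonist pathway (its assays among A1–A6, A12–A14).

`arbattery` implements the data-processing workflow that turns the full
model's per-chemical pathway-AUC scores into minimal testing batteries:

1. **Binarize** pathway AUC scores at 0.1 (≥ 0.1 is an active call) and score
   every subset model against the 14-assay reference with
   sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), MCC and balanced
   accuracy.
2. **Qualify** subset models per mode (sensitivity > 95%, specificity > 85%,
   strict comparison), and measure per-assay prevalence and
   leave-one-assay-out maximum sensitivity to find indispensable assays.
3. **Optimize**: cross every qualifying agonist model with every qualifying
   antagonist model, compute the assay union |A ∪ B| and Hamming distance of
   each pair, and keep the pairs achieving the minimal battery size; plus
   constrained fixed-size searches and assay-exclusion variants.
4. **Cluster** chemicals by structure: Tanimoto distance
   D = 1 − |a∧b|/|a∨b| on binary fingerprints, Ward hierarchical clustering,
   tree cut at height 1, 1-NN assignment of new chemicals, cluster activity
   labels, and a Henry's-law volatility filter.
5. **Prioritize**: chemical-assay-pair cost accounting
   (Σ chemicalsᵢ × assaysᵢ), prevalence-weighted overall sensitivity
   (w·s_ant + (1−w)·s_ag), cluster-based battery assignment, and a
   Monte-Carlo simulation of the two-stage testing workflow in which stage-1
   agonist positives select structural clusters for stage-2 retesting.

A synthetic-data generator produces every input the pipeline consumes —
ground-truth chemical classes at screening-like prevalences, noisy hit calls
with planted indispensable assays, clustered fingerprints, surrogate AUC
tables, QSAR-like predictions and Henry's-law constants — so the whole
workflow runs end to end with no external data.

## Worked example

```python
import arbattery as ab
from arbattery.synthetic_data import table1_calls

agonist = ab.parse_model_name("A00101011101000")
antagonist = ab.parse_model_name("A00101000000111")
print("agonist assays:   ", sorted(agonist.assays))
print("antagonist assays:", sorted(antagonist.assays))
print("battery (union):  ", ab.union_size(agonist, antagonist), "assays")
print("hamming distance: ", ab.hamming(agonist, antagonist))

cs = ab.confusion(*table1_calls("antagonist"))
print("antagonist agreement MCC:", round(cs.mcc, 2))

from arbattery.prioritization import scenario_cost, percent_of_max
pairs = scenario_cost([4235, 988], [6, 3])
print("multi-stage cost:", pairs, "chemical-assay pairs",
      f"({percent_of_max(pairs, 4235):.0f}% of the 14-assay maximum)")
```

prints

```
agonist assays:    [3, 5, 7, 8, 9, 11]
antagonist assays: [3, 5, 12, 13, 14]
battery (union):   9 assays
hamming distance:  7
antagonist agreement MCC: 0.79
multi-stage cost: 28374 chemical-assay pairs (48% of the 14-assay maximum)
```

The 6-assay agonist model and the 5-assay antagonist model share two upstream
assays, so one 9-assay battery hosts both: testing 4,235 chemicals needs 9
assays each instead of 14. The multi-stage variant runs a 6-assay battery on
everyone and retests only the ~988 chemicals in stage-1-positive clusters
with 3 more assays, cutting the cost to 48% of the maximum.

The same analysis runs end to end on synthetic data:

```python
from arbattery.synthetic_data import generate
from arbattery.pipeline import run_full_analysis

result = run_full_analysis(generate(seed=7))
print(result.battery.union_size)            # minimal battery size
print(result.battery.pairs.head())          # all pairs achieving it
```

Or from the shell:

```bash
arbattery generate --seed 7 --out-dir data/
arbattery evaluate --hit-calls data/hit_calls.csv --chemicals data/chemicals.csv \
    --mode antagonist --out summaries_ant.csv
arbattery qualify --summaries summaries_ant.csv --out qualifying_ant.csv
arbattery cluster --fingerprints data/fingerprints.csv --out clusters.csv
```

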