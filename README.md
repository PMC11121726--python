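# readacross

Read-across classification of compound potency from molecular descriptors,
built for early drug-discovery triage: given a query molecule, the model
reports its class (**active** / **inactive** against a target such as the
nuclear receptor PPARδ), the nearest characterized training compounds that
justify the call, and whether the query lies inside the model's
applicability domain.  The target audience is cheminformaticians building
QSAR/read-across workflows who want every step — labelling, splitting,
feature selection, classification, domain estimation, validation — as
plain, inspectable library functions.

## Method

Given compounds with potency EC50 (µM) and a descriptor matrix
**X** ∈ ℝ^{n×p}:

1. **Pruning** — drop columns whose modal value covers > 80 % of rows,
   exact duplicate columns, and columns with sample variance below 20 % of
   the largest column variance.
2. **Labelling** — two-means clustering of log₁₀(EC50).  In 1-D the global
   2-means optimum is a contiguous split of the sorted values, found
   exactly by scanning all n−1 split points; the lower-centroid cluster is
   *active* (lower EC50 = more potent).
3. **Standardization** — z-score each column, (x − μ)/σ (sample σ, n−1).
4. **Split** — Kennard–Stone max–min selection of a 70 % training set:
   seed with the two most distant rows, then repeatedly add
   argmax_i min_{j∈train} ‖x_i − x_j‖.
5. **Feature selection** — best-first search with the correlation-based
   merit k·r̄_cf / √(k + k(k−1)·r̄_ff) (a kNN-wrapper CV merit is
   available).
6. **Classifier** — kNN (k = 5, Euclidean) with inverse-distance vote
   weights Σ 1/dᵢ per class; an exact match (d < 10⁻¹²) decides alone.
7. **Applicability domain** — from all pairwise training distances with
   mean m, keep d ≤ m and set APD = z·σ_kept + d̄_kept (z = 0.5).  A
   prediction is *reliable* when the query's nearest-training-neighbour
   distance ≤ APD.
8. **Validation** — accuracy, sensitivity, precision, F1, MCC, Cohen's κ
   from the test-set confusion matrix, plus Y-randomization (retrain on
   permuted labels; accuracy should collapse to chance).

## Worked example

```python
import readacross as ra

compounds, descriptors, truth = ra.generate_dataset(ra.SyntheticConfig(seed=0))
bundle = ra.train_readacross(compounds, descriptors)

print(bundle.selected_features)        # ('inf_1', 'inf_2', 'inf_3')
print(round(bundle.apd.threshold, 3))  # 1.691
print(ra.evaluate_bundle(bundle, descriptors).rounded())
# {'accuracy_pct': 92.7, 'sensitivity_pct': 95.5, 'precision_pct': 91.3,
#  'f1_pct': 93.3, 'mcc': 0.853, 'kappa': 0.852}
```

The synthetic set has 136 compounds with bimodal log-EC50 and 61
descriptor columns of which 3 carry class signal; the search recovers
exactly those 3.  The test-set accuracy of 92.7 % is measured on the 41
compounds the Kennard–Stone split held out.  Predicting one held-out
compound:

```python
pred = ra.predict_table(bundle, descriptors.loc[["C001"]])[0]
# predicted_class='inactive', neighbors=[('C044', 0.571), ('C015', 0.622), ...],
# domain_distance=0.571 <= 1.691 -> reliable=True
```

The five neighbour ids and Euclidean distances are the read-across
evidence; `reliable` compares the nearest distance with the APD
threshold.  Y-randomization on the same model
(`ra.y_randomization(bundle, descriptors, repetitions=5, seed=0)`) drops
accuracy from 92.7 % to 31.7–70.7 % across the five scramblings — the
original performance is not chance correlation.

The same pipeline is available from the shell:

```sh
readacross simulate --out-dir data --seed 7
readacross train --compounds data/compounds.csv --descriptors data/descriptors.csv \
    --out model.json --metrics-out metrics.json --seed 7
readacross predict --model model.json --input data/compounds.csv \
    --descriptors data/descriptors.csv --out report.json --compat
readacross validate --model model.json --compounds data/compounds.csv \
    --descriptors data/descriptors.csv --yrand-out yrand.csv
```

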