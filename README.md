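# codp

Pathogenicity prediction for missense variants in *MSH6*, the mismatch-repair
gene with the highest fraction of unclassified missense variants among the
Lynch-syndrome genes. Most *MSH6* missense variants found in genetic testing
have unknown clinical significance; `codp` implements CoDP (Combination of
Different Properties), a meta-predictor that folds three sequence-based
scores and two protein-structure features into a single probability that a
variant is pathogenic, together with the evidence-based carrier
classification rules and the evaluation protocol of the underlying study.

## The model

For a substitution at position *i*, five predictors X₁…X₅ feed a logistic
regression:

```
logit(q) = ln[q / (1 − q)] = Z + Σ bᵢ Xᵢ
```

| predictor | meaning | default coefficient |
|---|---|---|
| `mapp_norm` | MAPP impact score, normalized so its decision threshold is 1.0 in every domain (raw thresholds: 4.1 PCNA-binding motif, 5.0 PWWP, 4.1 MutS, 8.5 elsewhere) | +0.1581 |
| `sift` | SIFT score (low = damaging) | −1.2824 |
| `pph2_humvar` | PolyPhen-2 HumVar score | +4.6733 |
| `delta_heavy` | absolute change in side-chain heavy-atom count (volume-change proxy) | +1.0475 |
| `rel_acc` | relative solvent accessibility of the wild-type residue (Shrake–Rupley ASA over a per-residue-type maximum) | −8.0548 |

with intercept Z = −3.7273. The joint score *q* ∈ (0, 1) is read as the
probability of pathogenicity: *q* ≤ 0.56 non-pathogenic, 0.56 < *q* ≤ 0.65
moderate impact, *q* > 0.65 impaired function. MAPP, SIFT and PolyPhen-2
scores are consumed as inputs; the package computes the normalization, the
structural features, the combination, refitting, and the evaluation
statistics (confusion metrics, ROC/AUC, Youden cut-off, Wilcoxon rank-sum,
leave-one-out jackknife).

Carriers with enough clinical/molecular evidence are labelled without the
model by rule: LLS ("likely Lynch syndrome", pathogenic) via functional
assay loss, MSH6-only IHC loss with MSI-H, or segregation/family-history
criteria; ULS ("unlikely") via polymorphism frequency, normal functional
assay, or MSS with normal MSH6 staining. The packaged tables carry the 34
evidence-classified carriers (15 LLS / 19 ULS) and the 260 unclassified
variants with their published joint scores.

## Worked example

```python
import pandas as pd
from codp import default_model, msh6_domain_map, predict_variants

variants = pd.DataFrame([{
    "variant": "G566R", "position": 566, "wt": "G", "mut": "R",
    "mapp_raw": 8.2, "sift": 0.01, "pph2_humvar": 0.99,
    "rel_acc_override": 0.05,
}])
table, errors = predict_variants(variants, msh6_domain_map(), default_model())
print(table[["variant", "mapp_norm", "delta_heavy", "rel_acc", "q", "category"]])
```

prints

```
  variant  mapp_norm  delta_heavy  rel_acc         q  category
0   G566R        2.0            7     0.05  0.999706  impaired
```

G566R sits in the MutS domain (raw MAPP 8.2 / threshold 4.1 → 2.0), swaps
glycine (0 side-chain heavy atoms) for arginine (7), and is buried
(accessibility 0.05): every predictor points the same way and the joint
score calls impaired function. The `examples/` directory has one short
script per capability (UV classification, evidence rules, accessibility,
fitting/evaluation); each prints the numbers it computes and what they
mean. A `codp` command-line interface wraps the same functions
(`codp features | predict | fit | classify-evidence | evaluate | jackknife |
simulate`).

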