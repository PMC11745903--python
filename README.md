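# hypersyn

Predicting the synergy of anti-cancer drug combinations with a
dual-relationship hypergraph neural network.

High-throughput screens measure how pairs of drugs act together on cancer
cell lines, but the combinatorial space is far too large to test
exhaustively, so computational ranking of candidate combinations matters —
especially for combinations involving drugs with little or no training
data.  `hypersyn` treats synergy prediction as hyperedge prediction on a
heterogeneous hypergraph: drugs, cell lines and diseases are nodes;
synergistic (drug, drug, cell line) triplets are order-3 hyperedges; drug
indications are ordinary (drug, disease) edges.

The model:

* **drug encoder** — SMILES → heavy-atom molecular graph → multi-head
  graph-transformer layers, a'ᵢ = σ(W₁aᵢ + Σ_{j∈N(i)} α_ij W₂aⱼ) with
  scaled dot-product attention α over bonded neighbours, max-pooled into
  one vector per drug;
* **cell-line / disease encoders** — one-layer MLPs on log2-transformed,
  z-scored expression profiles and on precomputed language-model
  embeddings of indication terms;
* **refinement** — degree-normalized hypergraph convolution
  X' = X + sigmoid(C W₇ᵀ + b₇) ⊙ X with C = σ(D⁻¹HW_eE⁻¹Hᵀ X W₆), a
  gated residual whose bias starts at −5 (equilibrium bias
  initialization) so deep stacks start as near-identity maps and resist
  over-smoothing;
* **classifier** — sigmoid MLP on the concatenated refined features of
  (drug_a, drug_b, cell line), trained with cross-entropy, symmetric
  drug-pair permutation augmentation, AdamW, dropout and early stopping.
  A synergy score is positive when the continuous measurement exceeds 30.

Evaluation follows the screening protocol: 90/10 test split, 5-fold
cross-validation under five stratifications (random; unseen cell lines;
unseen drug pairs; one unseen drug; both drugs unseen) with AUROC, AUPRC
and F1.

A fully self-contained synthetic-cohort generator plants a recoverable
trilinear synergy signal, so the entire pipeline is testable at desk
scale without downloading any screening database.

## Worked example

```python
from hypersyn import SynthConfig, generate_cohort, run_cv
from hypersyn.synergy_model import desk_scale_config

cohort = generate_cohort(SynthConfig(seed=7))      # 2000 samples, 20 drugs
result = run_cv(cohort, "random", desk_scale_config(seed=7))
print([round(m.auroc, 3) for m in result.fold_metrics])
print(round(result.mean.auroc, 4), round(result.test_metrics.auroc, 4))
```

prints

```
[0.816, 0.856, 0.831, 0.828, 0.852]
0.8364 0.7905
```

— the five validation-fold AUROCs, their mean, and the AUROC on the 10%
held-out test set.  The noiseless planted signal itself reaches ≈ 0.92 on
this cohort (5% of labels are flipped by construction), so the trained
model recovers most of the recoverable ranking.  Repeating with
`strategy="drugdouble"` (both drugs of every validation pair unseen in
training) drops the mean fold AUROC to ≈ 0.65–0.70: with this generator,
drug traits are not derivable from chemistry, so leave-both-drugs-out
performance falls toward cell-line-marginal performance — the expected
stress-test ordering.

The same pipeline runs from the shell:

```sh
hypersyn simulate --seed 7 --out cohort/
hypersyn cv --synergy cohort/synergy.csv --drugs cohort/drugs.csv \
    --expr cohort/expression.csv --indications cohort/indications.csv \
    --disease-emb cohort/disease_embeddings.csv --strategy random
hypersyn train --synergy cohort/synergy.csv --drugs cohort/drugs.csv \
    --expr cohort/expression.csv --out ckpt/
hypersyn predict --checkpoint ckpt/ --triplets cohort/synergy.csv \
    --out scores.csv
```

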