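# snosite

Sequence-based prediction of cysteine **S-nitrosylation (SNO)** sites.

S-nitrosylation — the covalent attachment of a nitric-oxide moiety to a
cysteine thiol — is a widespread post-translational modification involved in
cell signaling, apoptosis and several diseases. Experimental mapping of SNO
sites is laborious, so sequence-based predictors are used to triage candidate
cysteines. `snosite` implements such a predictor end to end: feature
extraction from the sequence neighborhood of each cysteine, a discriminative
probabilistic classifier with a tuned decision threshold, and the full
evaluation protocol (Sn/Sp/Acc/MCC, repeated 10-fold cross-validation,
jackknife, protein-level calls), plus a synthetic benchmark generator so the
whole pipeline is testable without any external data.

## Method

Each cysteine at 1-based position *p* of a protein is represented by the
(2ξ+1)-mer window `R₋ξ … R₋₁ C R₊₁ … R₊ξ` (default ξ = 10, i.e. 21-mers);
positions beyond a protein terminus are filled with the dummy symbol `X`.
The 20 native amino acids are coded 1…20 in alphabetical one-letter order
and `X` is 21.

From a labeled benchmark of SNO (positive) and non-SNO (negative) windows,
two 21 × 2ξ class-conditional frequency matrices are tallied — `p⁺(i, j)`
and `p⁻(i, j)`, the occurrence frequency of residue code *i* at flank offset
*j* in each class — and contrasted into the **position-specific amino acid
propensity (PSAAP)** matrix

    Z(i, j) = p⁺(i, j) − p⁻(i, j)

(a log-odds variant `ln(p⁺/p⁻)` with add-α smoothing is available behind a
flag). A window is then encoded in pseudo-amino-acid-composition form as the
vector **Ψ** = (Ψ₁, …, Ψ₂ξ) with Ψᵤ = Z(code of the residue at the u-th
non-center position, offset u); the central cysteine is constant and
omitted.

A discriminative probabilistic scorer — by default an L2-regularized
logistic model on **Ψ**, the single-clique degenerate case of a conditional
random field; optionally a two-state chain variant — emits a score in
[0, 1], and a window is called SNO iff its score ≥ δ, where the threshold δ
is chosen to maximize overall accuracy on the training scores. A protein is
called nitrosylated iff at least one of its cysteines is called SNO.

Performance is reported as sensitivity, specificity, accuracy and Matthews
correlation coefficient, computed equivalently from per-class miscounts or
from TP/FN/TN/FP, under repeated stratified 10-fold cross-validation (the
complete pipeline — PSAAP, scorer and δ — is refit inside every fold) and
under the jackknife (leave-one-out).

## Worked example

```bash
# 1. a synthetic benchmark (strong planted motif) + independent proteins
snosite --seed 3 simulate --out-benchmark bench.tsv --out-fasta query.fasta \
        --n-pos 60 --n-neg 60 --n-proteins 5 --strength strong

# 2. train: PSAAP + logistic scorer + tuned threshold
snosite --seed 3 train --benchmark bench.tsv --out model.txt
# trained on 60+60 windows; delta=0.4029; model -> model.txt

# 3. score every cysteine of the query proteins
snosite predict --model model.txt --fasta query.fasta --out preds.tsv
# 5 proteins, 80 cysteine sites scored; 5 proteins called nitrosylated; table -> preds.tsv

# 4. cross-validated performance on the benchmark
snosite --seed 3 evaluate --benchmark bench.tsv --k 5 --repeats 2
# Predictor                  Sn(%)   Sp(%)  Acc(%)      MCC
# 5-fold CV x2 (mean)        98.33   96.67   97.50   0.9501
```

`delta` is the tuned decision threshold; the `evaluate` table reports mean
held-out sensitivity/specificity/accuracy (in %) and MCC over the repeated
folds — here the planted motif is strong, so the pipeline recovers it almost
perfectly. `preds.tsv` lists one row per cysteine: protein, site, 21-mer
window, score and SNO / non-SNO call.

The same operations are available as a library:

```python
from snosite import SyntheticSpec, generate_benchmark, train, cross_validate, CVPlan

pos, neg = generate_benchmark(SyntheticSpec(seed=3))
model = train(pos, neg)                      # PSAAP + scorer + threshold
result = cross_validate(pos + neg, CVPlan(k=10, repeats=50, seed=3))
print(result.mean)                           # MetricSet(sn=..., sp=..., acc=..., mcc=...)
```

## Layout

| module | contents |
|---|---|
| `snosite.windowing` | residue alphabet, sanitization, window extraction |
| `snosite.psaap` | frequency/propensity matrices, encoding, TSV serialization |
| `snosite.model` | scorer configs, training, scoring, threshold tuning, model archive |
| `snosite.metrics` | Sn/Sp/Acc/MCC in both parameterizations, report table |
| `snosite.evaluation` | k-fold CV, jackknife, protein-level calls |
| `snosite.io` | FASTA, benchmark TSV, predictions TSV |
| `snosite.synthetic` | benchmark/protein generators with planted motifs |
| `snosite.cli` | `snosite` command (train / predict / evaluate / build-psaap / simulate) |

See `docs/methods.md` for modeling assumptions, defaults and limitations.
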