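# mirloop

Identification of pre-miRNA precursors — the ~50–120 nt stem-loop hairpins
from which mature microRNAs are excised — against *pseudo hairpins*:
genomic segments that fold into hairpin-like shapes but are never
processed. `mirloop` is for computational biologists who want a small,
fully reproducible hairpin classifier with scikit-learn-style estimators,
a shell pipeline, and a built-in synthetic benchmark so everything runs
without downloads.

## Method

Each candidate sequence is folded (ViennaRNA MFE folding when available,
otherwise a deterministic Nussinov pair-maximization fallback) and mapped
to a fixed 98-dimensional feature vector:

* 64 overlapping trinucleotide frequencies (`AAA`…`UUU`);
* 32 triplet structure-sequence codes — after unifying brackets
  (`)` → `(`), each 3-window is coded by its first nucleotide × its
  paired/unpaired pattern (4 × 8 combinations);
* the minimum free energy (MFE) of the predicted structure;
* the number of G-U wobble pairs.

Classification is AdaBoost over back-propagation neural networks: each
weak learner is a 98–12–1 feedforward net (tanh hidden layer, linear
output; hidden size from M = round(√(N + L) + a) with N = 98, L = 1,
a = 2), trained by Levenberg–Marquardt to MSE ≤ 0.01 or 50 epochs on a
weighted bootstrap. Round *t* gets classifier weight
α_t = ½ ln((1 − ε_t)/ε_t) from its weighted error ε_t, and sample weights
are raised on misclassified records before the next round (10 rounds by
default). The strong classifier is the α-weighted vote. Species
assignment runs the same ensembles one-vs-rest. Evaluation reports
accuracy, precision, recall and specificity under stratified V-fold
cross-validation (V = 10).

## Worked example

```python
import numpy as np
from mirloop import (BoostedHairpinClassifier, SynthConfig, generate_dataset,
                     feature_frame, fold, cross_validate)

config = SynthConfig(n_pos=100, n_neg=100, seed=1)     # 50-nt records
records, manifest = generate_dataset(config)
structures = [fold(r.sequence) for r in records]
X = feature_frame(records, structures)                 # 200 x 98
y = manifest["label"].values                           # 1 real / 0 pseudo

clf = BoostedHairpinClassifier(n_rounds=10, random_state=1)
report = cross_validate(X.values, y, clf, V=10, seed=1, positive=1)
for name, value in report.mean.items():
    print(f"{name:12s} {value:.3f}")
```

prints

```
acc          0.955
precision    0.972
recall       0.940
specificity  0.970
```

i.e. on the synthetic benchmark (perfect-stem hairpins vs mononucleotide
shuffles) the boosted ensemble recovers the real/pseudo split almost
perfectly: 95.5% of held-out records are called correctly, 97.2% of
"real" calls are true hairpins, and 94.0% of true hairpins are found.
A typical real record's features look like `MFE = -21.9` kcal/mol (a
stable stem) with sparse trinucleotide frequencies; shuffled negatives
sit near `MFE ≈ -5`.

The same pipeline from the shell:

```sh
mirloop simulate --out-dir data --n-pos 400 --n-neg 400 --seed 7
mirloop extract  --fasta data/sequences.fasta --out features.csv
mirloop train    --features features.csv --labels data/labels.tsv \
                 --rounds 10 --seed 7 --out model.json
mirloop evaluate --features features.csv --labels data/labels.tsv \
                 -V 10 --seed 7 --out-dir report
```

`report/report.csv` holds per-fold and mean metrics; every artifact embeds
the tool version, seed and a config hash.

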