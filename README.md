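# virionnet

Neural-network detection of phage and virus **structural proteins** —
capsid, tail, tail fiber, baseplate, portal, tape measure, connector,
collar — from translated ORF sequences.

Structural proteins are present in essentially every virus, but their
sequences are so diverse that similarity search (BLAST, HMMs, motif
finders) misses most of them. `virionnet` sidesteps alignment entirely: a
protein is encoded as its **amino-acid percent composition** (the 20-dim
vector `100·count(a)/length`, alphabetical one-letter order) optionally
extended with its **isoelectric point** pI — the pH at which the
Henderson–Hasselbalch net charge

```
Z(pH) = Σ_basic  n_g / (1 + 10^(pH − pKa_g))  −  Σ_acidic n_g / (1 + 10^(pKa_g − pH))
```

over the titratable groups (K, R, H, N-terminus; D, E, C, Y, C-terminus)
crosses zero. Small multilayer perceptrons (tanh units throughout, one or
two hidden layers, single output trained to +1 for structural / −1 for
everything else) are trained by **Levenberg–Marquardt**,

```
Δw = (JᵀJ + μI)⁻¹ Jᵀe ,
```

with validation-based early stopping (`max_fail = 6` consecutive epochs
without improvement). K-fold cross-validation yields one network per fold;
the top-N networks by held-out accuracy **vote** by averaging their
outputs, with mean output > 0 called positive and ≤ 0 negative.
Performance is reported as accuracy, sensitivity TP/(TP+FN), specificity
TN/(TN+FP), and 99% bootstrap bands of positive-call accuracy versus the
output threshold (1000 subsamples of 80% of the true-positive pool,
trimming 0.5% per tail).

The package is aimed at phage biologists and viromics/metagenomics
analysts who have protein sequences (e.g. translated ORFs of a prophage
region or a viral contig) and want candidate structural proteins worth
experimental follow-up.

## Worked example

```bash
# 1. simulate a labeled two-class benchmark (60 proteins)
virionnet simulate --separation 0.9 --n-per-class 30 --seed 4 \
    --out-fasta bench.fasta --out-labels labels.tsv

# 2. feature extraction (add --pi for the 21-dim encoding)
virionnet featurize bench.fasta --out features.tsv

# 3. join labels onto features (any table tool works), then train
virionnet crossval labeled.tsv --hidden 3 --k 5 --seed 2 --outdir models/
#   mean held-out accuracy 0.983 over 5 folds -> models

# 4. score new sequences with the 3 most accurate networks
virionnet predict bench.fasta --models models/ --size 3 --out predictions.tsv
#   scored 60 sequences with 3 voters -> predictions.tsv

# 5. metrics against the truth labels
virionnet evaluate predictions.tsv labels.tsv --out metrics.tsv
#    n  tp  fp  tn  fn  accuracy  sensitivity  specificity
#   60  30   0  30   0       1.0          1.0          1.0
```

(Accuracy 0.983 above is held-out fold accuracy during training; the final
table scores the voting committee on all 60 sequences, 29 of which each
network saw during training — expect the committee number to be
optimistic whenever prediction targets overlap the training set.)

The prediction TSV carries one column of raw outputs per voting network,
their mean, and the >0/≤0 decision; `metrics.tsv` summarizes the confusion
counts. An output near +1 means the committee unanimously recognizes the
composition of a structural protein; values near 0 are low-confidence
calls (see the bootstrap bands from `virionnet evaluate --bands`).

Library use mirrors the CLI: `virionnet.featurize`, `build_dataset`,
`crossval_train`, `select_voters`, `ensemble_predict`, `bootstrap_bands`.

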