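# profgram

Monogram and bigram features from protein alignment profiles (HHblits `.hhm`
and PSI-BLAST ASCII PSSM files) for DNA-binding protein prediction, with
maximum-margin and ensemble classifiers and a cross-validation / jack-knife
evaluation harness.

## The problem

DNA-binding proteins (transcription factors, nucleases, repair enzymes, ...)
must often be recognized from sequence alone. A strong sequence representation
is the alignment *profile*: for a protein of length L, an L × 20 matrix H of
per-position amino-acid substitution probabilities produced by iterative
database search (HHblits for profile HMMs, PSI-BLAST for PSSMs). profgram
turns such profiles into fixed-length feature vectors and trains a binary
classifier (1 = DNA-binding, 0 = non-binding) on them.

## The representation

`.hhm` files store match-emission scores N = −1000·log₂ p, recovered as

    p = 2^(−N / 1000)          ('*' entries denote p = 0)

PSSM log-odds scores x are squashed to (0, 1) with the logistic transform
1/(1 + e^(−x)). From the resulting row matrix H, two feature families are
computed:

    monogram:  m(j)   = (1/L)     · Σ_{i=1..L}   H[i,j]               (20 features)
    bigram:    b(j,k) = (1/(L−1)) · Σ_{i=1..L−1} H[i,j] · H[i+1,k]    (400 features)

with bigram entries ordered b(1,1), b(1,2), …, b(20,20). The combined vector
is the 420-long concatenation [m; b]. Classifiers: soft-margin SVM with
linear kernel K(u,v) = u·v or RBF kernel K(u,v) = exp(−‖u−v‖²/(2σ²)), plus
Random Forest and AdaBoost comparators. Evaluation: accuracy, sensitivity,
specificity, Matthews correlation coefficient, auROC, auPR under stratified
10-fold cross-validation or the jack-knife (leave-one-out) test.

Because generating real profiles requires HHblits/PSI-BLAST and large
sequence databases, the package ships a synthetic generator that emulates
class-separated profiles and writes parser-compatible `.hhm`/PSSM fixtures,
so the whole pipeline runs and is tested without any downloads. See
`docs/methods.md` for the generative model and its limitations.

## Worked example

```
$ profgram simulate --n-pos 40 --n-neg 40 --effect 0.6 --seed 7 --out demo/profiles
INFO profgram: wrote 80 fixtures to demo/profiles

$ profgram extract --profile-dir demo/profiles --group combined \
    --labels demo/profiles/labels.tsv --out demo/features.tsv
INFO profgram: wrote 80 x 420 feature table to demo/features.tsv

$ profgram evaluate --features demo/features.tsv --labels demo/profiles/labels.tsv \
    --algo svm-linear --k 10 --seed 7 --out demo/report.json
INFO profgram: pooled accuracy 0.9750, MCC 0.9500, auROC 0.9981
```

The report JSON contains the pooled out-of-fold confusion counts and metric
bundle (here accuracy 0.975, sensitivity 0.975, specificity 0.975, MCC 0.95,
auROC 0.9981, auPR 0.9981), per-fold metrics and their means, and the
instance → fold assignment. At `--effect 0.6` the two synthetic classes
differ moderately in composition and transition structure, so a linear SVM
on combined features recovers the labels almost perfectly; `--effect 0`
produces exchangeable classes and chance-level accuracy.

`profgram train` / `profgram predict` persist and apply a model archive;
`profgram evaluate --grid --hmm-dir ... [--pssm-dir ...]` runs the full
feature-group × algorithm grid (mono / bi / combined × SVM-linear / SVM-RBF /
RF / AdaBoost) and emits one combined report. Every command writes a
manifest JSON with its resolved parameters and input hashes.

The same pipeline is available as a library:

```python
from profgram import synthetic, features, evaluate
from profgram.classify import ClassifierSpec

ds = synthetic.generate_dataset(synthetic.SyntheticConfig(seed=1), "COMBINED")
report = evaluate.kfold_cv(ds, ClassifierSpec(), k=10, seed=1)
print(report.aggregate.accuracy, report.auroc)
```

For real data, point `profgram extract` at a directory of `.hhm` files
(HHblits, e.g. four iterations against UniProt) or ASCII PSSMs (PSI-BLAST
`-out_ascii_pssm`, e.g. three iterations against nr) together with a label
TSV; running the profile generators themselves is outside this package's
scope.

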