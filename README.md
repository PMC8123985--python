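# pscpred

Protein structural class prediction (all-α / all-β / α/β / α+β) from
amino-acid sequences and predicted 3-state secondary structure, with
random-forest relative-importance (RI) feature selection and RBF-SVM
jackknife evaluation.

## What it does

1. **Feature extraction** — four named, independently switchable families:
   - `PSF` (420): overlapping k-word content frequencies over the 20-letter
     alphabet, k = 1, 2.
   - `PPF` (420): k-word position features — semi-mean over semi-variance of
     the gaps between successive occurrences of each k-word.
   - `RCF` (24): the same content/position features on the sequence reduced
     to the 3-letter hydrophobicity alphabet {I, E, A}.
   - `PSSF` (22, or 11 with the `eleven` preset): secondary-structure
     descriptors — per-element content, composition moment vectors (orders
     1–2), longest/average run lengths (raw and length-normalized), and the
     helix/strand alternation frequency.
2. **Feature selection** — features are split into `s` random subsets; for
   each subset `t` entropy/information-gain decision trees are grown on
   random 50/50 sample splits and scored on their held-out halves with the
   weighted classification rate (macro recall). A feature's RI sums
   `w_tree · IG(node) · n(node)/n(root)` over all nodes splitting on it.
   Nested prefixes of the RI ranking are then scored to pick a subset size.
3. **Classification & evaluation** — one-vs-one RBF SVM (scikit-learn),
   (C, γ) from the dyadic grid 2⁻¹⁰…2¹⁰ by stratified 10-fold CV, evaluated
   by the jackknife (leave-one-out) with per-fold standardization;
   reports a 4×4 confusion matrix, per-class accuracy/Sens/Spec/F1, and
   overall accuracy.
4. **Synthetic benchmark** — class-conditional segment grammars generate
   labeled (sequence, secondary structure, class) triples, and a
   planted-feature matrix generator supports selection experiments, so the
   entire pipeline is testable without downloads.

## CLI

```bash
# generate a synthetic labeled dataset (FASTA + SS FASTA + labels TSV)
pscpred simulate --n-per-class 50 --seed 7 --outdir data/

# extract the named feature matrix (families switchable)
pscpred extract --fasta data/proteins.fasta --ss data/proteins.ss.fasta \
    --labels data/labels.tsv --out features.csv

# RI ranking + nested subset-size sweep
pscpred select --features features.csv --labels data/labels.tsv --outdir sel/

# grid search + jackknife evaluation
pscpred evaluate --features features.csv --labels data/labels.tsv --outdir eval/

# everything in one go (flags or a YAML config)
pscpred run --simulate-n-per-class 50 --seed 7 --outdir run/
pscpred run --config config.yaml
```

Real data come in as plain text: FASTA sequences; secondary structure as a
FASTA of H/E/C strings or a directory of PSI-PRED VFORMAT `<id>.ss2` files
(`-`/`L` accepted as coil aliases); labels as a two-column TSV with
configurable class-name aliases (`a`, `b`, `a/b`, `a+b`, `alpha+beta`, …).
Running PSI-PRED itself is out of scope — its output is consumed.

## Package layout

| module | contents |
| --- | --- |
| `pscpred.io_formats` | FASTA / `.ss2` / labels readers, `ProteinRecord`, `Dataset` |
| `pscpred.seqfeat` | k-word indexing, content (SCF) and position (SPF) features |
| `pscpred.reduced` | {I,E,A} reduction map and the 24-dim reduced block |
| `pscpred.ssfeat` | secondary-structure descriptors (content, CMV, runs, alternation) |
| `pscpred.assembly` | `FeatureMatrix` (CSV round trip) and family assembly |
| `pscpred.riforest` | entropy/IG trees, weighted rate, RI scores, subset selection |
| `pscpred.svm_eval` | grid search, jackknife evaluation, metrics |
| `pscpred.simulate` | synthetic protein datasets and planted matrices |
| `pscpred.pipeline` / `pscpred.cli` | orchestration, `RunConfig`, `pscpred` CLI |
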