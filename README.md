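# profold

Protein fold classification from multi-view descriptors with per-view
classifier selection and probability averaging.

Assigning a protein to a structural fold class (a SCOP-style label) is a
multi-class classification problem that matters wherever tertiary structure
is known or predicted but not yet catalogued. `profold` represents each
protein by four complementary feature views and classifies folds with an
ensemble that picks the best base classifier *per view* instead of
concatenating everything into one matrix:

* **DSSP (40D)** — statistics of the eight-state secondary-structure string
  (states G, H, I, E, B, T, S and the blank/irregular state encoded L,
  grouped into helix / strand / turn–bend / irregular): state and group
  compositions, counts and residue coverage of continuous (length ≥ 2)
  runs, and per-group alternation frequencies.
* **AAsCPP (188D)** — amino-acid composition (20D) plus, for each of eight
  physicochemical properties (hydrophobicity, van der Waals volume,
  polarity, polarizability, charge, surface tension, secondary-structure
  propensity, solvent accessibility), a composition/transition/distribution
  (CTD) block of 3 + 3 + 15 = 21 values over the classical three-group
  amino-acid partitions: 20 + 8·21 = 188.
* **PSSM (20D)** — the column means of the L×20 log-odds profile *S*:
  component *j* is (1/L)·Σᵢ *S*ᵢⱼ.
* **FunD (binary)** — functional-domain occupancy over a fixed ordered
  domain universe: 1 where some hit to that domain has expect value
  ≤ 0.001.

Training runs a stratified 5-fold cross-validation of a classifier roster
on each view, selects the argmax-accuracy classifier per view (ties → first
roster position), and refits it on the full view. Prediction averages the
per-view class probabilities, *q*ⱼ = (1/G)·Σᵢ *P*ᵢⱼ, and returns the argmax
class. Evaluation reports the overall accuracy **Q = C/N** with per-class
accuracies *c*ᵢ/*n*ᵢ.

The toolkit parses the standard file formats these views come from (FASTA,
DSSP text output, PSI-BLAST ASCII PSSM, BLAST tabular hit tables) but does
not run the external search tools itself; a synthetic-data module generates
every input kind so the whole pipeline is testable offline.

## Worked example

```sh
python examples/train_and_evaluate.py
```

generates a five-class, four-view synthetic dataset (60 samples per class,
strong class separation), holds out a third of the samples, and prints:

```
  DSSP: selected SimpleLogistic (5-fold CV accuracy 1.000)
AAsCPP: selected SimpleLogistic (5-fold CV accuracy 1.000)
  PSSM: selected SimpleLogistic (5-fold CV accuracy 1.000)
  FunD: selected SimpleLogistic (5-fold CV accuracy 1.000)
held-out overall Q = 1.000 (100/100 correct)
```

Each line is one view's cross-validated winner and its pooled out-of-fold
accuracy; Q is the fraction of held-out samples whose averaged-probability
argmax matches the true fold. `examples/extract_descriptors.py` shows the
four extractors on one synthetic protein (40D / 188D / 20D / 500D vectors),
and `examples/cli_pipeline.sh` walks the same pipeline through the shell
interface:

```sh
profold simulate --out work --n-classes 5 --n-per-class 20 --seed 0
profold train    --feature DSSP=work/features_DSSP.tsv ... --labels work/labels.tsv --out work/bundle
profold predict  --bundle work/bundle --feature ... --out work/predictions.tsv
profold evaluate --predictions work/predictions.tsv --labels work/labels.tsv --out work/evaluation.tsv
```

`profold extract {dssp,aascpp,pssm,fund}` turns raw format files into
feature TSVs; `profold cv-report` writes the per-view roster accuracy table.

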