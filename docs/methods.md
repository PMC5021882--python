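# Methods

## Problem setting

Protein fold classification assigns a query protein to one of k structural
fold classes (27–30 in the classical benchmarks). `profold` treats the
problem as supervised multi-class classification over four feature views
extracted from different information sources: the observed secondary
structure (DSSP), the amino-acid sequence (AAsCPP), evolutionary
conservation (PSSM), and functional-domain content (FunD). The toolkit's
contribution is the descriptor definitions and the per-view
selection-and-averaging ensemble; database searches (PSI-BLAST, RPS-BLAST)
and secondary-structure assignment (the DSSP program) are upstream tools
whose outputs it parses.

## Descriptors

### DSSP view (40D)

The per-residue eight-state string uses the alphabet {G, H, I, E, B, T, S,
L}, where L encodes the blank "no structure assigned" field of a DSSP file.
States aggregate into four groups: helix {G, H, I}, strand {E, B},
turn/bend {T, S}, irregular {L}. Seven blocks are concatenated, in order:

| block | dim | definition |
|---|---|---|
| state composition | 8 | fraction of positions per state |
| group composition | 4 | fraction of positions per group |
| state run counts | 8 | number of maximal runs of length ≥ 2 per state |
| group run counts | 4 | same over the group string |
| state run coverage | 8 | fraction of positions inside such runs, per state |
| group run coverage | 4 | same over the group string |
| group alternation | 4 | per group g, the number of adjacent pairs with differing groups in which one endpoint lies in g, divided by L−1 |

The run and alternation statistics are defined here with "continuous"
meaning a maximal run of length ≥ 2; the count blocks are raw counts, the
coverage blocks are residue fractions. These are the dimension-consistent
readings of the block names (8/4/8/4/4); they are a convention of this
package, and a brute-force loop implementation in the test suite pins the
semantics.

### AAsCPP view (188D)

Amino-acid composition (20D, alphabetical residue order) followed by one
21D CTD block per physicochemical property, eight properties in a fixed
order (hydrophobicity, van der Waals volume, polarity, polarizability,
charge, surface tension, secondary-structure propensity, solvent
accessibility). Each property partitions the 20 standard residues into
three groups (the classical Dubchak-style partitions). One widely
reprinted polarity row carries a typographical duplicate ("LIFWCMVF");
this package uses the partition-consistent form LIFWCMVY. Per property:

* composition (3D): fraction of residues per group;
* transition (3D): frequency of adjacent residue pairs spanning group
  pairs (1,2), (1,3), (2,3) in either orientation, divided by L′−1;
* distribution (15D): for each group, the 1-based positions of the first
  occurrence and of occurrence number ⌈q·n_g⌉ for q ∈ {0.25, 0.5, 0.75,
  1.0}, each divided by L′; an absent group contributes five zeros.

Values are reported as fractions (not percentages). Nonstandard residue
letters (B, J, O, U, X, Z) are removed before computation; L′ is the
standard-residue count. The ceiling-index and fraction conventions are
package choices where the descriptor literature varies; they are fixed and
column-named so matrices are reproducible.

### PSSM view (20D)

From the L×20 log-odds matrix of an iterative profile search, component j
is the mean of column j. Column order follows the source file (the
standard PSI-BLAST ordering A R N D C Q E G H I L K M F P S T W Y V). Only
the log-odds block of the ASCII file is read; the weighted-percentage
block is ignored.

### FunD view (binary)

Given a fixed ordered universe of domain identifiers, the component for
domain d is 1 iff some RPS-BLAST-style hit to d has E-value ≤ 0.001. The
threshold comparison is inclusive. Hits to domains outside the universe
are ignored with a warning. The universe's size and order define the
vector basis and are persisted with any trained model.

## Ensemble

Per view: every classifier in a roster is evaluated by stratified k-fold
cross-validation (default k = 5) on identical seeded splits; the reported
accuracy is pooled over folds (total correct / total samples — identical
to fold-averaging when folds are equal). The winner is the strict argmax,
ties resolved by roster order, and is refit on the full view. Classes
smaller than k reduce the fold count to the smallest class size (never
below 2), with a warning.

Prediction averages the per-view probability rows with equal weights and
returns the argmax class, ties to the lowest class index. All views fitted
at training time must be supplied at prediction time unless the caller
explicitly opts into averaging over the subset present (divisor = number
of views present). The class ordering is the sorted label set, shared by
all per-view models; probability rows are reindexed onto it defensively.

The default roster maps ten classical algorithms to scikit-learn
estimators: gradient boosting (for logistic model trees), random forest,
RBF- and linear-kernel SVMs with Platt-calibrated probabilities, logistic
regression, extremely randomized trees (for rotation forests, which have
no scikit-learn implementation), Gaussian naive Bayes, a
random-feature-subset decision tree, histogram gradient boosting (for
functional trees) and CART. The mapping is an approximation by design —
algorithm families, not a port — and the roster is configuration-driven
(`roster_from_config`), so any estimator exposing `fit`/`predict_proba`
can replace a member. Probability normalization per member is recorded in
the model-bundle manifest.

On a published-style 5-fold CV table for the four views, strict argmax
selects RandomForest (DSSP, 51.3), RandomForest (AAsCPP, 35.4) and FT
(FunD, 44.1). The PSSM column of that table marks RotationForest (56.1)
as winner while printing LibSVM at 57.2; this package implements the
stated rule (argmax, hence LibSVM) and surfaces the full report so the
discrepancy is visible rather than emulated.

Evaluation uses overall accuracy Q = C/N with per-class counts n_i, c_i
(N = Σn_i, C = Σc_i); the evaluation table lists per-class accuracies
c_i/n_i and the overall row.

## Synthetic data

The generator produces every input kind the parsers accept, and labelled
multi-view datasets for the ensemble. File fixtures (DSSP, ASCII PSSM,
BLAST tabular) are emitted in the same dialects the parsers read, and
round-trip identity is asserted across seeds, which keeps the dialect
decisions self-consistent.

The labelled dataset places class structure directly in feature space: per
class and view a standard-normal centroid is drawn and scaled by
`separation`; samples add unit-variance Gaussian noise. Defaults are 5
classes × 60 samples, view dimensions 40/188/20/500 (the FunD dimension is
reduced from a realistic ~17k-domain universe for speed; it is
spec-controlled), separation 10 for the separable regime. Separation 0
yields chance-level accuracy; difficulty is monotone in separation.

What this does and does not show: the synthetic experiments validate the
descriptor algebra, the selection rule, the averaging machinery and the
end-to-end plumbing. They do not test whether the descriptors separate
real fold classes — the class signal is injected into feature space, not
into sequences — so benchmark-scale fold-recognition accuracy is out of
scope here and requires the external datasets and database searches.

## Numerical and interface choices

* Fixed orderings everywhere (states GHIEBTSL; residues alphabetical; CTD
  pairs (1,2),(1,3),(2,3); property order as listed) give stable,
  documented column names (`dssp.comp.H`, `aascpp.hydrophobicity.T.g1g2`,
  `pssm.mean.A`, `fund.<domain_id>`).
* Feature TSVs are written with `repr`-level float precision, so
  write→read is bit-exact.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`, scikit-learn `random_state`); with a fixed
  seed, cross-validation splits, selections and predictions are
  deterministic end to end.
* Degenerate inputs: empty sequences/strings are rejected; a length-1
  string has zero alternation; a sequence with no standard residue is an
  error; an empty hit table yields the all-zero FunD vector.
* CLI outputs embed a configuration digest as a comment line and are
  written atomically (temp file + rename), so failures leave no partial
  artifacts.

## Problem sizes used in checks

Descriptor oracle comparisons run on 1,000 random inputs of length ≤ 30;
format round-trips on 100 seeds; accuracy bookkeeping on up to 27 classes
and 300 samples; ensemble experiments on 5 classes × 60 samples with view
dimensions 40/188/20/500. These sizes exercise every code path while
keeping the default suite fast.

## Known limitations

* The DSSP parser implements the fixed-column classic dialect (structure
  summary at column 16); variant dialects (e.g. mmCIF-derived output) are
  not parsed.
* Multi-chain DSSP files default to the first chain; how multi-chain
  entries should be reduced to one sequence is a convention of this
  package, overridable per call.
* The WEKA-era algorithm roster is approximated, not reproduced; selected
  winners on real data may differ from historical reports.
* FunD vectors are as wide as the domain universe; no sparse
  representation is used, which is fine at 10³–10⁴ domains but wasteful
  beyond.
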