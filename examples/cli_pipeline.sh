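#!/usr/bin/env bash
# End-to-end shell pipeline: simulate a toy experiment, train, predict,
# evaluate. Every step is deterministic given --seed.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

profold simulate --out "$workdir" --n-classes 5 --n-per-class 20 \
    --fund-dim 100 --seed 0

features=()
for g in DSSP AAsCPP PSSM FunD; do
    features+=(--feature "$g=$workdir/features_$g.tsv")
done

profold train "${features[@]}" --labels "$workdir/labels.tsv" \
    --out "$workdir/bundle" --roster fast --k-folds 5 --seed 0

profold predict --bundle "$workdir/bundle" "${features[@]}" \
    --out "$workdir/predictions.tsv"

profold evaluate --predictions "$workdir/predictions.tsv" \
    --labels "$workdir/labels.tsv" --out "$workdir/evaluation.tsv"

# The evaluation TSV lists per-fold-class accuracies c_i/n_i and an
# "overall" row with Q = C/N.
tail -3 "$workdir/evaluation.tsv"
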