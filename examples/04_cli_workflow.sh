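#!/usr/bin/env bash
# Shell workflow: simulate -> gridsearch -> predict -> evaluate.
# Every stage reads/writes plain files, so each step can be inspected.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

# 1. synthetic 22-channel session (montage written alongside the trials)
srmdrm simulate --channels 22 --rate 250 --trials-per-class 40 \
    --ratio 4 --noise 0.2 --seed 3 \
    --out "$workdir/trials.npz" --montage-out "$workdir/montage.txt"

# 2. select (alpha, r) by training-set CV, fit, and save the model
srmdrm gridsearch --train "$workdir/trials.npz" --montage "$workdir/montage.txt" \
    --alpha-grid 1e-4,1e-3,1e-2 --r-grid 0.05,0.1 --seed 3 \
    --model-out "$workdir/model.pkl" --cv-table-out "$workdir/cv.csv"

# 3. per-trial predictions with distances to each class mean
srmdrm predict --model "$workdir/model.pkl" --test "$workdir/trials.npz" \
    --out "$workdir/predictions.csv"

# 4. score against the labels stored in the container
srmdrm evaluate --predictions "$workdir/predictions.csv" \
    --truth "$workdir/trials.npz"

# reference methods on the same data
srmdrm baselines --train "$workdir/trials.npz" --test "$workdir/trials.npz"
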