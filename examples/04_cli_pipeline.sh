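#!/usr/bin/env bash
# The same pipeline from the shell: simulate -> train -> analyze.
set -euo pipefail

WORK=scratch/cli_demo
mkdir -p "$WORK"

cat > "$WORK/scene.yaml" <<EOF
duration_s: 30.0
ssi_mean_s: 1.5
ssi_sd_s: 0.8
EOF

# 8 synthetic recordings with ground-truth label tracks
gutsound simulate --config "$WORK/scene.yaml" --out "$WORK/data" --seed 1 --n-scenes 8

# train the CNN on the wav/label pairs
gutsound train --data "$WORK/data" --out "$WORK/cnn.npz" --iterations 1000 --seed 0

# one-shot analysis of a recording: predicted labels + motility CSV +
# manifest; --truth additionally prints the four frame metrics
gutsound analyze "$WORK/data/scene000.wav" \
    --model "$WORK/cnn.npz" --out "$WORK/analysis" \
    --truth "$WORK/data/scene000.txt"

ls "$WORK/analysis"
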