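#!/usr/bin/env bash
# File-based workflow: simulate a study, inspect region filters, screen it,
# and re-test the top gene with a permutation check.
set -euo pipefail

WORK=$(mktemp -d)
trap 'rm -rf "$WORK"' EXIT

wustat simulate --out "$WORK/study" --seed 42 --n 142 --n-genes 30 \
    --n-causal 2 --snvs-per-gene 50,150

ARGS=(--vcf "$WORK/study/genotypes.vcf"
      --annotation "$WORK/study/annotation.bed"
      --probe-map "$WORK/study/probe_map.tsv"
      --expression "$WORK/study/expression.tsv"
      --phenotype "$WORK/study/phenotype_quant.csv")

wustat regions "${ARGS[@]}" --out "$WORK/region_report.tsv"

wustat screen "${ARGS[@]}" --seed 42 \
    --out "$WORK/results.tsv" --qq-out "$WORK/qq.tsv"

echo "--- results header and top rows ---"
head -4 "$WORK/results.tsv"

wustat test-gene "${ARGS[@]}" --gene GENE0000 --mode GT --permute 2000 --seed 42
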