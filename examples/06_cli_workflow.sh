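#!/bin/sh
# Shell workflow: generate deformed phantom pairs, register one, warp the
# floating mask through the result and score the overlap.
set -e

inspire synth phantom --size 128 --n 1 --seed 0 --out-dir scratch/pairs

inspire register \
    --ref scratch/pairs/pair00_ref.tiff \
    --flo scratch/pairs/pair00_flo.tiff \
    --schedule phantom --seed 1 --out-dir scratch/reg

inspire transform \
    --transform scratch/reg/transform_ref_to_flo.json \
    --in scratch/pairs/pair00_ref_mask.tiff \
    --out scratch/reg/warped_ref_mask.tiff --nearest

inspire eval --metric jaccard \
    --pred scratch/reg/warped_ref_mask.tiff \
    --truth scratch/pairs/pair00_flo_mask.tiff
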