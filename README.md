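# obstruseg

Block-based grayscale image segmentation with a genetic-algorithm-initialised
back-propagation neural network (BPNN), max-flow/min-cut graph-cut refinement,
and classical threshold / edge-detection baselines — exercised end to end on a
built-in generator of synthetic "ileus phantom" images (dilated bowel-loop
ellipses with air-fluid interfaces and soft-tissue lesions, plus paired
ground-truth masks).

## How it works

1. **phantoms** — four morphology archetypes rendered as 2-D intensity
   rasters with 3-label ground truth (0 background, 1 lumen, 2 lesion),
   additive Gaussian noise; fully deterministic per `(spec, seed)`.
2. **images** — PNG/TIFF/NIfTI I/O, overlapping-block extraction (stride
   grid + edge-flush blocks so every pixel is covered), and probability-
   averaging reassembly of per-block class scores into a label map.
3. **features** — 6 texture/intensity features per block (mean, variance,
   histogram entropy, gradient energy, co-occurrence contrast/homogeneity).
4. **bpnn** — three-layer sigmoid network trained by online back-propagation
   on squared error, with error-goal / max-epoch stopping.
5. **gmm** — n-branch Gaussian mixture: density, EM fitting, sampling.
6. **ga** — real-valued GA with linear-ranking ("sorting") selection,
   fitness grouping, and a GMM offspring channel fitted to the elite groups;
   the best chromosome decodes into the BPNN's initial weights/thresholds.
7. **graphcut** — per-pixel class probabilities + image intensities mapped
   to a source/sink flow network; exact min-cut (integer-scaled
   `scipy.sparse.csgraph.maximum_flow`) smooths the segmentation.
8. **baselines** — Otsu / fixed thresholding and Canny-style edge
   detection with contour filling.
9. **evaluate / pipeline** — Dice/IoU/accuracy/confusion metrics,
   per-category recognition rates, hidden-layer-size cross-validation, and
   the block-size/overlap-step sweep (wall times reported, never asserted).

## CLI

```bash
obstruseg phantom --n 10 --size 96 --noise 0.05 --seed 17 --out data/
obstruseg blocks data/phantom_000_class0.png --block 32 --step 16
obstruseg train --n 5 --seed 17 --out model.json
obstruseg segment data/phantom_000_class0.png --method bpnn --model model.json --out mask.png
obstruseg segment data/phantom_000_class0.png --method threshold --out otsu.png
obstruseg eval mask.png data/phantom_000_class0_truth.png
obstruseg sweep-hl --hidden 2,3,4,5,6,7,8 --k-folds 3 --out hl.csv
obstruseg sweep-blocks --blocks 32,48 --steps 8,16 --out blocks.csv
```

Defaults live in `src/obstruseg/config.py` and can be overridden with
`obstruseg --config my.yaml ...`.

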