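# histotract

Quantitative analysis of cell migration in 2-D brain histology:

- **structure-tensor orientation/coherence mapping** of a myelin-stain
  channel (cubic-spline gradients, Gaussian-windowed tensor, closed-form
  2×2 eigendecomposition; coherence `C = (λmax − λmin)/(λmax + λmin)`),
- **NSC cluster geometry**: intensity-threshold detection, morphological
  coalescing (dilate/erode with Euclidean disks, defaults 200/100 px),
  circularity filtering (4πA/P², regions > 0.7 excluded), second-degree
  polynomial fits in the principal frame and per-cluster tangent angles
  θ_NSC,
- **spatial statistics**: cluster-size-weighted distances from an
  injection site (1000-px exclusion radius, default scale 1.444 µm/px so
  1000 px = 1444 µm), weighted cumulative probability distributions with
  medians, % of signal in white matter, exact distances to the WM/GM
  interface,
- **orientation regression**: θ_NSC against local θ_WM, weighted by
  coalesced-region cluster counts, reported for all/WM/GM subsets,
- **stochastic migration simulation**: orientation-axis-following steps
  in white matter (5-px-σ tensor field, sign persistence), uniform
  random turning in grey matter, truncation on self-intersection,
- **synthetic phantoms** with full ground truth (curved textured tracts,
  WM/GM masks, planted elongated clusters with controllable tract
  alignment) used to validate every stage end-to-end.

Angles are degrees, axial on [0, 180), measured from the positive x
axis; images are indexed `[y, x]` with the origin top-left and y
downward. Distances are reported in µm.

## CLI

One executable with one subcommand per stage:

```bash
histotract synth --size 384 384 --tract arc --n-clusters 14 --alignment 1.0 \
    --seed 0 --out phantom/
histotract orientation phantom/dii.tif --sigma 1 --out maps/
histotract clusters phantom/nsc.tif --dilate 200 --erode 100 \
    --circularity-max 0.7 --out clusters.csv
histotract distances clusters.csv --injection-x 60 --injection-y 192 \
    --exclusion-radius-px 1000 --pixel-scale-um 1.444 --out distances.json
histotract correlate --out run/          # regression slope / r² JSON
histotract simulate --n-paths 500 --kernel-sigma 5 --out run/
histotract run --config config.yaml --out run/   # full pipeline + manifest
```

`run` executes synth → orientation → clusters → distances → correlate →
simulate and writes a `manifest.json` with a SHA-256 per artifact; a
fixed config reproduces every output byte. Configs are YAML key-value
files; unknown keys are rejected, missing keys take the method defaults.

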