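# mammopipe

A tested library and CLI for mammogram contrast enhancement and its
evaluation. The pipeline runs five stages in a fixed order:

1. **Channel handling** (`mammopipe.imgio`) — images are read as three
   aligned planes on the 0–255 scale (grayscale inputs are replicated).
2. **Background uniformity** (`mammopipe.background`) — morphological
   bottom-hat/top-hat transforms recombined as `f + top_hat − bottom_hat`,
   rescaled to [0, 255], applied per channel.
3. **PCA gray fusion** (`mammopipe.gray_pca`) — the channels are moved to
   full-range BT.601 YCbCr, the 3×3 pixel covariance is eigendecomposed,
   and per-pixel projections are combined with eigenvalue-proportional
   weights.
4. **Pectoral-muscle removal** (`mammopipe.pectoral`) — orientation-aware
   seeded region growing from the top chest-wall corner (MLO views only),
   with masked pixels zeroed.
5. **Coherence** (`mammopipe.coherence`) — Laplacian-of-Gaussian
   normalization followed by coherence-enhancing anisotropic diffusion
   (structure-tensor driven, explicit scheme, entropy-based stopping).

Supporting modules:

- `mammopipe.metrics` — MSE/PSNR (two variants: the source convention
  `10·log10((L−1)/MSE)` with `L = 2⁸ − 1 = 255`, and the standard
  `10·log10(L²/MSE)`), log-contrast `10·log10(var)`, and block-based EME,
  plus CSV report assembly.
- `mammopipe.segment` — 1-D intensity k-means (deterministic quantile
  initialization) and specificity/sensitivity/accuracy mask evaluation.
- `mammopipe.baselines` — HE, CLAHE, and BBHE comparator enhancers.
- `mammopipe.phantom` — synthetic CC/MLO mammogram phantoms (half-ellipse
  breast, right-triangle pectoral wedge, Gaussian lesions, illumination
  ramp, per-channel noise) with ground-truth masks, so the whole pipeline
  is exercisable without clinical data.
- `mammopipe.pipeline` / `mammopipe.cli` — orchestration, batch
  processing, per-stage artifacts, manifest, and the `mammopipe` CLI.

## CLI

```sh
# generate a synthetic phantom bundle with ground-truth masks
mammopipe phantom --out ph --view MLO --noise-sigma 4 --seed 1

# run the full pipeline (writes per-stage artifacts + metrics.csv + manifest)
mammopipe enhance ph/degraded_green.png --out enhanced --view MLO

# k-means label maps for k = 2, 4, 6, 8, with optional evaluation
mammopipe segment enhanced/degraded_green__final.png --out seg \
    --truth-mask ph/lesion_mask.png

# metrics for an (original, enhanced) pair
mammopipe metrics ph/degraded_green.png enhanced/degraded_green__final.png

# benchmark against HE / CLAHE / BBHE on degraded phantoms
mammopipe bench --n-phantoms 20 --out bench.csv
```

Useful `enhance` flags: `--skip-pectoral`, `--skip-log`,
`--skip-diffusion`, `--se-shape {disk,square}`, `--se-radius`,
`--gray-method {pca,green-channel}`, `--tolerance`, `--max-region-fraction`,
`--dt`, `--alpha`, `--max-iters`, `--entropy-tol`, `--config FILE`
(plain-text `key=value`, flags override).

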