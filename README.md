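# ramanpc

Convert point-scan Raman spectra of cells into super-resolved pseudo-color
images. The pipeline extracts a band-limited peak-intensity grayscale image
from the spectra, enhances it (iterative ratio-reset Retinex + median
filter), super-resolves it with a three-layer convolutional network
alternated with bicubic upscaling until the image reaches 320 px, smooths it
with a self-guided filter whose window size and regularization come from a
fitted linear model in scan statistics, maps it through a Jet lookup, and
scores results with PSNR, information entropy, and CIELAB KL-divergence
sharpness.

## Input format

Plain-text TSV (or CSV): row 1 is the wavenumber axis in cm⁻¹ (strictly
increasing, typically 1024 channels over 155–3926); every following row is
one spectrum. Spectra are ordered row-major over the scan grid with repeated
scans of a point on consecutive rows. Grid shape and repeat count are passed
on the command line, not embedded in the file.

## CLI

```sh
# synthetic scene with ground-truth mask (TSV + mask PNG + spec JSON)
raman-pc phantom --grid 20x20 --repeats 2 --seed 0 --out scan.tsv

# full pipeline: 20x20 scan -> 320x320 pseudo-color PNG
raman-pc run --input scan.tsv --grid 20x20 --repeats 2 \
    --band 2750:3050 --out cell.png --debug-stages stages/

# quality metrics
raman-pc metrics --psnr a.png b.png --entropy a.png --kl a.png b.png

# refit the adaptive guided-filter model from a TSV of
# (N1, N2, sigma2, omega, eps) observations
raman-pc fit-adaptive --table fit.tsv --out coef.json

# retrain the super-resolution network (writes .json or .npz weights)
raman-pc train --seed 0 --epochs 40 --out weights.json
```

Useful `run` flags: `--no-srcnn` (bicubic-only ablation), `--skip-retinex`,
`--nsym {0,4,8,12}` (symmetric peak-neighbor averaging), `--filter-rgb`
(guided-filter the color channels after the Jet mapping instead of the
grayscale image before it), `--adaptive-coef FILE` (override the built-in
coefficient matrix), `--var-threshold`, `--sigma2-mode`.

## Library layout

| module | contents |
| --- | --- |
| `ramanpc.spectra_io` | TSV/CSV scan reading/writing, geometry validation, repeat averaging |
| `ramanpc.peak_image` | band-peak grayscale extraction, normalization, band-variance maps |
| `ramanpc.enhance` | ratio-reset Retinex, median filter, minimum-size bilinear resize |
| `ramanpc.srcnn` | three-layer CNN: forward, bicubic+network super-resolution loop, training, weight I/O |
| `ramanpc.adaptive_guided` | self-guided filter, adaptive (window, eps) model, least-squares fitting |
| `ramanpc.colorize` | Jet pseudo-color lookup |
| `ramanpc.metrics` | PSNR, gray/color entropy, CIELAB KL sharpness |
| `ramanpc.phantom` | synthetic Raman scene generator with ground truth |
| `ramanpc.pipeline` | end-to-end orchestration, stage artifacts, PNG output |

Packaged data: `ramanpc/data/default_weights.json` (reproduce with
`python scripts/train_default_weights.py`) and `ramanpc/data/jet_lut.csv`
(256-entry lookup fixture).

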