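# lspost

Post-processing toolkit for light-sheet (ultramicroscopy) stacks of cleared
tissue. It implements the per-plane enhancement chain used on large
monochrome autofluorescence recordings:

1. **CLAHE** — contrast-limited adaptive histogram equalization tuned for
   16-bit input (bin count defaults to the full 65,536 grey levels),
2. **destripe** — suppression of directional stripe artefacts by a
   pie-slice (wedge) mask in the centred 2D Fourier spectrum, with
   Gaussian-smoothed edges and automatic stripe-angle estimation,
3. **unsharp** — unsharp masking for final sharpness,

plus intensity-threshold segmentation and brightness-to-colour mapping for
highlighting structures in the monochrome volumes, a synthetic phantom
generator (bright tubular vessels, dark nuclei, multiplicative occluder
shadows at a known angle, noise, full ground-truth masks), and small
protocol calculators for the associated clearing-chemistry arithmetic
(DMP/water stoichiometry, section undersampling, volume shrinkage).

Stacks are multi-page grayscale TIFFs (uint8/uint16) or directories of
numbered single-page TIFF slices; runs are described by a YAML config.

## CLI

```sh
# generate a synthetic striped stack with ground-truth masks
lspost phantom --output scratch/ph.tif --seed 7 --planes 8 --size 256 --angle 25

# estimate the stripe angle from the power spectra
lspost estimate-angle --input scratch/ph.tif

# run the enhancement chain
cat > scratch/config.yaml <<EOF
schema_version: 1
stages:
  - name: clahe
  - name: destripe
    alpha: auto
    d1: 2
    w1: 8
    w2: 60
  - name: unsharp
input: scratch/ph.tif
output: scratch/out.tif
EOF
lspost run --config scratch/config.yaml

# protocol calculators
lspost calc dmp --water-mass 1.0
lspost calc undersampling --block-um 3000 --section-um 5
lspost calc shrinkage volumes.csv     # columns: id,treatment,pre,post
```

A JSON run report (per-plane stripe-band energy before/after destriping,
effective config, checksums) is written beside the output stack.

Stage order is fixed to `clahe -> destripe -> unsharp -> segment ->
colormap`; configs may select a subset but not permute it.

## Library

```python
from lspost import (
    PhantomSpec, generate_phantom, PieFilterSpec, destripe_plane,
    estimate_stripe_angle, ClaheParams, equalize_clahe,
)

stack, truth = generate_phantom(PhantomSpec(shape=(16, 256, 256),
                                            occluders_per_plane=20, seed=7))
alpha = estimate_stripe_angle(list(stack.planes)).angle_deg
clean = destripe_plane(stack.planes[0],
                       PieFilterSpec(alpha_deg=alpha, d1=2, w1=8, w2=60))
```

Angle conventions: the stripe angle `alpha` is measured from the horizontal
image edge (counter-clockwise as displayed, y down, stored modulo 180); the
corresponding wedge axis lies at `90 - alpha` degrees in the centred power
spectrum.
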