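# afmstripes

Gabor-bank stripe segmentation, single-molecule morphometry and
bead-aggregation quantification for high-speed AFM (HS-AFM) height images
of elongated biomolecules such as cadherin ectodomains.

## The problem

HS-AFM height movies of cadherin ectodomains adsorbed on mica show
elongated molecules built from a **strand-like portion** (tandem EC
repeats, apparent stripe width ~6–9 nm, height ≤ ~3.5 nm), optional
compact **knot-like structures**, and a taller membrane-proximal
**globule** (height > ~5 nm). Quantifying these molecules requires:

1. segmenting the striped (strand) texture from knots and bends,
2. measuring per-molecule geometry (area, Feret-type length, ellipse
   axes, height profiles, volume fractions),
3. classifying molecule morphologies into three classes
   (1: two terminal knots joined by a straight linker; 2: two terminal
   knots joined by a bent/kinked linker; 3: everything else), and
4. quantifying the companion bead-aggregation adhesion assay
   (aggregate areas binned into five size ranges).

Because no public AFM image set accompanies this workflow, every stage is
driven and validated by a **ground-truthed phantom generator**
(`afmstripes.synthetic`): worm-like molecule height maps with scripted
knots, bends and globules, and bead fields with aggregates of controlled
area.

## The core method

Stripe texture is scored with a bank of 12 Gabor kernels
(θ = 0°, 15°, …, 165°),

```
g(x, y) = exp(−(x′² + γ² y′²) / (2σ²)) · cos(2π x′/λ + ψ)
x′ =  x cos θ + y sin θ
y′ = −x sin θ + y cos θ
```

with λ = 20, ψ = 0, σ = 2, γ = 0.4 sampled on a 12 × 12 half-integer
grid (which preserves exact point symmetry). Each kernel is
cross-correlated with the **binarized** height image; the kernel mean is
subtracted at application time so that wide uniform regions score zero,
which makes the bank a genuine width-tuned stripe detector: at the
parameters above the optimal stripe width is 4–6 px, matching the EC
repeat's apparent width at 1.5 nm/pixel. The 12 outputs are combined
pixelwise (default: maximum) into a stripe score `G`, and merged with the
normalized height image into a two-channel pseudo-color overlay in which
knot/bend regions are bright in the height channel but dark in the
stripe channel.

Morphometry follows ImageJ conventions: 8-connected components,
systematic selection of objects with area within mean ± 1 s.d.,
maximum point-pair distance as the length metric (exact, via convex
hull), moment-matched ellipse axes ("Fit Ellipse"), skeleton-backbone
height profiles, and overlap-based frame-to-frame tracking.

## Worked example

```python
from afmstripes import (GaborParams, build_bank, apply_bank, binarize, denoise,
                        subtract_background, normalize_height, merge_overlay,
                        label_objects, max_height, stripe_width_tuning)
from afmstripes.synthetic import make_class_phantom
from afmstripes.morphometry import backbone_height_profile
from afmstripes.classify import extract_features, classify_morphology

# a bent two-knot molecule phantom with 0.2 nm scan noise
hm, truth = make_class_phantom(class_id=2, seed=7, noise_sd_nm=0.2)

smooth = subtract_background(denoise(hm, median_size=3, mean_size=3))
sharp = subtract_background(denoise(hm, median_size=3, mean_size=1))
mask = binarize(smooth)                       # Otsu by default
score = apply_bank(mask, build_bank(GaborParams()))
overlay = merge_overlay(normalize_height(smooth), score)

mol = label_objects(mask, min_area_px=20)[0]
profile = backbone_height_profile(mol, sharp)
feats = extract_features(mol, overlay, profile, height_map=sharp.values)
cls = classify_morphology(feats)
print(f"scripted: class {truth.class_id}, bend {truth.linker_bend_deg:.1f} deg")
print(f"measured: area {mol.area_nm2:.0f} nm^2, length {mol.length_nm:.1f} nm, "
      f"max height {max_height(mol, sharp):.2f} nm")
print(f"features: {feats.terminal_knot_count} terminal knots, "
      f"bend {feats.linker_bend_deg:.1f} deg -> class {cls}")

table = stripe_width_tuning(GaborParams(), list(range(1, 13)))
best = int(table.loc[table['mean_response'].idxmax(), 'width_px'])
print(f"optimal stripe width: {best} px")
```

prints

```
scripted: class 2, bend 103.2 deg
measured: area 1017 nm^2, length 67.2 nm, max height 4.16 nm
features: 2 terminal knots, bend 103.2 deg -> class 2
optimal stripe width: 4 px
```

The molecule's measured area (1017 nm² ≈ 452 px at 1.5 nm/px), its
Feret-type length (67.2 nm, shortened from the 80–90 nm contour by the
103° kink), the knot peak height (4.16 nm, above the ~3.5 nm strand
ceiling) and the recovered bend angle together reproduce the scripted
class-2 morphology; the tuning table confirms the bank is matched to
4-px-wide stripes.

A command-line interface mirrors the library:

```bash
afmstripes synth --class-id 1 --n 5 --out phantoms/
afmstripes segment --input mol.tiff --pixel-size 1.5 --out overlay.png
afmstripes measure --input mol.tiff --pixel-size 1.5 --out records.csv
afmstripes beads --input well.png --edges 2,50,200,800,3200 --out report.csv
afmstripes run-all --config run.yaml
```

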