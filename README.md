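# kflbpcm

Filtered multi-scale local binary patterns fused with contour-mask
features — **k-FLBPCM** — for telling apart plant species that share
color and general shape, such as a broadleaf crop and a broadleaf weed
photographed on soil.  Intended for researchers and engineers in
machine-vision weed detection who need a fast, trainable-on-little-data
alternative to CNNs, and for anyone studying texture + shape feature
fusion.

## The method

For an RGB plant image the pipeline computes two branches:

* **pass_features** — rotation-invariant uniform LBP codes
  (`riu2`, operators (P, R) ∈ {(8, 1), (16, 2), (24, 3)}) of the raw
  grayscale image, histogrammed per operator;
* **cmask_features** — the image is smoothed by 5×5 morphological
  opening + closing, segmented with the excess-green minus excess-red
  index (vegetation ⇔ ExG − ExR > 0, ExG = 2g − r − b, ExR = 1.4r − g on
  chromatic coordinates), and a contour band of thickness *t* (default 2,
  `veg ∧ ¬erode^t(veg)`) is traced along the plant boundary; the same LBP
  operators then run on the band raster, encoding leaf-margin morphology.

Each histogram has its dominant bin zeroed ("filtered" LBP) and is
L1-normalized; the branches are fused elementwise as

```
combined = k · pass_features + cmask_features        (default k = 0.2)
```

and classified by an RBF-kernel SVM (one-vs-one) under stratified 5-fold
cross-validation, with grid search over (C, γ, k, thickness).  Because
margin style is a scale-stable species property, the fused features keep
working when the classifier is trained on mature plants and applied to
small early-stage plants — the regime where whole-image descriptors and
small-data CNNs fail.

A parametric scene generator ships with the package: soil background plus
green plants whose species differ in leaf margin (smooth-lobed,
deeply-serrated, grass blade) and venation texture but deliberately share
hue and leaf area, rendered across growth stages, rotations and
illumination levels.  It makes every experiment reproducible without any
dataset download.

## Worked example

```python
from kflbpcm import cross_validate, stage_transfer
from kflbpcm.synth import background_spec, default_species, generate_dataset

specs = [background_spec(), *default_species().values()]
_, images = generate_dataset(specs, n_per_class=30, stages=(2, 3, 4), seed=42)

result = cross_validate(images, n_folds=5, seed=42)
print("fold accuracies:", [round(a, 3) for a in result.fold_accuracies])
print("mean accuracy:  ", round(result.mean_accuracy, 4))
print(result.confusion_table())
```

prints

```
fold accuracies: [0.958, 1.0, 0.958, 1.0, 0.958]
mean accuracy:   0.975
             background  barley_like  canola_like  radish_like
background           30            0            0            0
barley_like           0           28            1            1
canola_like           0            0           30            0
radish_like           0            1            0           29
```

i.e. 97.5 % mean accuracy over 120 images of four classes; the only
confusions are between the grass and the two broadleaf species, never
with the soil background.  The growth-stage transfer experiment trains
on large stage-4 plants only and tests on small stage-2 plants:

```python
species = default_species()
pair = [species["canola_like"], species["radish_like"]]
_, train = generate_dataset(pair, n_per_class=60, stages=(4,), seed=42)
_, test = generate_dataset(pair, n_per_class=30, stages=(2,), seed=43)

result = stage_transfer(train + test, train_stages=[4], test_stages=[2], seed=42)
print("stage 4 -> 2 accuracy:", round(result.accuracy, 4))

control = stage_transfer(train + test, train_stages=[4], test_stages=[2],
                         seed=42, feature_kind="mean_rgb")
print("color-only control:", round(control.accuracy, 4))
```

prints

```
stage 4 -> 2 accuracy: 0.9833
color-only control: 0.5
```

— contour-fused features transfer across a >2× scale change (98.3 %),
while a color-only classifier on the same split is at chance, confirming
that hue carries no class signal in these scenes.

## Command line

The same experiments are available as subcommands:

```
kflbpcm simulate --out data/ --n-per-class 50 --seed 0
kflbpcm extract --data data/ --out features.csv
kflbpcm cv --data data/ --out results/ --seed 0
kflbpcm gridsearch --data data/ --out results/ --C-grid 10,30,100
kflbpcm stage-transfer --data data/ --train-stages 4 --test-stages 2 --out t.json
kflbpcm benchmark-time --data data/ --limit 50
```

Inputs are an image directory with a `manifest.csv` (path, label, stage),
so user-supplied datasets plug in the same way.  A YAML `--config` file
can hold any defaults; CLI flags override it.  Exit codes: 0 success,
2 configuration error, 3 data error.

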