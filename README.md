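# podfusion

Grading the freshness of vegetable-soybean (edamame) pods from paired RGB
photographs and hyperspectral reflectance, by fusing the two modalities into
one tensor and classifying it with a small residual network.

## The problem

Vegetable soybean is harvested immature and degrades within days: pods
yellow, brown spots spread, and soluble sugars collapse (e.g. from 12.64% to
7.22% between storage days 1 and 3 — a 42.88% decrease). Storage day
(Day1/Day3/Day5/Day7) is therefore used as a 4-level freshness label.
Neither data source suffices alone: early chemical change (Day1 vs Day3) is
visible to spectroscopy but not to the eye, while late visual change
(Day5 vs Day7) shows in photographs but not in composition. This package
implements the full fusion pipeline:

1. **Spectral preprocessing** — ROI-mean spectra (462 bands, 386–1004 nm),
   multiplicative scatter correction against the dataset-mean "ideal
   spectrum" (per-sample OLS; correct by `(x − a)/b`), min–max
   normalization, first derivatives.
2. **RGB preprocessing** — ROI crop, exact area-average downsampling to
   22×21×3, CIELAB green-intensity hue `H = atan2(b*, a*)`.
3. **Fusion** — reshape the 462-band spectrum row-major into a 22×21 plane
   and concatenate as a fourth channel: `22·21·4 = 22·21·3 + 462` (1848
   elements).
4. **Classifier** — a residual network with a conv1 stem (4→64, kernel 3)
   and 8 residual/downsampling modules computing `relu(h(x) + F(x, w))`,
   global average pooling, and a 4-class linear head, trained with Adam on
   cross-entropy over a stratified 70/30 split (416 samples → 125 test).
   Implemented as a self-contained NumPy CNN engine with hand-written
   backward passes.
5. **Baselines** — decision tree, random forest, AdaBoost, KNN on flattened
   features of either source or the fusion.
6. **Band selection** — per-band distance correlation against the label,
   `dCor(X,Y) = dCov(X,Y)/√(dVar(X)·dVar(Y))`, keep bands scoring > 0.7,
   zero the rest (ablation).
7. **Evaluation** — 4×4 confusion matrices; accuracy, macro
   precision/recall/F1; Wilson score intervals for test accuracy.

A synthetic pod generator (`podfusion.synthetic`) emulates the statistical
structure of the real data — reflectance peak near 562 nm, trough near
688 nm, class signal concentrated in known wavelength windows with the
strongest components near 670 and 980 nm, per-sample multiplicative/additive
scatter, pods that yellow and develop brown spots with storage — and records
its ground truth, so every stage is testable without the original imagery.

## Worked example

Build a complementary-information dataset (spectra separate Day1/Day3 but
not Day5/Day7; images the reverse) and run the three-way comparison:

```python
import podfusion as pf
from podfusion.experiment import ExperimentConfig, run_experiment
from podfusion.synthetic import complementary_config

config = ExperimentConfig(
    generator=complementary_config(n_per_class=24, seed=0),
    seed=0, epochs=15, base_channels=8, batch_size=16,
)
result = run_experiment(config)
print(result.summary["accuracy"].round(3).to_string())

n_test = result.split[1].size
acc = result.reports[("fusion", "resnet_rh")].accuracy
lo, hi = pf.wilson_interval(n_test, acc, 0.95)
print(f"fused accuracy {acc:.3f} on {n_test} test pods; "
      f"Wilson 95% CI [{lo:.3f}, {hi:.3f}]")
```

This prints:

```
model          adaboost  decision_tree    knn  random_forest  resnet_rh
source
rgb               0.724          0.862  0.724          0.724      0.724
hyperspectral     0.793          0.690  0.724          0.655      0.759
fusion            1.000          1.000  1.000          1.000      1.000

fused accuracy 1.000 on 29 test pods; Wilson 95% CI [0.883, 1.000]
```

Single-source models top out near their 75% ceiling (each source cannot
tell one class pair apart), while every fused model resolves all four
classes — the qualitative fusion result, reproduced at desk scale. The
Wilson interval quantifies the uncertainty of a proportion on a small test
set; for 125 test samples at 97.6% accuracy it gives 93.18%–99.18%.

The same experiment is available from the shell:

```bash
podfusion generate --n-per-class 104 --seed 0 --outdir data/
podfusion run-all --manifest data/manifest.json --outdir results/ --seed 0
podfusion select-bands data/manifest.json --threshold 0.7 --out mask.json
```

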