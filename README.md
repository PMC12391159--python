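# hemovision

Tooling for evaluating stain-free blood-cell detectors on brightfield
microfluidic imagery.

Label-free imaging flow systems classify unstained blood cells —
erythrocytes, their spiculated echinocyte phenotype, leukocytes
(lymphocytes, monocytes, neutrophils) and platelets — directly from
brightfield frames of a 200 µm microfluidic channel, with an object
detector standing in for the stains and antibodies of a conventional full
blood count. Training and judging such a detector requires a substantial
amount of dataset plumbing and a precisely specified evaluation protocol.
This package implements that surface as a tested library and CLI for
researchers building or auditing such systems:

* **`yolo_io`** — YOLO-format annotation I/O (normalized center boxes
  `class cx cy w h`), class schemes, and merge/drop remapping between the
  6-, 4- and 3-class vocabularies.
* **`dataset_engineering`** — tiling of full camera frames into 416×416
  training tiles with annotation remapping and a 5-px edge rule, plus the
  augmentation suite (90/180/270° rotations, flips, ±5 % photometrics).
* **`synth_flow`** — a synthetic brightfield scene generator with exact
  ground truth: class-specific physical sizes (platelets ≤ 5 µm, red cells
  6–8 µm, leukocytes 10–22 µm), echinocyte spiculation
  r(θ) = r₀(1 + a·sin kθ), channel walls, noise, blur and seeded
  reproducibility — so every downstream stage is testable without any real
  data.
* **`detection`** — a classical reference detector (background flattening,
  Otsu segmentation, watershed declumping, size/texture classification)
  that fills the detector slot on one CPU, and an adapter for external
  Darknet/YOLO detection JSON.
* **`evaluation`** — the evaluation protocol: IoU matching at threshold
  0.75, greedy one-to-one claiming by confidence, K×(K+1) confusion
  matrices with a *non-detected* column and a spurious-detection vector,
  per-class and macro precision/recall/F1, stratified 5-fold 70/20/10
  splitting and fold aggregation (mean ± sample sd).
* **`composition_analysis`** — physical sizing via the 57.37 µm / 416 px
  calibration, population ratio tables, and least-squares agreement (R²,
  slope) between paired ratio series, e.g. device vs flow cytometry.

Six published single-fold confusion matrices of YOLOv4 blood-cell
detectors ship as CSV fixtures (`hemovision.fixtures`) and serve as worked
examples for the metric derivation.

## Core definitions

For ground-truth class *c* with confusion matrix `N` (rows = ground truth,
columns = predicted classes then non-detected) and spurious vector `s`:

    recall_c    = N[c,c] / Σ_p N[c,p]           (misclassified and
                                                 non-detected both count)
    precision_c = N[c,c] / (Σ_g N[g,c] + s_c)
    F1_c        = 2·P·R / (P + R)
    macro       = unweighted mean over classes

A detection claims its highest-IoU unmatched annotation when
IoU ≥ 0.75; class-mismatched claims fill the off-diagonal confusion cell;
unclaimed detections are spurious (or duplicates) and count against
precision only.

## Worked example

```python
from hemovision import load_reference_table, metrics_from_confusion

cm = load_reference_table("two_class_optimised")   # 81,15,2 / 9,232,1
for cls, m in metrics_from_confusion(cm).items():
    print(cls, m.as_percent())
```

prints

```
echinocyte {'precision': 90.0, 'recall': 82.7, 'f1': 86.2}
erythrocyte {'precision': 93.9, 'recall': 95.9, 'f1': 94.9}
macro {'precision': 92.0, 'recall': 89.3, 'f1': 90.5}
```

i.e. the optimised two-class detector identifies 90.0 % of its echinocyte
calls correctly, recovers 95.9 % of erythrocytes, and balances to an
echinocyte F1 of 86.2 %.

A full synthetic round trip:

```python
from hemovision import (SCHEME_3, SimConfig, generate_dataset,
                        evaluate_image_set, metrics_from_confusion)
from hemovision.detection import detect_reference, resolve_classes
from hemovision.synth_flow import DEFAULT_MIXTURE_3

cfg = SimConfig(mixture=dict(DEFAULT_MIXTURE_3), noise_sd=0,
                blur_sigma_px=0, defocus_probability=0, seed=1)
frames = generate_dataset(cfg, 300, seed=1)
dets = {f.source_id: resolve_classes(detect_reference(f), SCHEME_3).detections
        for f in frames}
cm, _ = evaluate_image_set(frames, dets, SCHEME_3)
print(metrics_from_confusion(cm)["macro"].as_percent())
```

prints `{'precision': 98.9, 'recall': 93.0, 'f1': 95.8}` — the classical
reference detector on 300 noiseless three-class tiles.

The same stages are scriptable from the shell:

```
hemovision simulate --n 200 --seed 1 --out run/
hemovision detect --in run/simulate --out run/dets.json \
    --classes run/simulate/classes.txt
hemovision evaluate --labels run/simulate --detections run/dets.json \
    --classes run/simulate/classes.txt --out run/report
```

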