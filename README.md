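# esohsi

Hyperspectral-imaging (HSI) analysis of esophagogastric surgical specimens:
simulation of annotated hyperspectral phantom cohorts, spectral
preprocessing, physiological index mapping, pixel-wise tissue
classification with a hybrid 3D-1D convolutional network under
leave-one-patient-out cross-validation, and statistical comparison of
tissue physiology between classes and tumor-stage groups.

## The problem

Intraoperative HSI records a reflectance cube R(x, y, λ) — here 100
spectral channels over 500–1000 nm — of the opened, tumor-carrying
specimen. Two questions matter clinically:

1. **Can tumor be distinguished from healthy esophageal and gastric
   mucosa pixel by pixel?** Spectral differences arise from hemoglobin
   absorption (Q-bands at 542/577 nm, the deoxy-Hb band at 760 nm) and
   water absorption near 970 nm.
2. **Do physiological parameters differ between tissues and stages?**
   Carcinomas are typically blood-richer, better perfused and wetter
   (edema) than healthy mucosa, and advanced (T3/T4) tumors wetter than
   early (T1/T2) ones.

Clinical cubes are not publicly available, so the package ships a
first-class phantom generator: per-tissue chromophore parameters
(oxygen saturation f, total hemoglobin c_Hb, water fraction w, scattering
power law) are rendered through a Beer–Lambert model

    R(λ) = S(λ) · 10^(−A(λ)),
    A(λ) = c_Hb · [ f·ε_oxy(λ) + (1−f)·ε_deoxy(λ) ] + w · ε_water(λ),

with Gaussian extinction templates, per-pixel log-normal physiology
jitter and additive noise. Every downstream stage is exercised and
tested against this generator.

## Pipeline

| stage | module | what it does |
|---|---|---|
| simulate | `esohsi.phantom` | annotated phantom cohorts (ENVI + PNG + CSV manifest) |
| I/O | `esohsi.hsi_io` | ENVI cube reader/writer (BSQ/BIL/BIP), mask PNGs, RGB previews |
| preprocess | `esohsi.preprocess` | spectral median filter, SNV normalization, 520–1000 nm crop |
| indices | `esohsi.physio` | StO2, NIR-PI, TWI, OHI band-ratio maps from raw reflectance |
| classify | `esohsi.model` | hybrid 3D-1D CNN (numpy, class-weighted CE, cancer-F1 early stop) |
| evaluate | `esohsi.evaluate` | LOPO folds, patient-wise sensitivity/specificity/F1/MCC/AUC |
| stats | `esohsi.stats` | Welch t-tests of per-patient region means, star annotation |

The classifier takes p×p×B′ patches (default 3×3×96 after preprocessing),
applies two Conv3D layers, collapses the spatial axes, two Conv1D layers
along the spectrum, then dropout and a softmax over
{esophagus, stomach, cancer}. Training uses balanced class weights
w_c = N/(K·n_c) against the heavy class imbalance (cancer is ~7.5 % of
annotated pixels) and stops early on the validation F1 of the cancer
class. Evaluation is strictly patient-wise: each LOPO fold holds out one
test patient and three validation patients; metrics are averaged across
patients, then macro-averaged across the three classes.

## Worked example

```python
from esohsi.phantom import PhantomSpec, generate_cohort
from esohsi.model import ModelConfig
from esohsi.evaluate import run_lopo
from esohsi.physio import compute_physio_maps, summarize_regions, summaries_to_frame
from esohsi.stats import compare_groups

cohort = generate_cohort(8, PhantomSpec(image_height=32, image_width=32), seed=0)

summaries = summaries_to_frame([
    s for p in cohort
    for s in summarize_regions(compute_physio_maps(p.cube), p.mask,
                               p.patient_id, p.tumor_stage)])
for c in compare_groups(summaries, designs="AC", index_names=("TWI", "OHI")):
    print(f"{c.design} {c.index_name:4s} {c.label:34s} "
          f"{c.mean_a:.3f} vs {c.mean_b:.3f}  p={c.p:.4f} {c.stars}")

cfg = ModelConfig(optimizer_name="adam", learning_rate=1e-3,
                  max_epochs=4, early_stop_patience=2, seed=0)
report = run_lopo(cohort, cfg, seed=0, max_train_patches=1500, max_val_patches=800)
mac = report["macro"]
print(f"macro sens={mac['sensitivity']['mean']:.2f}+/-{mac['sensitivity']['sd']:.2f} "
      f"auc={mac['auc']['mean']:.3f}")
```

prints

```
A TWI  healthy stomach vs cancer          0.641 vs 0.699  p=0.3214
A OHI  healthy stomach vs cancer          0.570 vs 0.741  p=0.0061 **
C TWI  T1/T2 vs T3/T4 (cancer regions)    0.621 vs 0.777  p=0.0433 *
C OHI  T1/T2 vs T3/T4 (cancer regions)    0.770 vs 0.712  p=0.5384
macro sens=0.98+/-0.02 auc=0.993
```

Cancer regions carry more hemoglobin than healthy stomach (OHI, p < 0.01)
and advanced-stage tumors are wetter than early-stage ones (TWI, p < 0.05)
— exactly the physiology the cohort generator programs in. The 8-fold
LOPO classifier separates the three phantom tissues almost perfectly at
this noise level; clinical tissue is far more heterogeneous.

A shell workflow over the same stages:

```
esohsi simulate --n-patients 8 --size 64 --seed 0 --out cohort/
esohsi indices cohort/P000.raw --mask cohort/P000_mask.png --out idx/P000
esohsi evaluate --data cohort/ --out eval/ --seed 0
esohsi stats --summaries summaries.csv --out comparisons.csv
```

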