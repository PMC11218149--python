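# slicefill

Sparse-slice segmentation completion for 3D medical volumes.

## The problem

Pediatric renal tumors (nephroblastoma / Wilms' tumor) are resected after
surgical planning that benefits greatly from a patient-specific 3D model
of the tumor and the surrounding neoplastic kidney. The bottleneck is
segmentation: labelling every axial CT section by hand takes an expert
hours, while fully automatic networks fail on these large, heterogeneous,
anatomy-deforming masses. The practical middle ground is *completion*:
the expert segments only every (g+2)-th section and an automatic method
fills in the *g* withheld sections between each annotated pair.

`slicefill` implements this workflow end to end for volumes labelled
`{0: background, 1: neoplastic kidney, 2: tumor}`:

- **gap schedules** — which sections are manual, which are completed, and
  the resulting expert time saving `g/(g+2)` (gap 1 → 33 %, gap 5 → 71 %,
  gap 8 → 80 %, gap 10 → 83 %);
- two **completion backends**: deterministic shape-based interpolation of
  signed distance fields, and a per-volume 2D U-Net (numpy, no framework
  dependency) trained *only on the manual sections of the volume being
  completed* — deliberate overfitting that memorises one patient's
  anatomy and fills the gaps;
- a fully automatic **leave-one-patient-out** baseline;
- **Dice evaluation** (`2A/(2A+B+C)`) with table aggregation, crossing-gap
  analysis against inter-rater agreement, and report rendering;
- a **synthetic phantom cohort** (lobulated tumor compressing a thin
  kidney crescent, CT-like noise, simulated second rater calibrated to a
  target inter-rater Dice) standing in for the non-distributable clinical
  cohort;
- NIfTI / NRRD I/O and a `slicefill` command-line interface
  (`phantom`, `schedule`, `train`, `complete`, `eval`, `sweep`, `report`).

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Complete a synthetic patient at gap 5 with both backends and compare to
the ground truth:

```python
import slicefill as sf

volume, labels = sf.generate_phantom(sf.PhantomConfig(seed=11))

model = sf.SliceCompletionModel(volume, labels, gap=5, backend="net",
                                train_config=sf.TrainConfig(epochs=30, seed=0),
                                extent="auto")
result = model.fit()
print(result.summary(labels))
```

```
        Sparse-Slice Completion Results
================================================
backend:              net
gap:                  5
slices:               24 (9 manual, 15 completed)
manual fraction:      0.375
est. time saving:     71%
epochs trained:       30
final loss:           0.9243
parameters:           536947
------------------------------------------------
Dice vs reference      all     withheld
  kidney             0.930    0.906
  tumor              0.939    0.918
================================================
```

The 15 completed sections reach a tumor Dice of 0.92 against the full
reference annotation while the expert drew only 9 of 24 sections — an
estimated 71 % time saving at this gap. (The schedule keeps 9 manual
sections rather than the asymptotic 2/7 of 24 because the block pattern
is tiled over the anatomy's extent and truncated blocks keep their end
slice manual.) The deterministic interpolation backend
(`backend="interp"`) needs no training, and a sweep over gaps quantifies
the accuracy-vs-effort curve:

```python
cohort = sf.generate_cohort(3, seed=7, rater_targets=None)
from slicefill.experiments import run_gap_sweep
sweep = run_gap_sweep(cohort, [1, 5, 10], backend="interp")
print(sweep.mean_by_gap("tumor"))   # {1: 0.99, 5: 0.91, 10: 0.70}
print(sweep.time_saving_row())      # {1: 33, 5: 71, 10: 83}
```

The same studies are available from the shell:

```bash
slicefill schedule 12 10
# manual=2 automatic=10 saving=83%
slicefill phantom --n-patients 3 --seed 1 --out-dir cohort/
slicefill sweep --config examples/sweep.yaml --seed 1 --out-dir results/
```

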