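# pdseverity

Weakly supervised four-class severity staging (healthy / mild / moderate /
severe) from wrist-worn IMU recordings, evaluated end-to-end on a synthetic
cohort generator.

A subject's recordings are treated as a *bag* of 1.5 s windows (instances):

1. **simulate** — synthetic cohorts: six-channel 200 Hz recordings across 12
   scripted activities, with severity-graded intermittent tremor,
   bradykinesia-like amplitude reduction, per-subject idiosyncrasies, and
   configurable class imbalance. CSV-per-recording + JSON manifest on disk.
2. **preprocess** — causal 4th-order Butterworth bandpass (0.3–20 Hz),
   per-recording z-score, segmentation into 300-sample windows with 50 %
   overlap.
3. **features** — 54 statistics per window: std, variance, skewness,
   kurtosis, RMS, energy, median, range per channel, plus Pearson
   correlations within the accelerometer and gyroscope triads.
4. **bags** — per-activity k-means codebooks turn windows into
   activity-qualified words; each subject becomes a chronological word
   document; an LDA topic model adds a per-subject topic posterior; the bag
   vector is `[word counts || topic probabilities]`.
5. **augment** — bag-level augmentation: Hamming-nearest same-class pair
   selection, positionwise pair crossover, and within-activity instance
   shuffling, balancing minority classes with full parentage audit.
6. **evaluate** — subject-level leave-one-out CV with strictly per-fold
   fitting, one-vs-rest metrics (weighted recall ≡ accuracy), instance and
   SimpleMI baselines, and a (k, t) hyperparameter grid.

## CLI

```sh
# generate a cohort (Table-1-style imbalance) as CSV + manifest
pdseverity simulate --classes 15,41,17,12 --seed 1 --preset easy --out scratch/cohort

# full-pipeline leave-one-out evaluation
pdseverity evaluate scratch/cohort --activities 2,3,4,5 --k 8 --t 4 --classifier knn

# baselines and ablations
pdseverity evaluate scratch/cohort --baseline instance
pdseverity evaluate scratch/cohort --baseline simplemi-mean
pdseverity evaluate scratch/cohort --no-lda

# hyperparameter sweep and augmentation audit
pdseverity grid scratch/cohort --k-grid 4,8,12 --t-grid 4,6
pdseverity augment-audit scratch/cohort --out scratch/audit.json
```

## Library usage

```python
from pdseverity import generate_cohort, loocv
from pdseverity.simulate import GeneratorConfig
from pdseverity.evaluate import PipelineConfig

cohort = generate_cohort((10, 10, 10, 10), seed=1,
                         config=GeneratorConfig.from_preset("easy"))
report = loocv(cohort, PipelineConfig(activities=(2, 3, 4, 5), k=8, t=4))
print(report.accuracy, report.confusion_frame())
```
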