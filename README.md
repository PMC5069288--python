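# wedag

Wavelet-entropy features and DAG-SVM classification for 2D brain-slice
images.

`wedag` is a computer-aided-diagnosis pipeline for a three-class problem in
structural MRI of sensorineural hearing loss: distinguishing left-sided
(LHL) and right-sided (RHL) unilateral hearing loss from healthy controls
(HC) using a single preprocessed sagittal brain slice per subject. It is
aimed at researchers studying texture-based MRI classification who need a
tested, reproducible reference implementation — including a synthetic
phantom cohort, since no public dataset exists for this task.

## Method

1. **Wavelet entropy (WE).** An n-level 2D discrete wavelet transform with
   the biorthogonal `bior5.5` pair decomposes a slice into 3n+1 subbands
   (LLn plus HL/LH/HH per level). On each subband the Shannon entropy of
   the normalised energy distribution is computed,

       p_i = c_i² / Σ_j c_j²,   H = −Σ_i p_i log₂ p_i  [bits],

   reducing a 256×256 image to a (3n+1)-element feature vector (10
   features at the default n = 3).

2. **DAG-SVM.** Every class pair gets a soft-margin linear SVM

       min ½‖w‖² + ε Σ_n ξ_n   s.t.  y_n(w·x_n − b) ≥ 1 − ξ_n,  ξ_n ≥ 0

   (default ε = 0.05, features z-scored on training statistics). The
   (C−1)C/2 = 3 binary models are wired as a decision DAG: each node's
   score sign eliminates one class, and C−1 evaluations yield the label.

3. **Evaluation.** 10 × 10-fold stratified cross-validation; validation
   predictions from all runs pool into one confusion matrix, from which
   overall accuracy and one-vs-rest per-class sensitivity, specificity,
   precision and accuracy are derived.

See `docs/methods.md` for conventions, the phantom generator's model, and
limitations.

## Worked example

```python
from wedag import (PhantomConfig, generate_cohort, build_filter_bank,
                   extract_batch, run_cv, overall_accuracy, metrics_table)

cfg = PhantomConfig(seed=1)          # 49 phantoms: 20 HC, 15 LHL, 14 RHL
images, labels = generate_cohort(cfg)
fb = build_filter_bank("bior5.5")
features = extract_batch(images, fb, level=3)   # 49 x 10 wavelet entropies
print(features.round(3).head(3))

result = run_cv(features, labels, k=10, runs=10, penalty=0.05, seed=1)
print(f"overall accuracy: {overall_accuracy(result.confusion):.2f}%")
print(result.confusion.to_frame())
print(metrics_table(result.confusion))
```

prints

```
     LL3    HL3    LH3    HH3    HL2    LH2    HH2    HL1    LH1    HH1
0  9.000  7.638  7.802  6.881  7.852  7.924  7.253  8.177  8.158  8.062
1  9.002  7.751  7.722  7.257  8.436  8.287  7.409  8.173  8.164  8.100
2  8.999  7.628  7.799  7.201  7.887  7.873  7.213  8.143  8.172  8.099

overall accuracy: 100.00%
      HC  LHL  RHL
HC   200    0    0
LHL    0  150    0
RHL    0    0  140

       Sensitivity  Specificity  Precision  Accuracy
Class
HC           100.0        100.0      100.0     100.0
LHL          100.0        100.0      100.0     100.0
RHL          100.0        100.0      100.0     100.0
```

Each feature row is one phantom's ten subband entropies in bits (LL3 near
log₂ of its subband size means near-uniform energy; lower detail-band
values mean spatially concentrated texture). The confusion matrix pools
490 validation predictions (10 runs × 49 subjects); the default
strong-effect phantoms are fully separable, while the null generator
(`effect_size=0, lesion_contrast=0`) drops accuracy to chance (~35%).

The same workflow is available from the shell:

```sh
wedag synth   --out cohort/ --seed 1
wedag extract --cohort cohort/ --level 3 --out features.csv
wedag cv      --features features.csv --out report
wedag sweep   --cohort cohort/ --levels 1,2,3,4 --out levels.csv
wedag metrics --confusion report_confusion.csv --out metrics.csv
```

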