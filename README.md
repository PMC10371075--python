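# babykin

Classification of infant movement context from 3D motion capture.

In a mobile conjugate reinforcement (MCR) experiment an infant lies under a
mobile whose motion is, depending on the experimental stage, absent (B1,
spontaneous baseline), driven by the experimenter (B2, non-contingent
baseline), tethered to one of the infant's feet (CR1/CR2, the coupled
minutes), or cut loose again (DC, decoupled). If the functional context
shapes the structure of infant movement, the stage should be decodable from
the kinematics alone. `babykin` implements that decoding pipeline for
marker-based motion capture (12 keypoints at 100 Hz, millimetres) and a
synthetic-session generator so every step is testable without access to
infant recordings.

## Method

1. **Preprocessing.** Each coordinate stream J(t) is cleaned with the
   three-sigma rule — values outside E[J] ± 3σ(J) (one pass, statistics
   over the whole stream) are set to NaN — and all missing samples are
   filled by natural cubic spline interpolation through the observed ones.
2. **Body-centred spherical coordinates.** Per frame, an orthonormal frame
   is anchored at the Center Pelvis: lateral axis left→right pelvis
   (hips), longitudinal axis pelvis→head orthogonalised against it, normal
   axis their cross product. Joint displacements relative to this root are
   view-invariant.
3. **Histogram of Joint Displacement (HJD).** The direction of each
   joint's displacement is quantised on an 8 azimuth × 8 elevation = 64-bin
   equal-angle spherical grid (radius ignored). Over a 500-frame window
   (100-frame overlap, so step 400; windows never cross a stage boundary),
   the HJD counts frames per bin. Per-joint histograms are fused by
   concatenation (1D) or row-stacking into a parts × 64 matrix (2D), e.g.
   Feet = L + R foot, Full-body = hands + knees + feet.
4. **Classifiers.** Seven families map a window's HJD to one of the five
   stage labels 0–4: kNN and LDA baselines; a fully connected net
   (240, 60, 15 hidden units, dropout 0.5); 1D and 2D convolutional nets
   (16/32 and 4/8 filters, kernel 3); and 1D/2D capsule networks that keep
   the convolutional front-end (32 and 16 filters) but replace pooling
   with 8-dimensional primary capsules routed by agreement —
   cᵢ = softmax(bᵢ), s_j = Σᵢ c_ij û_ij, v_j = squash(s_j),
   b_ij += û_ij·v_j over 3 iterations, squash(s) = (‖s‖²/(1+‖s‖²))·s/‖s‖ —
   into five 16-dimensional class capsules scored by vector norm and
   trained with the margin loss. The neural stack is implemented in NumPy
   inside the package (see `babykin._nn`).
5. **Evaluation.** Leave-one-subject-out: fit on all windows of the other
   subjects, test on the held-out subject, report the unweighted mean of
   per-fold window accuracies, confusion matrices, temporal label traces,
   and the per-stage feet displacement rate in m/min.

## Worked example

```python
from babykin import CohortSpec, build_dataset, generate_cohort
from babykin import classifiers as clf, evaluation as ev

spec = CohortSpec(n_subjects=5, seed=1)
cohort = generate_cohort(spec)          # five subjects, ~48,000 frames each

print(ev.cohort_displacement_rates(cohort).round(2))

dataset = build_dataset(cohort, feature_kind="fused1d", parts="feet")
print(f"\n{len(dataset)} windows of 500 frames, feature dim {dataset.features.shape[1]}")

for family in ("knn", "lda", "fcnet"):
    config = clf.default_config(family, epochs=20, seed=0)
    result = ev.loso_evaluate(dataset, config)
    print(f"{family:6s} LOSO accuracy: {100 * result.mean_accuracy:.2f}%")
```

prints

```
        mean    se  n_subjects
stage
B1      7.80  0.29           5
B2      3.66  0.10           5
CR1     7.97  0.52           5
CR2     9.21  0.72           5
DC     12.52  0.46           5

575 windows of 500 frames, feature dim 128
knn    LOSO accuracy: 61.39%
lda    LOSO accuracy: 60.52%
fcnet  LOSO accuracy: 60.00%
```

The displacement-rate table shows the generator's built-in stage contrast:
feet activity collapses in B2 (the infant watches the mobile), rises
through the coupled minutes, and peaks after decoupling — and that contrast
is what makes the stages decodable at roughly three times the 20 % chance
level from foot HJDs alone.

The same pipeline is scriptable from the shell:

```sh
babykin simulate --seed 1 --out raw/
babykin preprocess --in raw/S1_session.csv --out clean/S1_session.csv
babykin features --in clean/ --parts feet --kind fused1d --out features.h5
babykin evaluate --features features.h5 --families knn,lda --out results/
babykin run-all --seed 1 --families knn,lda,fcnet --out results/
```

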