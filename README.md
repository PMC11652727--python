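# mammoread

Radiologists reading dense screening mammograms make errors that are not
random: readers from the same cohort tend to false-call the same
normal-looking regions and miss the same cancers. `mammoread`
reconstructs, as a tested and reusable Python library, an analysis
pipeline that maps those cohort-level errors to quantitative image
appearance:

1. **Suspicious areas** — per-reader marks on a 1–5 suspicion scale are
   pooled (rating ≥ 3 is a positive call), clustered with a
   bounded-diameter complete-linkage rule (no two marks in a cluster
   farther apart than 250 px at study scale), and boxed with a 10 px
   margin. Marks within a lesion's radius (12.5 mm) of its centre join
   that lesion's cancer area; unmarked lesions still become areas.
2. **Reader outlier exclusion** — readers are rows of a binary
   false-response matrix (1 = false positive on a normal area, or false
   negative on a cancer area). Ward/Euclidean hierarchical clustering
   groups readers by error agreement; readers in the dendrogram's outer
   branch are excluded from the false-positive model, together with
   areas only they marked.
3. **Difficulty labels** — per area kind, a false-response count above
   the cohort median makes the area *difficult*, otherwise *easy*.
4. **Radiomics** — each area yields a named 201-feature vector:
   28 first-order statistics; 139 texture features (GLCM 88, GLRLM 6,
   GLSM 6, GLDS 15, NGTDM 15, SFM 8, fractal dimension 1); and 34
   filter-based features (Laws energies 18, a λ=4 px/cycle Gabor bank
   at 0°–150° in 30° steps, the 38-filter root filter set collapsed to
   8 maximum-response (MR8) outputs, and 2 Fourier band fractions).
5. **Difficulty model** — a random forest (`max_features="sqrt"`,
   forest size tuned over a grid) evaluated with nested
   cross-validation: leave-one-out outer loop, repeated (×3) 3-fold
   stratified inner loop, with SMOTE oversampling, a variance > 1
   feature filter and standardization all fitted strictly inside each
   training fold. Out-of-fold scores give the AUC with a 2000-replicate
   stratified-bootstrap 95% CI.
6. **Feature statistics** — each outer fold records the forest's top-10
   features; the five most frequent are compared between easy and
   difficult groups with two-tailed Mann-Whitney U tests under a
   Bonferroni family-wise error rate of .05, reported as median (IQR).

The reading-study data this design comes from are not publicly
available, so the package ships a first-class **synthetic cohort
generator**: breast-like textured views with planted suspicious areas
whose *difficult* class carries orientation-coherent λ=4 texture (an
architectural-distortion-like signature), and simulated readers with
configurable false-response rates and planted outlier over-callers.
Every pipeline stage is tested against this generator's ground truth
and against independent brute-force oracles.

Intended users: researchers in observer performance / mammography CAD
who want to run this error analysis on their own reading data, and
methodologists who want a fully specified, leakage-audited reference
implementation of the pipeline.

## Worked example

`examples/05_difficulty_model.py` builds a 24-area synthetic cohort
(8 difficult), extracts the 201 features per area and runs the nested
cross-validation:

```text
cohort: 24 areas, 8 difficult, injected orientation 120 deg
out-of-fold AUC 1.000 (95% CI 1.000-1.000), accuracy 1.000
chosen tree counts across outer folds: [25, 50]

top-5 discriminative features (easy vs difficult, median (IQR), Bonferroni-adjusted p):
                    feature                               easy                          difficult  p_adjusted significance
 glcm_d1_cluster_prominence 321366.966 (314215.543-327901.014) 361314.025 (355775.255-368569.584)    0.000504           **
              gabor_l4_t120                8.799 (7.363-9.161)             17.138 (15.322-19.524)    0.000504           **
               gabor_l4_t60                8.670 (7.297-9.228)                4.770 (4.502-5.561)    0.000504           **
                gabor_l4_t0                8.009 (6.841-8.447)                3.899 (3.545-4.358)    0.000504           **
glcm_d3_difference_variance             69.754 (66.524-72.537)             84.047 (80.347-95.598)    0.000829           **
```

The AUC of 1.000 says the model separates the two difficulty classes
perfectly out of fold; the feature table shows *why*: the difficult
areas carry coherent texture at 120°, so the matched Gabor response
(`gabor_l4_t120`) is elevated in the difficult group while the
off-orientation responses are depressed — exactly the signature the
generator planted. The remaining examples cover cohort generation
(`01`), suspicious-area construction (`02`), reader-outlier detection
(`03`, which recovers the two planted over-callers exactly) and raw
feature extraction (`04`).

A thin CLI wraps the same library calls:

```bash
mammoread demo --seed 1 --out demo_out     # full synthetic end-to-end run
mammoread areas --annotations ann.csv --lesions les.csv --spacing 0.1
mammoread cluster-readers --matrix responses.csv
```

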