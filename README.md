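# fcgrad

Functional-gradient analysis of parcellated resting-state fMRI, built as a
fully synthetic, ground-truth-checked pipeline. The scientific question it
serves: do psychiatric groups (recent-onset psychosis, recent-onset
depression, clinical high-risk) differ from healthy controls in the
*hierarchical organization* of cortical functional connectivity — the
low-dimensional gradients along which regional connectivity profiles vary —
and in how differentiated their networks are in gradient space?

The pipeline is the field-standard chain:

1. **FC**: Pearson correlation between parcel time series, Fisher
   z-transform; per-row thresholding to the strongest 10% of connections;
   cosine-similarity affinity.
2. **Gradients**: diffusion-map embedding (α = 0.5, automatic diffusion time
   λ/(1−λ)); subject gradients aligned by orthogonal Procrustes to a
   reference derived from the healthy-control mean FC.
3. **Harmonization**: parametric empirical-Bayes ComBat across acquisition
   sites, preserving group, age, sex and mean framewise displacement
   (matches `sva::ComBat` to ~1e−13 RMS on a frozen fixture).
4. **Differentiation metrics**: network mean gradient scores, gradient range
   (max − min), and within-/between-network dispersion around coordinate-wise
   median network centroids in the (g1, g2) plane — 7 within- and 21
   between-network scores for a seven-network scheme.
5. **Inference**: parcel-wise OLS t-maps with covariates; Mann-Whitney U
   tests (exact enumeration at small n, tie-corrected normal approximation
   otherwise, η² = Z²/N) of confound-regressed metrics; Benjamini-Hochberg
   FDR within declared families; clinical screening (>30% missing excluded,
   group-median imputation) and Spearman correlations.
6. **Spatial association**: spin-permutation nulls (mirrored random
   rotations of the spherical parcel centroids, nearest-neighbour
   reassignment) for t-map × receptor-map correlations with FDR.

Because no public data accession exists for the motivating cohort, the
package ships a first-class synthetic cohort generator (`fcgrad.simulate`)
that plants known two-dimensional gradient geometry, scanner-site effects,
group effects on network means/dispersion/range, and clinical readouts —
so every stage is testable against ground truth. See `docs/methods.md` for
the model and its assumptions.

## Worked example

The numbered scripts under `analysis/` walk the full study on a deterministic
107-subject, 100-parcel, two-site synthetic cohort (seed 0) with the
canonical planted effects. For example:

```sh
python analysis/01_simulate_cohort.py
python analysis/05_group_inference.py
```

prints, among other lines:

```
 * HC vs CHR-P+ROD+ROP      network_mean_g1      nm_g1_SMN    q=3.47e-16 eta2=0.658   [SMN shift]
 * HC vs ROD                range                range_g1     q=5.63e-10 eta2=0.676   [g1 range shrink]
 * HC vs ROD                within_dispersion    wd_VAN       q=1.90e-08 eta2=0.578   [DAN/VAN shrink]
 * HC vs ROP                network_mean_g1      nm_g1_SMN    q=2.89e-10 eta2=0.682   [SMN+VAN shifts]

clinical correlations: 0 of 176 pairs significant after FDR

null cohort (no planted effects): 1 of 176 network/metric tests significant
```

Read: in every FDR family where an effect was planted, that effect is the
smallest-q finding (the bracketed annotations name the planted ground truth);
with nothing planted the battery stays quiet. `02_embed_gradients.py` reports
how well the aligned gradients recover the planted axes (mean |r| ≈ 0.97 /
0.91 on this cohort), `03_harmonize_scores.py` shows the site gap shrinking
under ComBat, `06_receptor_association.py` demonstrates the spin test with a
positive control (a noisy copy of a t-map: r = 0.83, p_spin = 0.002), and
`07_density_sensitivity.py` matches gradients across 10% vs 20% thresholding
(|r| ≈ 0.98 for both analyzed gradients).

A `fcgrad` command-line tool wraps the same machinery
(`fcgrad simulate|run|sensitivity|report --seed N --out DIR`).

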