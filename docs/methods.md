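# Methods

## The model

Resting-state fMRI network analysis conventionally reduces time-varying
functional network connectivity (dFNC) to a handful of *fixed* connectivity
patterns: sliding-window correlation matrices are pooled over subjects and
k-means-clustered, and each window is assigned to its nearest "snapshot"
state.  That representation is time-blind — it cannot distinguish a
connectivity pattern that is dissolving from the same pattern that is
forming.  This package implements an alternative that summarizes the
dynamics as a small set of *evolving* multiframe motifs (EVOdFNCs):

1. **Windowed dFNC.**  For each subject, network timecourses (T timepoints
   × N networks) are correlated inside a tapered rectangular window of
   `window_len` TRs advanced one TR at a time.  Taper weights enter the
   Pearson correlation as observation weights.  Each window yields a
   D = N(N−1)/2 vector Γ(t) (row-major upper triangle); a subject
   contributes W = T − window_len + 1 frames.
2. **Averaged planar embedding.**  All subjects' frames are embedded
   jointly into 2D with UMAP (`n_neighbors = 25`, `min_dist = 0.75`,
   spectral initialization), R times with seeds `base_seed + r`, and the R
   coordinate matrices are averaged pointwise.  Continuity of
   within-subject trajectories is preserved under summation, and averaging
   stabilizes the layout.  Optional full-Procrustes alignment of runs onto
   run 1 is available because unaligned averaging is vulnerable to the
   rotation/reflection indeterminacy of independent runs; the default is
   plain averaging.
3. **Linear trajectory exemplars.**  Every continuous sub-segment of τ
   consecutive embedded points (τ = 2 × window_len by default) is
   linearized: centroid midpoint (x̂, ŷ), OLS slope m̂ of y on x clipped to
   ±max(|x|, |y|) over the embedding, and length ℓ̂ = maximum pairwise
   distance.  The (x̂, ŷ, m̂) triples are k-means-clustered into K
   exemplars; exemplar k inherits the centroid triple, a length d_k equal
   to the mean member length, and a temporal orientation given by the sign
   of the dot product between its direction vector and the members' mean
   (last − first) displacement.
4. **Lifting (data-driven inversion).**  τ evenly spaced points are placed
   along each oriented exemplar; each point is lifted to connectivity space
   as the unweighted mean of the dFNC frames whose embedded coordinates are
   its n = 25 spatially nearest neighbors (matching the embedding's
   `n_neighbors`).  The result is a τ × D motif.  Search is exact; ties at
   the n-th neighbor break toward the lower frame index.
5. **Representational importance (RI).**  Each length-τ window w of a
   subject's observed sequence is compared frame-by-frame to the motifs:
   ϱ_t = argmax_k corr(frame_t(w), frame_t(motif k)), and
   λ_k(w) = |{t : ϱ_t = k}|/τ.  Rows of the resulting K-variate series lie
   on the simplex lattice with denominator τ.  A `meancorr` mode
   (β_k(w) = mean_t corr) is also provided.
6. **Meta-states and occupancy.**  Stacked weight vectors are
   k-means-clustered into M meta-states; each centroid induces a
   meta-EVOdFNC as the centroid-weighted sum of basis motifs; a subject's
   occupancy rate of a meta-state is the fraction of their weight vectors
   in its cluster.
7. **Statistics.**  Per feature (subject-mean RI per motif, meta-state
   occupancy, snapshot occupancy, exemplar-membership fraction), OLS on
   gender + age + meanFD + diagnosis reports the diagnosis effect;
   patients-only OLS on the six positive symptoms jointly (plus the same
   covariates) reports per-symptom effects.  Benjamini–Hochberg FDR is the
   default correction (Bonferroni available) — the correction method is an
   interpretation, stated in the output metadata.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `window_len` | 22 | TRs | correlation window (44 s at TR = 2 s) |
| `taper_sigma` | 3 | TRs | Gaussian convolved with the rectangle; `inf` = pure rectangle |
| `tau` | 2·window_len = 44 | windows | trajectory-segment / motif duration (88 s) |
| `n_neighbors` | 25 | — | UMAP neighborhood size |
| `min_dist` | 0.75 | — | UMAP minimum embedding distance |
| `n_runs` (R) | 25 | — | embedding runs averaged |
| `K` | 10 | — | linear trajectory exemplars |
| `n_lift` | 25 | — | nearest neighbors in the inversion |
| `M` | 10 | — | meta-state clusters |
| `k_snap` | 5 | — | time-blind snapshot states |
| k-means | 2000 iter, 250 restarts (500 for weight vectors) | — | best inertia kept, seeded |

The K and M defaults come from an elbow-criterion diagnostic; the package
reports k-means inertia at each clustering stage so users can redo that
diagnostic on their own data.

## Numerical conventions

- Degenerate windows (a network flat inside a window) abort with an error
  naming subject, window and network; flat frames inside RI scoring score
  correlation 0 with a logged warning instead, so synthetic edge cases do
  not abort runs.
- Vertical trajectory segments (zero x-variance) take the positive slope
  bound; argmax ties in RI go to the smallest motif id; nearest-neighbor
  distance ties go to the lower frame index; a zero mean displacement
  orients an exemplar +1.  All stages are bit-reproducible given seeds.
- "Midpoint" of a curved segment is the centroid of its points, which
  coincides with the chord midpoint for straight uniformly sampled
  segments.  OLS of y on x (not total least squares) is used because the
  slope-clipping bound exists precisely to tame near-vertical OLS slopes.
- The subject-level RI feature for statistics is the temporal mean of the
  weight rows (median available).  A constant response across subjects
  yields coefficient 0 and p = 1 by convention.
- Meta-state occupancy assigns rows to the nearest centroid, which equals
  the stored k-means labels in-sample and projects new subjects onto an
  existing meta-state set.
- Bundles store matrices as CSV at 17 significant digits (lossless float64
  round trip) plus JSON metadata; a stage's `meta.json` is written last and
  serves as its completion marker for resume.

## The synthetic generator

`synthgen` emulates exactly the structure the pipeline claims to recover:
block-modular SPD anchor correlation patterns; evolving motifs as convex
interpolations between anchor pairs (SPD by convexity); per-subject
schedules tiling the scan with motif instances, the "signal" motif drawn
with group-dependent probability (ratio 2:1 by default); Gaussian
timecourses sampled per TR through the scheduled covariance's Cholesky
factor plus white noise (sd 0.2); covariates (age, gender, mean frame
displacement) with configurable usage effects (0 by default) and six
positive-symptom scores for patients.  Ground truth stores each motif at
dFNC *window* resolution — the TR-level correlation sequence averaged
under the analysis taper — because windowing is a smoothing the pipeline
cannot undo, so recovery is compared like-with-like.

What it does **not** emulate: hemodynamic filtering and realistic fMRI
noise spectra, scanner/site effects, between-subject anatomy, negative
symptom structure, or motion artifacts correlated with connectivity.
Passing recovery tests therefore shows the pipeline's machinery is correct
and sensitive at realistic SNR, not that real resting-state data contain
motifs of this form.

## Problem sizes used by the test suite and acceptance script

Full-scale defaults (N = 47, R = 25, K = M = 10) are kept in
`PipelineConfig`; the shipped experiments run at desk scale, chosen as the
package's own fast-feedback conditions:

- *tiny preset*: 20 subjects (10 per group), N = 12 networks, T = 158 TRs,
  two planted motifs, R = 5 embedding runs, K = M = 6, reduced k-means
  restarts (20–50).  Used for continuity (< 0.5 mean continuity ratio) and
  motif recovery (≥ 0.7 mean frame-wise Pearson per planted motif).
- *group-effect replicates*: 10 cohorts of 24 subjects with 316-TR scans
  (≈ 5 motif instances per subject) and the 2:1 usage ratio, R = 2, K = 6.
  The longer scans are a power consideration: with ~3 instances per
  158-TR scan the per-subject usage fraction is a 3-draw binomial and the
  diagnosis contrast, though of the planted sign, is unstable at n = 24.
- *null calibration*: 200 replicates of 40 patients with independent
  features and symptoms.

Motif-recovery scoring compares both temporal orientations of a lifted
motif and keeps the better: the orientation of an exemplar is a package
convention (mean member displacement), and a motif is the same object as
its time reversal up to that convention.

## Limitations

- Unaligned run averaging (the default, for fidelity to the procedure the
  package implements) can shrink coordinates toward zero if runs differ by
  reflection/rotation; `align_runs` mitigates this but changes the
  procedure.  At desk scale with spectral initialization the runs are
  stable enough that the default works.
- Exemplars are straight lines; strongly curved trajectory families are
  represented piecewise at best.
- The argmax RI weighting is winner-take-all per frame; near-ties between
  motifs are invisible in λ (use `meancorr` to see them).
- OLS with a binary diagnosis regressor assumes homoscedastic residuals
  across groups; no site/scanner harmonization is modeled.
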