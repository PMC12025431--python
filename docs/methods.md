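# Methods

## The model

Resting-state EEG microstate analysis describes the scalp voltage field as a
sequence of quasi-stable topographies ("microstates"), each lasting roughly
60–120 ms, drawn from a small set of K template maps. This package
implements the standard estimation pipeline and the statistical layer of a
three-arm pre/post stimulation study design, together with a synthetic
generator that produces EEG with known microstate structure so every stage
is testable without acquired recordings.

The pipeline, in execution order:

1. **Preprocessing** (`recording_io`). Re-reference to the mean of a channel
   set (linked mastoids by default, `M1`/`M2`), zero-phase 4th-order
   Butterworth band-pass (1–40 Hz default), anti-aliased downsampling
   (polyphase; 500 Hz default). Zero-phase filtering is used because
   microstate segmentation depends on topography *timing*; a causal filter
   would shift boundaries. GFP is reference-invariant (it removes the
   spatial mean), so the choice of reference does not affect clustering;
   both linked-mastoid and common-average re-referencing are exposed.
2. **GFP peaks** (`gfp`). GFP(t) is the spatial (population) standard
   deviation of the map at sample t. Clustering operates on local GFP
   maxima: high signal-to-noise topographies. Peaks closer than a minimum
   interval (10 ms) are thinned greedily by descending height; peaks whose
   GFP deviates from the series mean by more than 2 SD are excluded.
   Exclusion is two-sided (the literal reading of "exceeding 2 standard
   deviations from the mean"); one-sided is available. Outlier exclusion
   runs before spacing enforcement (configurable, as the order is not
   canonical). The first sample of a plateau counts as the peak.
3. **Modified k-means** (`clustering`). Polarity-invariant clustering of the
   peak maps: membership maximizes the squared normalized inner product
   (x·T)²/(‖x‖²‖T‖²) on spatially centered maps, and each template update is
   the dominant eigenvector of the scatter matrix of its assigned maps —
   the polarity-invariant analog of a cluster mean. Initialization samples
   k distinct observed maps; empty clusters are re-seeded with the worst-fit
   observation; ties in assignment go to the lowest class index. Defaults:
   50 random restarts, up to 1000 iterations, convergence at stable
   assignment or relative GEV change < 1e-6. The best restart by GEV wins.
4. **Model selection**. GEV (GFP-weighted explained topographic variance)
   and the cross-validation criterion CV = σ̂²·((C−1)/(C−1−k))², with σ̂² the
   mean per-degree-of-freedom residual after projecting each map on its
   assigned template. k is the CV argmin over the scan range (4–7 default);
   ties within a relative 1e-9 of the minimum (on the per-dof power scale)
   resolve to the smallest k, so noise-free data — where CV ≈ 0 for every
   k ≥ k_true — selects the generating k deterministically.
5. **Canonical alignment**. Fitted templates are relabeled to classes A–D by
   the permutation maximizing total absolute spatial correlation with
   canonical maps (linear sum assignment). The shipped canonical maps are
   montage-generated: A and B are left/right-mirrored diagonal gradients, C
   the anterior–posterior gradient, D a frontocentral radial bump. The A/B
   gradient axes sit 60° off the anterior axis: a 45° diagonal would
   correlate at |r| ≈ 0.71 with C on any symmetric layout, while 60° keeps
   all pairwise |r| ≤ ~0.5. Note A, B, C are linear in the head-plane
   coordinates and hence linearly dependent as a set (A + B ∝ C).
6. **Back-fitting and smoothing** (`segmentation`). Every sample is assigned
   to the class with the highest polarity-invariant spatial correlation;
   spatially flat samples inherit the previous label. Interior segments
   shorter than 30 ms are then merged into neighbors, shortest first. Each
   frame of an offending segment prefers the neighbor class with the
   smaller polarity-invariant global map dissimilarity (GMD); contiguity is
   enforced by an optimal split point (frames left of the split join the
   left neighbor, the rest the right, split minimizing total GMD). A purely
   independent per-frame choice could interleave the two classes and create
   new sub-threshold runs with no termination guarantee; the split variant
   strictly reduces the run count each step, so it provably terminates with
   every interior segment at or above the threshold. Boundary segments are
   exempt.
7. **Parameters**. Per class: mean duration (ms), coverage (time fraction),
   occurrence (runs/s), and the K×K transition matrix (adjacent-run counts,
   rows normalized over outgoing transitions, structural zero diagonal).
   With boundary runs included (default), coverage = duration·occurrence/1000
   holds exactly. Transition rows are normalized per source class — the
   convention consistent with three-destination rows summing to ~1.
8. **Statistics** (`stats`). Paired/two-sample t with Cohen's d, Pearson χ²
   (no continuity correction), one-way ANOVA, mixed-design rmANOVA
   (between = group, within = class; no sphericity correction by default,
   Greenhouse–Geisser by flag), Dunn's rank post hoc with tie-corrected
   variance, Bonferroni correction, OLS change-rate regression, and TANOVA:
   the permutation test whose statistic is the GMD between GFP-normalized
   group-mean maps, with p = (1 + #{perm ≥ obs})/(1 + n_perm) so p is never
   0 and identical groups give exactly 1. All tests two-sided.
9. **Orchestration** (`pipeline`, `cli`). `run_study` chains the stages over
   a manifest: subject-level clustering → per-condition meta-clustering of
   pooled subject templates (the two-level convention) → TANOVA between
   groups per class and stage → alignment → per-recording back-fit and
   parameters → pre/post paired tests (Bonferroni per K-class family) →
   post-stage mixed ANOVA + Dunn → change-rate regressions restricted to
   cells with significant pre/post change. Everything is seeded and
   deterministic; provenance (config hash, seed, version) is written with
   the report.

## The synthetic generator

`synthetic.SyntheticSpec` defaults are the emulated study conditions:
64 channels on a sunflower head-disk layout, 120 s at 500 Hz, K = 4 classes
with mean dwell times (70.95, 73.52, 86.90, 79.82) ms — the sham-condition
parameter regime — uniform off-diagonal transitions, 10 Hz rectified-sine
amplitude envelope with a random phase per segment, envelope-peak signal GFP
10 µV against 2 µV i.i.d. Gaussian sensor noise (peak SNR 5).

Labels follow a semi-Markov process: gamma dwell times (shape 4) per visit,
then a transition-row draw. A per-sample first-order Markov chain would give
geometric dwells far more dispersed than empirical microstate durations;
gamma shape 4 matches the observed regime. Every segment gets a random
polarity sign, so any accidentally polarity-sensitive analysis code fails
loudly. `generate_study` adds participant-level lognormal jitter (SD 0.05)
of the dwell means shared across stages, per-group post-stage dwell shifts
(triangular: class C shortened, B/D lengthened; sine: D lengthened), and a
behavioral table in which the three-back reaction-time change rate is
`rt_slope`·(class-C coverage change) + N(0, 0.02).

What the generator does **not** emulate: volume-conduction-realistic
topographies (maps are geometric gradients/bumps, not forward-modeled
dipoles), spatially correlated sensor noise (optional smoothing kernel
aside), artifacts (ocular, muscle, cardiac), non-stationarity across the
recording, and any true stimulation physiology. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated generative assumptions, not performance on real EEG.

## Numerical choices and degenerate inputs

- All map comparisons operate on spatially centered maps; correlations are
  clipped to [−1, 1]; templates are re-centered and re-normalized after
  every eigenvector update.
- Zero-variance (spatially constant) samples: back-fit inherits the previous
  label (class 0 at the start); smoothing scores them equally for both
  neighbor classes; clustering rejects all-constant inputs.
- Assignment ties break to the lowest class index; peak-height ties in
  spacing enforcement keep the earlier sample; plateau maxima report their
  first sample.
- Change rates (post − pre)/pre are undefined at pre = 0 and raise.
- Dwell discretization: gamma dwells (ms) round to the nearest sample with a
  1-sample floor.

## Known limitations

- **Duration bias under 30 ms smoothing.** With gamma-shape-4 dwells at
  60–100 ms means, 5–9% of *true* segments are shorter than 30 ms. The
  mandated merging of sub-30 ms segments removes them and donates their
  frames to neighbors, inflating recovered mean durations by ~8–10% per
  class even when back-fitting is perfect. This is a property of the
  estimator/generator pair, not an implementation defect: coverage,
  occurrence ratios, transition structure (max elementwise error ~0.02 at
  10 minutes) and label agreement (~98%) are unaffected. Recovered mean
  durations should be read as durations *after* short-segment suppression.
- Reported problem sizes in the test-suite recovery experiments (10-minute
  single recordings; studies of up to 10 participants per group at label
  level) were chosen to keep the full suite fast while leaving Monte-Carlo
  margins well above the assertion thresholds.
- The mixed ANOVA assumes a balanced within factor; unbalanced designs are
  rejected rather than approximated.
- EDF/BrainVision reading is delegated to MNE; the package's own exchange
  format is the delimited matrix dialect with a key=value sidecar.
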