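# microstates

Resting-state EEG **microstate analysis** as a reusable, tested Python
pipeline — for researchers studying how interventions (e.g. non-invasive
brain stimulation) reshape large-scale brain dynamics, and for anyone who
needs a transparent, scriptable alternative to GUI toolboxes.

The scalp voltage field at rest passes through brief (~60–120 ms)
quasi-stable topographies drawn from a few template maps, classically
labeled A–D. The package estimates them and their dynamics end to end:

- **GFP peaks** — global field power `GFP(t) = sqrt((1/C) Σᵢ (vᵢ(t) − v̄(t))²)`
  and local-maximum selection (≥ 10 ms apart, amplitude within 2 SD).
- **Polarity-invariant modified k-means** — cluster membership maximizes
  `(x·T)²/(‖x‖²‖T‖²)` (a map equals its negation); templates update as the
  dominant eigenvector of the assigned scatter matrix; model choice by
  global explained variance (GEV) and the cross-validation criterion
  `CV = σ̂²((C−1)/(C−1−k))²`.
- **Back-fitting + smoothing** — per-sample assignment by absolute spatial
  correlation; interior segments < 30 ms merged into neighbors by global
  map dissimilarity (GMD).
- **Microstate parameters** — per class: duration (ms), coverage, occurrence
  (1/s), and the transition-probability matrix `P(i→j)` over adjacent
  segments (`coverage = duration × occurrence / 1000` holds exactly).
- **Statistics** — paired/two-sample t with Cohen's d, χ², one-way and
  mixed-design repeated-measures ANOVA, Dunn's post hoc, Bonferroni,
  TANOVA (permutation test on GMD between group-mean maps), and OLS
  regressions between change rates `Δ = (post − pre)/pre`.
- **Synthetic generator** — semi-Markov label sequences (gamma dwell times),
  canonical topographies on a head-disk montage, GFP-like amplitude
  envelope, per-segment polarity flips, sensor noise, and matched ground
  truth; plus a full 3-group pre/post study generator with a coupled
  behavioral table.

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

```python
import numpy as np
from microstates import (SyntheticSpec, generate_recording, compute_gfp,
                         select_gfp_peaks, peak_maps, TopographySet,
                         modified_kmeans, align_labels, backfit,
                         smooth_segments, compute_params)

spec = SyntheticSpec(length=120.0, seed=1)       # 64 ch, 500 Hz, SNR 5
rec, truth = generate_recording(spec)

peaks = select_gfp_peaks(compute_gfp(rec), min_interval=10, outlier_sd=2)
obs = TopographySet(maps=peak_maps(rec, peaks), channels=rec.channels)
ts, _, _ = modified_kmeans(obs, k=4, n_restarts=50, seed=1)
ts = align_labels(ts, truth.templates)           # relabel to classes A-D

labels = smooth_segments(backfit(rec, ts), rec, ts, min_duration=30)
params = compute_params(labels)
print(f"GEV {ts.gev:.3f}  agreement "
      f"{np.mean(labels.labels == truth.labels.labels):.3f}")
print(params.to_frame(ts.labels).round(3))
```

Output:

```
GEV 0.958  agreement 0.981
  class  duration_ms  coverage  occurrence_per_s
0     A       78.472     0.235             3.000
1     B       78.024     0.220             2.817
2     C       96.365     0.286             2.967
3     D       86.072     0.259             3.008
```

GEV ≈ 0.96 on GFP-peak maps and 98% per-sample agreement with the ground
truth labels; recovered durations sit a few percent above the generating
means (70.95, 73.52, 86.90, 79.82 ms) because sub-30 ms true segments are,
by design, merged away during smoothing (see `docs/methods.md`,
"Known limitations"). Coverage is largest for class C, whose dwell time is
longest.

For a whole synthetic study from the shell:

```bash
microstates fixtures --out study/ --n-per-group 5 --seed 0
microstates run --manifest study/manifest.csv --out report/ --seed 0
```

`report/` then contains per-condition templates, per-participant parameter
tables, a group summary (mean ± SEM per class/parameter), and
`stats.json` with pre/post paired tests, transition tests, TANOVA,
mixed-ANOVA/Dunn group comparisons, and change-rate regressions.

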