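# mitohet

Stochastic modelling and single-cell analysis of mitochondrial DNA
(mtDNA) heteroplasmy segregation in budding yeast.

When two mtDNA variants coexist in one cell (heteroplasmy), mitotic
growth drives their rapid divergence: within a few generations many
descendants carry essentially a single variant (homoplasmy).  `mitohet`
provides the computational side of studying this process with dual
fluorescent reporters (Atp6-NeonGreen marking one mtDNA variant,
Atp6-mKate2 the other) in time-lapse movies of populations growing from
single heteroplasmic zygotes:

* **Segregation simulator** — each cell's mitochondrial network is an
  unbranched array of `n` mtDNA copies (default 32), one symbol per
  nucleoid.  Per synchronous 1.5-h generation the array is replicated
  back to capacity by relaxed (Pólya-urn) replication with new copies
  placed beside their template, cut into `nspl` fragments that re-fuse
  in random order (fission–fusion), and split so that a contiguous
  block of `ndau` copies (at most `n/2`) founds the daughter cell.
* **Quantification** — per-cell fluorescence is background-subtracted,
  volume- and per-frame-median-normalised, and summarised as the
  heteroplasmy value `h = I_mKate2 / (I_NG + I_mKate2)` ∈ [0, 1].
* **Classification** — a three-component Gaussian mixture fitted to the
  h distribution yields homoplasmy thresholds at the component
  intersections (the canonical pair is 0.33 / 0.71); a kernel-density
  valley threshold handles dark/bright colony scoring.
* **Model fitting** — `SegregationModel.fit()` grid-searches
  `(ndau, nspl)` by least squares between simulated and (sigmoid-
  smoothed) empirical homoplasmic-fraction curves at t = 1.5 … 7.5 h,
  returning a `SegregationResults` object with the SSE surface, the
  best pair, and `summary()`.
* **Lineage analysis** — pedigree trees from tracking output, h sampled
  at a matched growth stage (20 % bud-to-mother volume ratio), Spearman
  correlations for mother–daughter / mother–self relations, paired
  t-tests across populations.
* **Kinetics** — exponential decay fits `I(t) = A e^(-kt) + C` for
  translation-shutoff (chloramphenicol) series, and the
  nucleoid-transfer estimate `foci_rate / 5 min x 47.5 min`.
* **Synthetic data** — a generator that emulates the tracked per-cell
  tables (protein turnover lag at k = 0.31 / h, autofluorescence,
  photobleaching, measurement noise, bud growth) on top of ground-truth
  simulated lineages, so the whole pipeline runs and is testable
  without any microscopy data.

## Worked example

Fit the two segregation parameters to a homoplasmy time course (here
one simulated at known truth `ndau=14, nspl=4`):

```python
import numpy as np
from mitohet import SegregationModel, SimConfig, simulate_curve

empirical = simulate_curve(SimConfig(ndau=14, nspl=4, n_replicates=50, seed=7))
print(np.round(empirical.fractions, 3))
# [0.    0.03  0.25  0.418 0.601 0.698]

model = SegregationModel(empirical, ndau_range=[6, 10, 14, 16],
                         nspl_range=[1, 4, 16, 32])
res = model.fit(n_replicates=10, seed=11)
print(res.summary())
```

```
Segregation model fit (least-squares grid search)
==================================================
copy number n          : 32
classification         : (0.33, 0.71)
replicates per pair    : 10   seed: 11
grid                   : ndau 6-16, nspl 1-32 (16 pairs)
comparison timepoints  : (1.5, 3.0, 4.5, 6.0, 7.5) h
target fractions       : [0.0711 0.2078 0.4326 0.6111 0.6878]
--------------------------------------------------
best ndau              : 14
best nspl              : 4
best SSE               : 0.005427
pairs within 2x minimum: 2
sigmoid smoothing      : L=0.7212 r=0.8728 t0=4.0365
```

The fit recovers the generating pair: about 14 of 32 copies pass to
each daughter, with the network shuffling into ~4 fragments per cycle.
The sigmoid line gives the smoothed target curve (plateau L, rate r,
midpoint t0, hours).

The kinetics estimators on generator output:

```python
from mitohet import GeneratorConfig, generate_cap_series, fit_decay, nucleoids_per_division

cap = generate_cap_series(GeneratorConfig(noise_cv=0.0), duration_h=6.0)
series = cap[cap.channel == "mkate"]
d = fit_decay(series.time_h, series.intensity)
print(f"k = {d.k:.3f} per h (SEM {d.k_sem:.3f}), plateau {d.offset:.1f} a.u.")
# k = 0.310 per h (SEM 0.000), plateau 25.0 a.u.

print(nucleoids_per_division(1.18, 5, 47.5))
# 11.2
```

A `mitohet` command-line tool wraps the same functionality
(`simulate`, `generate`, `analyze`, `fit`, `lineage`, `kinetics`);
every run writes a JSON manifest with config, seed and file digests.

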