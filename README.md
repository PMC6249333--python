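# morphokey

Multivariate Ratio Analysis (MRA) for morphometric species delimitation,
plus a weighted multi-access identification-key engine.  Built for
taxonomists working on cryptic species — the motivating case is
parasitoid wasps of the genus *Pteromalus* (Hymenoptera: Pteromalidae),
where close relatives differ in body proportions rather than in
qualitative characters — but every component works on any table of
positive linear measurements.

## What it computes

Linear measurements $x_{i1}, \dots, x_{ip}$ (µm) of specimen $i$ are
log-transformed and split into an isometric size score and a shape
vector:

$$\mathrm{isosize}_i = \frac{1}{p}\sum_j \ln x_{ij}, \qquad
  s_{ij} = \ln x_{ij} - \mathrm{isosize}_i .$$

Because every ratio $x_{ij}/x_{ik}$ satisfies
$\ln(x_{ij}/x_{ik}) = s_{ij} - s_{ik}$, an analysis of shape vectors is
an analysis of all body ratios at once.  On top of this decomposition
the package provides:

- **shape PCA** — PCA of the shape covariance; loadings are orthogonal
  to the equal-weights (size) direction, variance is reported as percent
  of total shape variance;
- **PCA ratio spectrum** — a PC's loadings ordered on a line, with
  seeded bootstrap intervals; the variables at the two extremes define
  the single ratio that best approximates the PC;
- **allometry diagnostics** — per-group regression of a shape PC on
  isosize and an ANCOVA-style test of whether two groups share a common
  allometric axis (i.e. whether their shape difference could be a size
  artefact);
- **LDA ratio extractor** — every pair $(i, j)$ is scored by the
  standardized two-group separation of the projection onto
  $(e_i - e_j)/\sqrt2$; the winner is the measurable ratio that best
  reproduces the linear discriminant, reported with per-group ranges
  and a gap-midpoint threshold;
- **measurement QC** — Bland–Altman agreement (bias ± 1.96 SD limits)
  for comparing gaugers, and per-species range summaries that feed
  directly into quantitative key descriptors;
- **key engine** — taxa × descriptor matrices (categorical state sets
  or numeric ranges, importance weights 1–5), free-order elimination in
  which unknown cells never exclude, checkbase-style database
  diagnostics, exhaustive shortest-identification-path search, and
  export of flat dichotomous keys;
- **synthetic data** — a log-normal measurement generator with shared
  size factors, planted ratio contrasts and allometric slopes, and a
  random key-matrix generator, so the whole pipeline is testable
  without any downloads.

## Worked example

```python
from morphokey import (SyntheticSpec, simulate_measurements,
                       to_log_shape, shape_pca, pca_ratio_spectrum,
                       extract_best_ratios)

spec = SyntheticSpec(groups=(("A", 30), ("B", 30)),
                     planted_pair=("ant.l", "ool.l"),
                     planted_delta=0.06, noise_sd=0.02, seed=11)
table = simulate_measurements(spec)          # 60 specimens x 28 variables
data = to_log_shape(table)                   # isosize + shape vectors
pca = shape_pca(data)
print(f"PC1 explains {pca.variance_fraction[0]:.1f}% of shape variance")
print("spectrum extremes:", pca_ratio_spectrum(pca, pc=0).extreme_pair)
best = extract_best_ratios(data, top_k=1)[0]
print(f"best ratio {best.numerator}:{best.denominator} "
      f"separation {best.separation:.2f}, high group {best.high_group}")
```

prints

```
PC1 explains 15.5% of shape variance
spectrum extremes: ('ool.l', 'ant.l')
best ratio ant.l:ool.l separation 5.20, high group B
```

The generator planted a +δ/−δ log-contrast on `ant.l` (antenna length)
and `ool.l` (ocello-ocular distance) in group B, with δ three times the
residual noise SD.  PC1 picks up the planted shape difference, the
spectrum places exactly those two variables at its extremes, and the
extractor recovers `ant.l:ool.l` as the best discriminating ratio with
a standardized separation of 5.2 within-group SDs (group B having the
larger ratio, as planted).

The same pipeline runs from the shell:

```sh
morphokey simulate --out meas.csv --seed 11 --planted-pair ant.l,ool.l
morphokey analyze --input meas.csv --groups A,B --bootstrap 200 \
    --seed 11 --out-dir run1
morphokey key export --matrix key.json --format flat
```

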