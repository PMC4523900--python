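# mrin

Direct assessment of mRNA integrity from RNA-Seq data, at the sample and the
individual-gene level.

RNA collected from post-mortem tissue (or any sample that sat around before
extraction) is often partially fragmented.  After poly-dT selection, only
fragments retaining the poly-A tail are sequenced, so read coverage piles up
toward the transcript 3′ end.  This 3′ bias skews expression estimates for
most — but not all — genes, and the RIN values that would flag such samples
are frequently unavailable for public data.  `mrin` quantifies the bias
directly from the reads, so quality control can be done *post hoc* on the
sequencing data alone.

## The statistic

For each gene (one representative transcript, the longest per gene, genes
overlapping neighbours excluded) and each sample, per-base read depth
$n_x$ is indexed from the transcript 3′ end ($x = 1..L$).  The cumulative
coverage distribution

$$f(x) = c(x)/h,\qquad c(x) = \sum_{i\le x} n_i,\qquad h = c(L)$$

is compared with the uniform null $x/L$ through a signed
Kolmogorov–Smirnov statistic

$$d = f(x^\*) - x^\*/L,\qquad x^\* = \arg\max_x |f(x) - x/L| ,$$

which is positive under 3′ bias and negative under 5′ bias.  The gene ×
sample matrix of $d$ values is median-centred per gene (**mKS**), removing
gene-intrinsic coverage bias, and each sample's

$$\mathrm{mRIN} = -\frac{1}{N}\sum_{g} \mathrm{mKS}_{g}$$

is referred to a null distribution $N(\mu, \sigma^2)$ of non-degraded
samples, fitted either by a scaled median absolute deviation over samples
with positive mRIN, or by a truncated-normal moment fit with a grid search
over the truncation threshold $\alpha \in [-0.05, 0.05]$.  Each sample gets
$z = (\mathrm{mRIN} - \mu)/\sigma$ and a one-sided $P = \Phi(z)$.

Gene-specific degradation is scored by the **GIS** — the Pearson
correlation of a gene's mKS values with the sample mRINs (negative =
degrades faster than average) — and related to transcript features (region
lengths, GC content, AU-rich elements, PUM2 motifs in the 3′UTR) by binned
correlation and grouped OLS regression on Fisher-transformed scores.

A synthetic-degradation simulator (3′-anchored exponential fragment
survival with per-sample hazards and per-gene stability multipliers) makes
the whole pipeline testable without external data.

## Worked example

```python
from mrin import (SimulationConfig, simulate_cohort, attach_rpkm,
                  build_ks_matrix, MRINModel)

cohort = simulate_cohort(SimulationConfig(n_samples=50, n_genes=200, seed=1))
attach_rpkm(cohort.profiles)
ks = build_ks_matrix(cohort.profiles, mode="per_base")
results = MRINModel.from_ks_matrix(ks).fit()
print(results.summary())
```

prints

```
mRIN sample-integrity results
=============================
samples:            50
genes used (median): 164
null method:        truncnorm
alpha:              -0.0080
mu:                 0.00435886
sigma:              0.000527544
goodness-of-fit D:  0.1067
degraded at P<0.05 : 11 (22.0%)
degraded at P<0.1  : 14 (28.0%)
degraded at P<0.25 : 21 (42.0%)
```

The cohort was simulated with 10 of 50 samples degraded; all 10 are among
the 11 samples called at P < 0.05.  The null parameters say the
non-degraded samples' mRINs sit around 0.0044 with spread 5×10⁻⁴ — on
simulated data the spread is pure counting noise, far tighter than on real
cohorts.  `results.samples` holds the per-sample table (mrin,
n_genes_used, z, p); `mrin.GISModel(mks, results.samples["mrin"]).fit()`
scores per-gene stability.

The same pipeline runs from the shell on BAM, bedGraph or exon-RPKM input:

```sh
mrin simulate --out sim --seed 1 --n-samples 50 --n-genes 200
mrin ks --annotation sim/annotation.refflat --bedgraph-dir sim --out ks
mrin mrin --mks ks/mks.tsv --filter-report ks/filter_report.tsv --out mrin_out
mrin gis --mks ks/mks.tsv --filter-report ks/filter_report.tsv \
         --samples mrin_out/samples.tsv --out gis_out
```

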