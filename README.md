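# cypwaves

Zebrafish cytochrome P450 (CYP) genomics and developmental expression
analysis, packaged as a library with a thin command-line front end.

Zebrafish carry 94 CYP genes in 18 families — the enzymes that oxidize
steroids, retinoids, vitamins, drugs and pollutants — and during the first
two days of development different sets of these genes are expressed in
successive *waves*. `cypwaves` bundles the pieces needed to study that
picture quantitatively:

- **gene registry** — a curated table of all 96 annotated CYP loci (Zv8
  assembly coordinates), with gene/family accounting and detection of tandem
  duplication arrays (e.g. the 8-gene CYP2K array on chromosome 3, the
  10-gene CYP2AA array on chromosome 23, and the 11-gene CYP2J-like cluster
  on chromosome 20) by single-linkage interval grouping;
- **microarray preprocessing** — single-color signal conditioning: floor at
  5 fluorescence units, baseline selection by the median of per-array
  medians, Schadt-style rank-invariant probe selection with a
  piecewise-linear running-median normalization curve per array, duplicate
  spot averaging, and QC removal of saturated / never-above-background
  probes;
- **temporal differential expression** — an empirical-Bayes time-course
  model (in the style of Bayesian estimation of temporal regulation): per
  probe, the vector of timepoint mean differences relative to 3 hpf is a
  two-component multivariate-normal mixture whose DE component carries an
  empirically estimated, autocorrelation-aware signal covariance; the
  posterior probability of that component is the DE call, with naive one-way
  ANOVA as a comparator;
- **expression clustering** — within-gene z-normalization,
  hierarchical-initialized K-means (K = 10 by default), the cluster affinity
  search technique (CAST, affinity 0.7 on a 0–1 scale), maternal-profile
  affinity screening, and peak/bimodality classification;
- **qPCR absolute quantification** — plasmid standard curves
  (`Ct = b + m·log10(copies)`, efficiency `E = 10^(-1/m) − 1`), molecule
  counts, ARNT2 reference normalization, and array/qPCR concordance;
- **synthetic data** — a seeded generator emulating the study design (6
  timepoints × 4 biological replicates, duplicate spots, per-array monotone
  distortions, saturation clipping, below-background probes) with full
  ground truth, so every stage is testable without any download.

## Worked example

```python
>>> import cypwaves as cw
>>> registry = cw.load_registry()
>>> len(registry), cw.count_genes(registry), cw.count_families(registry)
(96, 94, 18)
>>> [c.size for c in cw.tandem_clusters(registry, chromosome="3", subfamily="2K")]
[3, 8]
```

96 table rows collapse to 94 distinct genes (CYP2X10 and CYP2X12 each appear
twice as exact assembly copies) across 18 families; the chromosome-3 CYP2K
genes fall into a tandem array of eight plus a separate three-gene group
~1.7 Mb away.

Running the expression chain on synthetic data
(`python examples/temporal_de.py`):

```
{'n_probes': 2000, 'n_significant': 401, 'fraction_significant': 0.2005}
planted waves detected: 100.0%   flat probes mis-called: 0.06%
```

2000 probes were simulated with 20% carrying a planted 4-fold expression
wave; the time-course model recovers every planted wave at posterior > 0.99
while mis-calling almost no unregulated probes. The other scripts in
`examples/` (one per capability) print registry surveys, normalization
quality, cluster mean profiles, qPCR standard-curve fits, and a fully
manifest-logged pipeline run; each ends with a comment explaining what the
numbers mean.

A thin CLI mirrors the library:

```sh
cypwaves registry count
cypwaves registry clusters --chrom 20 --family 2
cypwaves simulate --seed 1 --out raw.tsv
cypwaves normalize --input raw.tsv --out norm.tsv --qc-report qc.json
cypwaves de --input norm.tsv --alpha 0.01 --out de.tsv
cypwaves run --config run.yaml
```

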