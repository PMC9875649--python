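# spatialpgx

Spot-level pharmacogene expression heterogeneity and differential
expression for Visium-style spatial transcriptomics.

Chemotherapeutic drug exposure varies across regions of a tumor, and part of
that variation may come from spatially heterogeneous expression of
*pharmacogenes* — the genes that absorb, transport, metabolize, and detoxify
drugs (the ADME panel: CYP enzymes, ABC and SLC transporters, GSTs, ...).
`spatialpgx` implements an analysis of this question for spot-based spatial
transcriptomics: starting from 10x-style UMI count matrices with pathologist
region annotations, it ranks pharmacogenes by within-region expression
heterogeneity, tests tumor vs non-tumor differential expression, and
categorizes the panel into families and a reactive-oxygen-species (ROS)
gene set. A seeded negative-binomial simulator generates Visium-like
multi-sample datasets with planted signal, so the entire analysis is
runnable and testable without any external data.

## The statistics

For spot $j$ with UMI counts $c_{ij}$ over genes $i$:

- **Normalization** — expression fractions $r_{ij} = c_{ij} / T_j$ with
  $T_j = \sum_i c_{ij}$ the spot's total UMI count (TPM-like, without the
  $\times 10^6$ rescale). Tables are reported both raw and normalized,
  because normalization can mask heterogeneity when unrelated highly
  expressed genes inflate $T_j$.
- **Heterogeneity** — for each gene within a group of spots (tumor spots of
  one sample; tumor spots combined across samples; each annotated region),
  the interquartile range $\mathrm{IQR} = Q_{75} - Q_{25}$ of per-spot
  expression, with linear interpolation at position $(n-1)p$. Genes are
  ranked by descending IQR; the genes with IQR $> 0$ in tumor regions are
  the export surface for downstream gene-set analysis. No log transform.
- **Differential expression** — for each gene and sample, tumor spots of
  that sample vs non-tumor spots (normal + lymphocytes + stroma) pooled
  across all samples: $\log_2(m_T/m_N)$ on normalized means, a two-sided
  Welch's $t$-test (Welch–Satterthwaite degrees of freedom) on the same
  values, and Bonferroni correction $p_{\mathrm{adj}} = \min(1, p \cdot M)$
  with $M$ the number of tests actually performed. When exactly one group
  mean is zero the fold change is kept as $\pm\infty$ rather than dropped
  or pseudocounted — a zero mean is informative, and these records survive
  ranking, summaries, and serialization (`inf`/`-inf` in the TSVs).
- **Composite tumor region** — pathologist labels tumor, DCIS, cellular
  tumor, and desmoplastic tumor all count as tumor; mixed and unannotated
  spots are excluded from every statistic.
- **ROS genes** — panel genes whose GO term names contain *oxidative*,
  *stress*, *oxygen*, or *reactive* (case-insensitive substring), minus the
  CYP and ABC families; the GO table is a frozen input file and curation is
  an editable term blocklist.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default simulated design (6 samples × 400 spots × 600 genes, 286-gene
panel, 20 planted heterogeneous and 20 planted DE genes):

```sh
python analysis/01_simulate.py        # writes results/fixture/
python analysis/02_preprocess.py
python analysis/03_heterogeneity.py
python analysis/04_differential.py
python analysis/05_categorize.py
python analysis/06_report.py          # figures + sidecar TSVs
```

`02_preprocess` reports the panel filter (the 298-symbol panel keeps the
286 symbols present in the matrices):

```
panel: 298 symbols, 286 present, 12 absent from the matrices: ['PANELONLY01', ...]
```

`03_heterogeneity` ranks genes by raw tumor-spot IQR and checks the planted
truth:

```
286 of 286 panel genes have tumor IQR > 0 (raw counts)
planted heterogeneous genes in top 20 by tumor IQR: 18/20; all planted in IQR>0 set: True
   gene  n_spots  q25  q75  iqr
 CYP208     1536  3.0 14.0 11.0
 GST184     1536  3.0 14.0 11.0
 ...
```

(two planted heterogeneous genes were also drawn into the planted DE set,
which halves their tumor mean and with it their count-scale IQR — the
overlap is reported by `01_simulate`.)

`04_differential` runs 1716 Welch tests and summarizes per gene:

```
1716 (gene, sample) records, 1716 Welch tests (Bonferroni M), 0 infinite fold changes
18 genes significantly down in every sample at alpha=0.05
planted DE genes flagged down-in-all: 18/20
```

Alternatively the same pipeline runs as one command with a manifest
(input hashes, versions, per-region spot counts, stage timings):

```sh
spatialpgx simulate --out fixture --seed 0
spatialpgx run --config run.yaml
```

where `run.yaml` contains e.g. `input_dir: fixture` and
`out_dir: results/run`.

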