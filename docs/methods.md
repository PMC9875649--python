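# Methods

## Problem and scope

Spot-based spatial transcriptomics (Visium-style) measures deduplicated
transcript counts (UMIs) in ~55 µm barcoded capture areas ("spots") across
a tissue section. Each spot may contain several cells, and a pathologist
assigns each spot a histological label. This package quantifies, for a
curated pharmacogene (ADME) panel, (1) how heterogeneously each gene is
expressed *within* a region — tumor spots in particular — and (2) how
differently it is expressed *between* tumor and surrounding non-tumor
tissue. Everything downstream of the count matrices is in scope; upstream
read processing (basecalling, alignment, spot calling) and histology-image
handling are not.

## Spot classification

Raw pathologist labels map onto composite regions through a fixed table:
tumor, DCIS, cellular tumor, and desmoplastic tumor all become **tumor**;
stroma, lymphocytes, and normal map to themselves. Spots labeled **mixed**
and spots with no (or an unrecognized) annotation are excluded from every
statistic and counted in the run summary. Three groupings are supported:
tumor spots per sample, each region pooled across samples, and all tumor
spots combined.

## Normalization

Per-spot expression fractions r_ij = c_ij / T_j, where T_j is the spot's
total UMI count over **all** genes, not just the panel — panel-only totals
would reintroduce composition artifacts. The pipeline normalizes on the
full matrix first and filters to the panel afterwards (a test pins this
order). Spots with zero total are dropped and reported. Raw and normalized
tables are carried in parallel through every stage: normalization removes
per-spot library-size variation but can also mask genuine heterogeneity
when other highly expressed genes inflate a tumor spot's total, so neither
view is authoritative on its own.

## Heterogeneity score

For each (gene, group), the interquartile range Q75 − Q25 of per-spot
expression, with no log transform. The IQR captures spread without being
dominated by outlier spots and reads directly in count (or fraction)
units. Quantiles interpolate linearly at position (n−1)·p between order
statistics — the common default in mainstream statistical environments;
the convention is recorded in the output metadata. Ranking within a
(group, normalized) stratum is by descending IQR with lexicographic
tie-break on the gene symbol, so output is deterministic across platforms.
Groups with fewer than 4 spots are flagged low-n but still computed. The
genes with IQR strictly above zero in tumor spots (raw counts, the primary
variant) form the exported candidate list.

Caveat: on raw counts the IQR of an overdispersed count variable grows
roughly linearly with its mean, so a raw-IQR ranking partially reflects
expression magnitude. This is inherent to the score (and one reason the
normalized variant is reported alongside); the simulator's narrow
baseline-mean spread (below) makes planted-spread recovery measurable at
desk scale, and wider real-data mean ranges would mix magnitude into the
ranking.

## Differential expression

For each pharmacogene and each sample: tumor spots of that sample vs the
non-tumor spots (normal + lymphocytes + stroma) pooled across **all**
samples, on normalized values.

- log2 fold change log2(m_T / m_N) of the group means. If exactly one mean
  is zero the value is +∞ (tumor-only expression) or −∞ (non-tumor-only);
  if both are zero there is no comparison and the record is flagged. No
  pseudocounts anywhere: infinities are first-class through ranking,
  summaries, and TSV serialization (`inf`/`-inf`; missing values `NA`).
- Welch's two-sided t-test on the same per-spot values, zeros included as
  data points (zeros are special only for the mean-ratio infinity rule);
  degrees of freedom by Welch–Satterthwaite; both groups need ≥ 2 spots,
  the weakest precondition under which the sample variances exist.
- Bonferroni correction multiplies by M, the number of tests actually
  performed — records with no test (both-zero means, degenerate variance)
  do not inflate M.
- Degenerate variance (both sample variances zero): equal means give
  t = 0, p = 1; unequal means leave t undefined, so p is NA and the record
  is flagged rather than fabricating significance.

The per-gene summary reports the mean of finite fold changes (NA when all
records are infinite), counts of ±∞ records, the minimum corrected p, and
a down-in-all-samples flag (every sample's record significant with negative
fold change), ordered ascending by mean fold change as in the S-plot.

## Synthetic data generator

The simulator emulates the structure of a multi-sample Visium experiment at
desk scale, so the whole pipeline can be exercised, power-checked, and
calibrated without external data.

Counts: gene i in spot j is negative binomial with mean L_j · µ_i,region(j)
and dispersion φ (variance m + m²/φ); φ = ∞ selects the Poisson limit.
L_j is a log-normal library-size factor with unit mean — the standard
overdispersion model for UMI data, and it gives per-spot normalization
something real to remove.

Planted signal, in tumor spots only:

- **H** (heterogeneous): each tumor spot's mean is drawn from the mixture
  {µ_i, f_het·µ_i} with weight p_hi on the high component, independently
  per spot and gene — bimodal within-tumor expression.
- **D** (differential): all tumor-spot means scaled by f_de.

f_het = 1 and f_de = 1 give fully exchangeable regions (the null used for
type-I-error calibration). H and D are drawn independently, so they may
overlap; an overlapping gene has tumor mean (1 + p_hi(f_het−1))·f_de·µ ≈
1.25 µ at defaults — neither clearly down-regulated nor strongly
heterogeneous. Recovery measurements therefore use dedicated simulations
(H-only or D-only); the default end-to-end run plants both and reports the
overlap.

Region geometry: each raw label receives an exact spot budget
(largest-remainder rounding of the configured proportions) and grows
blob-wise from random seeds on the spot grid; a label with budget left but
no free frontier seeds a new blob, so budgets are met exactly while labels
stay spatially coherent, like contiguous histological areas.

Defaults (the study design; chosen once): 6 samples × 400 spots on a 20×20
grid × 600 genes, 286 of them panel members, plus 12 panel symbols absent
from the matrices so the panel-filter step has something to filter
(298 → 286). Baseline means µ_i ~ LogNormal(ln 3, 0.2) UMI/spot — a
curated, mid-expressed panel with modest gene-to-gene spread; φ = 5;
library σ_L = 0.3 (≈30% spot-depth variation); region shares tumor 0.33 /
DCIS 0.10 / cellular tumor 0.11 / desmoplastic tumor 0.10 / stroma 0.26 /
normal 0.03 / lymphocytes 0.01 / mixed 0.06, patterned on a breast-tumor
section dominated by tumor and stroma with rare lymphocyte and normal
areas; |H| = |D| = 20, f_het = 4, p_hi = 0.5, f_de = 0.5. Determinism: one
(config, seed) pair produces one byte stream (numpy PCG64; the algorithm
name is recorded in the emitted config). Reproducibility is promised
within this implementation, not across libraries or languages.

What the simulator does **not** emulate: spatial correlation of expression
beyond region structure, cell-type mixtures within a spot, segmentation or
doublet artifacts, zero-total spots (real Visium spots essentially never
have zero totals; the pipeline still handles them), or realistic
orders-of-magnitude spreads in baseline expression. Passing recovery tests
therefore show the statistics behave correctly under the stated generative
model, not that real tumor data would yield any particular gene list.

## ROS categorization

Families come from ordered symbol-prefix rules (first match wins; explicit
families on the panel file take precedence; unmatched genes are "other").
The ROS set: a panel gene is ROS iff at least one of its GO term *names*
contains at least one of the keywords oxidative / stress / oxygen /
reactive as a case-insensitive substring — mirroring a batch-query keyword
workflow — and its family is not CYP or ABC. The exclusion is applied
after matching (a test constructs a fixture where the order changes the
outcome). GO annotations are a frozen input file, never a live query:
keyword hits depend on the GO release. Manual curation of matched terms is
an editable blocklist (term names or IDs) applied before matching. The
fixture GO table shipped by the simulator is synthetic and labeled as such.

## Numerical and format choices

- Quantiles: numpy linear interpolation, equivalent to the explicit
  sort-and-interpolate oracle to ≤ 1e-12 (tested on random vectors of
  lengths 1–50).
- Welch: explicit closed form with p from the t distribution; tested to
  1e-10 against an independent implementation.
- TSV outputs: `inf` / `-inf` literals, `NA` for missing, header always
  present; writes are deterministic, so identical inputs give
  byte-identical tables (the basis of the end-to-end determinism test).
- MTX on disk follows the 10x convention (genes as rows); in-memory
  matrices are spot-major. Duplicate feature symbols are kept and suffixed
  `_1`, `_2`, ... in load order — summing them would corrupt per-gene IQR.
- Barcode matching between matrix and annotation export is exact-string;
  an optional flag strips a trailing GEM-well suffix.

## Problem sizes

The default design (2400 spots, 600 genes) runs the full pipeline in
seconds; the null-calibration check pools six independent replicates of
the design (10 296 Welch tests) to estimate the type-I error rate. These
sizes are the package's desk-scale study conditions; all of them are
configurable upward.

## Known limitations

- The raw-IQR ranking conflates spread with magnitude (discussed above).
- Bonferroni across 6 × 286 tests is deliberately conservative; no FDR
  alternative is offered because the analysis contract specifies
  family-wise control.
- The Welch test on expression fractions ignores the slight dependence
  between genes induced by the shared per-spot denominator.
- Figures are best-effort visual analogs; the tested contract is each
  figure's sidecar TSV, which contains exactly the plotted numbers.
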