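# seedmet

Seed metabolomics and germination-vigor analysis for introgression-line (IL)
populations.

Tomato ILs each carry one defined chromosome segment of the wild species
*Solanum pennellii* in the background of the cultivated line M82, so any
trait difference between an IL and M82 maps that trait to the introgressed
segment — a putative QTL. `seedmet` implements the full analysis chain for a
field trial in which the IL population is grown under fresh-water (SDF) and
saline (SDS) maternal irrigation, dry seeds are profiled by GC-MS, and seed
lots are scored for germination vigor:

1. **Normalization** — raw peak heights to *relative metabolite content*
   (RMC): divide by extracted seed mass, then by the sample's total peak
   sum, then per metabolite by the median within each analytic run block
   (RMC has per-block median 1); natural-log transform; iterative low-rank
   (probabilistic-PCA-style) completion of missing values before the
   multivariate stages.
2. **Germination traits** — per plate: final percent, T50 (first day on
   which cumulative germination reaches 50% of the seeds that eventually
   germinate) and SD-plate (SD of per-seed germination day, a uniformity
   measure); plate means per field plot; salinity response as per-line
   SDS/SDF trait ratios with Welch t-tests.
3. **QTL scans** — Welch t-tests of each IL against M82 per condition
   (f-QTLs under fresh water, s-QTLs under salinity, plus seed weight,
   maturation percent and germination QTLs), SDS-vs-SDF tests within each
   line, and fold-change (FC-) QTLs as the log-scale interaction contrast
   (ΔIL − ΔM82 of the salinity response). Multiplicity per scan by
   Bonferroni (α/n) or the permissive variant **Bcp** (α/√n).
4. **Signed correlation network** — all-pairs Spearman correlations of
   metabolites and germination traits; edges where BH-FDR-adjusted p < 0.05
   and |r| > 0.4; Walktrap communities (|r| as walk weights); each community
   2-colored into an internally positive, mutually negative pair of subsets
   by minimum-frustration search (exact up to 15 nodes, seeded multi-restart
   local search above); subsets assembled across communities into two global
   antagonistic metabolite sets, **ms1** (members correlate negatively with
   germination percent) and **ms2** (positively).
5. **Vigor integration** — PCA of the log-RMC matrix, k-means clustering of
   plots (k = 3), chi-square enrichment of non/intermediate/well germination
   groups (0%, 1–94%, ≥95%) across clusters, and per-metabolite Welch
   contrasts of well- vs non-germinating plots with linear-scale fold
   differences.

A first-class **synthetic-data generator** reproduces the statistical
structure this analysis assumes — 72 ILs + M82, five replicate plots per
line × treatment, 65 metabolites drawn from a multivariate normal with two
anti-correlated latent sets, run-block and sample-load multiplicative
factors, planted QTL effects, and germination driven by the per-plot balance
score (mean latent ms2 − mean latent ms1) — with full ground truth, so the
whole pipeline runs and validates itself without any external data.

## Worked example

The salinity-response operation reproduces published germination
fold-changes from the line-level trait means bundled as the worked example:

```python
>>> from seedmet import fold_change_table, germination_line_means
>>> fc = fold_change_table(germination_line_means("SDF"),
...                        germination_line_means("SDS"))
>>> print(fc.round(3))
         fc_percent  fc_t50  fc_sd_plate
line
M82           0.954   1.286        1.820
IL1-1-3       1.186   0.616        0.631
IL2-1-1       1.021   0.833        0.660
IL2-5         0.931   1.000        0.939
IL3-4         1.155   1.000        1.388
IL4-1         1.037   1.000        0.579
IL8-3-1       1.029   1.000        1.741
IL11-4        0.967   0.857        1.750
```

Each entry is the ratio of a line's trait mean in SDS over SDF: M82's
germination percent drops 4.6% under saline maternal irrigation
(fc_percent 0.954) while its T50 slows by 29% (fc_t50 1.286); IL1-1-3
instead *improves* under salinity (fc_percent 1.186, faster T50).

The full pipeline on a synthetic dataset:

```sh
seedmet run-all --seed 1 --out out/
```

runs simulate → normalize → germination traits → QTL scans → network →
integration and writes TSV artifacts plus a manifest. With the default
configuration (seed 1) it reports, among others: the two per-condition
networks each keep all 65 metabolites plus the 3 germination traits
(68 nodes, ≈2200 signed edges); the global bipartition assigns 40
metabolites to ms1 and 25 to ms2, exactly the planted sets; all 131
germination-trait edges in the SDF network obey the ms1/ms2 sign rule; the
f-QTL map calls 8 planted loci with zero spurious calls at Bonferroni; and
the three k-means clusters separate germination groups sharply (one cluster
holds every non-germinating plot, χ² = 642.4, df = 4, p < 10⁻¹⁰⁰).

The same run from Python:

```python
from seedmet import PipelineConfig, run_pipeline
artifacts = run_pipeline(PipelineConfig(seed=1), "out")
```

Real data are supplied as three TSV tables (`peaks.tsv`, `morphology.tsv`,
`germination.tsv`; schemas in the module docstrings) via the config's input
paths instead of the simulate block.

## Layout

| module | contents |
|---|---|
| `seedmet.synthetic` | study-design config, latent/peak/germination/morphology generators, ground truth |
| `seedmet.normalize` | peak-table I/O, RMC normalization, log transform, imputation |
| `seedmet.germination` | plate measures, plot aggregation, salinity fold-changes, group classification |
| `seedmet.qtl` | Welch t, multiplicity rules, trait/treatment/FC QTL scans |
| `seedmet.network` | Spearman matrix, BH-FDR, signed graph, Walktrap, frustration bipartition, ms1/ms2 |
| `seedmet.integrate` | PCA, k-means, cluster enrichment, germination-group contrasts |
| `seedmet.pipeline` / `seedmet.cli` | end-to-end orchestration, YAML config, `seedmet` CLI |
| `seedmet.recovery` | ground-truth recovery scoring used by tests and the acceptance script |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
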