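# epimemory

A tested pipeline for studying gestational-age (GA)-related DNA methylation
in cord blood, its relation to transcription, and "epigenetic memory"
candidates whose methylation persists into postnatal blood — plus a
synthetic-cohort generator that plants every signal the pipeline is
designed to detect, so each stage can be validated against ground truth.

## What it does

1. **Covariate screen** — univariate and multivariate association of
   prenatal covariates with GA and birth-weight SD score, with two-SD
   (Gelman) scaling of continuous covariates.
2. **Preprocessing** — beta computation from allele intensities
   (`M / (U + M + 100)`), ordered probe filtering (non-CpG, sex
   chromosomes, detection p, beadcount, blacklists) with a reconciled
   removal report, and reference-based cell-fraction estimation by
   constrained least squares (non-negative, sum ≤ 1; optional sum = 1).
3. **Dual-model EWAS** — per-CpG OLS of %methylation on GA + SD score
   under two adjustment sets (Model 1: sex, batch, cell fractions;
   Model 2: plus six prenatal covariates), Benjamini–Hochberg FDR per
   coefficient family, direction-consistent model intersection,
   single-covariate sensitivity fits, and CpG-island-relation enrichment.
4. **Gene sets** — direction-stratified promoter gene lists (≥ 2
   supporting CpGs per gene) and one-sided hypergeometric enrichment
   against GMT collections.
5. **Integration** — CpG-to-expression-probe matching within ±250 kb
   (boundary inclusive), transcript association models, and per-pair
   Pearson methylation–expression correlation with promoter
   concordant/discordant calling (negative r = concordant).
6. **Memory & chromatin** — cord–postnatal per-CpG correlation across
   paired subjects (candidates at r ≥ 0.7), the draw-interval
   confounding check, 25-state chromatin distribution/enrichment
   (two-sided Fisher, Bonferroni 0.05/25, Haldane–Anscombe CIs for zero
   cells), correlation-decile enrichment trends, region cross-correlation
   maps, and overlap/gene ranking of memory candidates against
   expression-correlated CpGs.
7. **Synthetic data** — a miniature cohort (defaults: 110 cord samples,
   47 paired postnatal, 55 with expression, GA 23–41 weeks) with
   GA-associated CpGs in both directions, GA-dependent cell composition,
   tunable cord–post correlation for memory CpGs, signed CpG–transcript
   links on a toy genome, and a full ground-truth table.

## Run the tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (FDR control,
parameter recovery, confounding neutralization, deconvolution accuracy,
enrichment-trend behaviour, count conservation), each implemented as a
simulation against planted ground truth.

## CLI

```sh
# generate a synthetic dataset with ground truth
epimemory simulate --outdir data/ --seed 1

# run everything on it
epimemory run --datadir data/ --outdir out/

# individual stages
epimemory covariates --sheet data/sample_sheet.csv --outcome GA --out eff.tsv
epimemory preprocess cellfrac --beta data/beta_cord.tsv \
    --reference data/reference_profiles.tsv --out cf.tsv
epimemory ewas fit --beta data/beta_cord.tsv --sheet data/sample_sheet.csv \
    --cellfrac cf.tsv --model model1 --out r1.tsv
epimemory ewas consensus --r1 r1.tsv --r2 r2.tsv --out-prefix consensus
epimemory memory score --cord data/beta_cord.tsv --post data/beta_postnatal.tsv \
    --sheet data/sample_sheet.csv --out memory.tsv
```

Exit codes: 0 success, 2 validation error, 3 computation error.

`epimemory run` writes one TSV per stage plus `run_manifest.json`
recording the config snapshot, per-stage SHA-256 output digests and the
stage count summary; reruns with identical inputs reproduce identical
digests.

## File formats

* **Beta / expression matrices** — TSV, probes × samples, first column
  `probe_id` / `expr_probe_id`. Betas must lie in [0, 1) (exactly 1.0 is
  impossible given the +100 offset); expression is log2 scale, ≥ 0.
* **Sample sheet** — CSV with columns `sample_id, subject_id, tissue
  (cord|postnatal), ga_weeks, bw_sd_score, sex (male|female), batch,
  maternal_age, maternal_bmi, paternal_age, paternal_bmi, parity_gt0,
  cesarean, art, smoke_before, gdm, cam, iprom, preeclampsia, previa,
  postmenstrual_age_at_draw, interval_weeks` (interval only for
  postnatal rows).
* **CpG manifest** — TSV: `probe_id, chrom, pos` (1-based),
  `gene, gene_region (TSS200|TSS1500|UTR5|FirstExon|Body|UTR3|IGR)`,
  `island_relation (Island|Shore|Shelf|OpenSea)`, `chromstate_T,
  chromstate_B` (25-state labels). BED inputs are converted to 1-based
  points on load.
* **Expression manifest** — TSV: `expr_probe_id, chrom, pos, gene`.
* **Reference profiles** — TSV, CpGs × 7 cell types
  (CD4T, CD8T, NK, B, Gran, Mono, nRBC).
* **Gene sets** — GMT (set name, description, genes, tab-separated).
* All stage outputs are tab-delimited with fixed column orders (header
  first), written with `\n` line endings for bit-stable reruns.

## Reproducibility

All randomness flows through `numpy.random.default_rng` (PCG64) seeded
with `(design.seed, stage_index)`, so each generator stage has an
independent deterministic stream and full datasets are byte-identical
across runs and platforms for a fixed seed.
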