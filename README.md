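# twinewas

An epigenome-wide association pipeline for discordant monozygotic (MZ) twin
pairs and lung function. Within each genetically identical pair, the twin
with the higher lung-function z-score is labelled *superior*; every analysis
quantity (methylation M value, covariates, outcome) is differenced superior
minus inferior, cancelling genetic and shared-environment confounding, and
each methylation probe is regressed on the transformed z-score difference.

The package contains:

| module | role |
|---|---|
| `twinewas.synthetic_data` | cohort / methylome / manifest / LMS / gene-set generators with planted effects |
| `twinewas.standardization` | LMS-based spirometry z-scores (zFEV1, zFVC, zFEV1/FVC) and change scores |
| `twinewas.twin_design` | superior/inferior ordering, intra-pair differences, predictor transform |
| `twinewas.methylation` | probe QC (bead count / detection p / zero signal / blacklist), beta–M transforms, reference-based leukocyte deconvolution |
| `twinewas.ewas` | mass univariate pair-difference OLS, BH-FDR, genomic inflation, direction labels, hit selection, Manhattan/QQ tables |
| `twinewas.enrichment` | hypergeometric over-representation analysis (C/O/E/R/rawP/adjP) against the array gene universe |
| `twinewas.pipeline_cli` | orchestration of the six analyses (3 metrics × cross-sectional/longitudinal) and the `twinewas` CLI |

No cohort data ship with the package: `synthetic_data` generates inputs with
the statistical structure the analysis assumes (MZ constraints, bimodal
betas, within-pair correlation, five-cell mixtures, smoking discordance,
planted probe-level associations), so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic input bundle (phenotypes, beta/QC matrices, manifest,
# blacklist, LMS table, cell panel + counts, gene sets, truth sidecar)
twinewas simulate --out bundle/ --seed 1 --n-probes 2000 --n-planted 25 \
    --planted-metric zFEV1 --planted-slope -0.3

# run all six analyses: standardization -> QC -> cell fractions ->
# pair designs -> EWAS -> enrichment -> Manhattan/QQ tables
twinewas run --in bundle/ --out run/

# summary tables (demographics, per-analysis hits, enrichment)
twinewas report --run-dir run/ --in bundle/ --out report/

# individual stages
twinewas zscores --in bundle/ --out z/
twinewas qc --in bundle/ --out qc/
```

All outputs are TSV with `#`-prefixed provenance headers plus a
`run_manifest.json` with SHA-256 checksums; reruns from the same seed are
byte-identical.

## Conventions

- M value = log2(beta / (1 − beta)); beta clipped to [1e-6, 1 − 1e-6].
- Probe removal: failed (beads < 3, detection p > 0.01, or zero/missing
  signal) in strictly more than 5% of samples, or blacklisted.
- Predictor transform: natural log of the z difference for zFEV1/zFVC and
  their changes; identity for the FEV1/FVC ratio metrics.
- Thresholds (strict): p < 1e-6 significant, p < 1e-5 tabled, BH-FDR at 0.05.
- Direction: estimate < 0 → inferior twin relatively **Hyper**-methylated.
- Cell fractions: non-negative sum-to-one least squares against a five-cell
  reference panel; neutrophils serve as the reference category in the
  regression design.
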