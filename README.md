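# mascsig

Tools for deriving a stem-cell gene-expression signature from purified
mammary epithelial populations, scoring its activation in breast-tumour
cohorts, and testing whether high activation stratifies survival.

Mammary stem cells (MaSC) are a rare basal subpopulation; their
transcriptional programme — enriched for cell migration, cytoskeletal
regulation and epithelial/mesenchymal co-expression — overlaps the
biology of aggressive triple-negative breast cancers (TNBC). The
analysis chain this package implements answers three questions:

1. **Which genes are stem-cell-specific?** SAM-style moderated statistics
   d = Δx̄/(s + s0) with permutation-based local FDR, run for the stem
   cells against each other purified population; the signature is the
   intersection of up-calls at local FDR < 5% and fold change ≥ 1.5,
   with a ≥ 2.5-fold top refinement against myoepithelial and pooled
   luminal cells.
2. **Is the programme active in a tumour?** A per-tumour activation
   score: the median-centred average of signature-gene expression, or a
   relevance-network variant that first prunes signature genes
   inconsistent with the signature's cohort-wide correlation structure.
3. **Does activation predict outcome?** Top-tertile or median
   dichotomisation followed by Kaplan-Meier, log-rank and univariate Cox
   (HR with Wald 95% CI) — plus an expression-matched random-gene-list
   permutation null that re-runs the whole scoring pipeline on 1000
   size- and expression-matched random signatures, so significance is
   judged against what *any* comparable gene list could achieve.

Single-cell RT-qPCR utilities (spike-in linearity, ΔΔCt, 1/Ct
heterogeneity and two-gene co-expression contingencies), nearest-centroid
subtype classification and hypergeometric gene-list overlap complete the
chain. Synthetic-data generators with planted ground truth make every
stage testable without any external download; see `docs/methods.md` for
models, defaults and limitations.

## Worked example

Simulate the four-population replicate design (7 stem-cell, 3
myoepithelial, 3 + 3 luminal arrays; 100 planted stem-cell genes at
4-fold, 100 basal-shared decoys, 100 luminal-specific, 700 null), then
derive the signature:

```sh
$ mascsig simulate-populations --n-genes 1000 --seed 1 --out-dir pops
wrote 1000 genes x 16 samples to pops
$ mascsig derive-signature --matrix pops/expression.tsv \
    --labels pops/populations.csv --n-perm 200 --seed 1 --out-dir derived
signature: 92 genes; top refinement: 92 genes
```

The 92 derived genes are all planted stem-cell-specific genes (92%
sensitivity); none of the 100 basal-shared decoys — genes high in both
stem cells and myoepithelium — slip through, because the intersection
demands up-regulation against *every* other population.

Score a simulated tumour cohort whose hazard depends on the latent
signature activation (β = 1.1), stratify, and run the matched null:

```sh
$ mascsig simulate-cohort --n-tumours 500 --beta 1.1 --seed 2 --out-dir cohort
wrote cohort of 500 tumours to cohort
$ mascsig prognose --matrix cohort/expression.tsv \
    --survival cohort/survival.csv --signature cohort/signature.txt \
    --n-lists 1000 --seed 3 --out-dir prog
log-rank chi2=241.480 p=1.87e-54; HR=5.668 CI=(4.456, 7.209); matched-null p=0.000999
```

Top-tertile tumours carry a 5.7-fold event hazard; the matched-null
p = 1/1001 (the add-one minimum) says none of 1000 expression-matched
random gene lists stratified the cohort as strongly.

Every subcommand (`simulate-populations`, `simulate-cohort`,
`simulate-cells`, `derive-signature`, `score`, `prognose`, `subtype`,
`single-cell`, `overlap`) is a thin wrapper over the library
(`mascsig.diffexpr`, `mascsig.scoring`, `mascsig.survival`, …); all
thresholds and seeds are flags or YAML config keys, and every artefact
carries a `#`-prefixed provenance header.

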