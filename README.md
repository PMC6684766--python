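# tcrpair

Paired αβ T cell receptor (TCR) repertoire analysis: how much does the
pairing of an α and a β chain tell you about a T cell's lineage (CD4
helper vs CD8 cytotoxic) and its antigen specificity?

Single-cell sequencing yields both chains of each cell's receptor.
`tcrpair` takes a table of paired clonotypes (or simulates one with
known planted structure), applies standard exclusion rules, deduplicates
to unique clonotypes, and runs five analyses:

- **Overlap** — Jaccard sharing of unique clonotypes between the CD4 and
  CD8 repertoires, separately for α chains, β chains, and whole αβ
  pairs, with a product-rule diagnostic and a CDR3-length comparison of
  shared vs lineage-exclusive clones.
- **Association** — CD4:CD8 odds-ratio scans over V/J genes, gene pairs,
  CDR3 charge and length, with exact two-sided hypergeometric p-values,
  Woolf confidence intervals, and Bonferroni or q-value control.
- **Information** — mutual information (bits) between TCR features and
  lineage with a subsampling-extrapolation correction for finite-sample
  bias, and the αβ synergy S = I(Xα,Xβ;L) − I(Xα;L) − I(Xβ;L).
- **Classification** — gradient-boosted lineage classifiers on α, β,
  concatenated-pair, and additive-ensemble feature encodings, compared
  by repeated stratified cross-validation; the paired model can only
  beat the additive ensemble if pairing itself carries information.
- **Annotation** — matching chains against a VDJdb-style specificity
  database and classifying each pair as matched-epitope, same-species /
  different-epitope, or different-species.

A seeded synthetic generator plants all of these signals (per-gene
log-odds effects, Vα×Vβ interactions, charge/length effects, clones
shared between lineages, dual-receptor and unlabeled cells, annotation
fixtures), so every estimator is tested against known ground truth.

## Worked example

Simulate a 5,000-cell repertoire under the reference conditions and look
at CD4/CD8 sharing:

```console
$ tcrpair simulate --seed 7 --n-cells 5000 --out cells.tsv
wrote 5000 cells to cells.tsv

$ tcrpair overlap cells.tsv
excluded: {'dual_receptor': 89, 'no_lineage': 143}
scope   jaccard                 overlap_percent      n_shared  n_cd4_only  n_cd8_only
alpha   0.07391910739191074     7.391910739191074    212       1737        919
beta    0.0404138376980278      4.04138376980278     125       1925        1043
paired  0.009292565947242206    0.9292565947242206   31        2135        1170
```

Single chains are shared between lineages an order of magnitude more
often than whole αβ pairs — each chain alone under-determines the
receptor. The Vα odds-ratio scan recovers the planted TRAV1 enrichment
in CD4 (true effect log 2, Bonferroni-adjusted):

```console
$ tcrpair associate cells.tsv --feature v --chain alpha
feature  odds_ratio          p                       adjusted                significant
TRAV1    1.8497393451618804  2.3426152267997073e-09  7.027845680399122e-08   True
TRAV10   0.8117020764079588  0.30629729535792083     1.0                     False
TRAV11   0.6670542525736649  0.07841105086280589     1.0                     False
...
```

The information profile quantifies how much V-gene usage tells you about
lineage, and how much the αβ *pairing* adds beyond the two chains:

```console
$ tcrpair info cells.tsv --features v --n-boot 20 --seed 7
feature_type  mi_alpha             mi_beta              mi_sum               mi_paired            synergy
v             0.013116883501927275 0.017968136574392612 0.031085020076319886 0.04554601278719315  0.014460992710873262
```

Other subcommands: `tcrpair classify` (cross-validated AUC per mode),
`tcrpair annotate` (specificity concordance against a VDJdb-dialect
TSV), and `tcrpair run` (the full seeded pipeline, writing every table
plus a `manifest.json` with per-stage summaries and output checksums).

## Input format

A tab-separated table with one row per cell:

```
cell_id  subject  lineage  v_a  j_a  cdr3_a  v_b  j_b  cdr3_b  [n_alpha_chains  n_beta_chains]
```

`lineage` is `CD4`, `CD8`, or anything else (treated as unlabeled and
excluded). CDR3 sequences are amino acids inclusive of the flanking
C/F residues; allele suffixes on gene names (`TRAV1-2*01`) are stripped.
Column names can be remapped with a dialect mapping
(`read_clonotype_table(path, dialect=...)`). Cells with more than one α
or β chain are excluded as dual-receptor; analyses operate on unique
clonotypes (V gene + CDR3 per chain; J is excluded from the identity key
and re-included only for J-specific scans).

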