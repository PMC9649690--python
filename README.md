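# txaxes

Transcript-resolution analysis of cancer cell-line panels: which
transcripts are lineage specific, which are regulated by RNA-binding
proteins (RBPs), which predict anti-cancer drug sensitivity — and how those
three layers join into RBP–transcript–drug axes.

The package is aimed at computational biologists who work with
transcript-level expression matrices (TPM) across annotated cell-line
panels together with knockdown / binding assays and drug-response (AUC)
panels. Because the real inputs are consortium scale, `txaxes` ships a
first-class synthetic-data module that emulates their statistical structure
with planted ground truth, so every stage is testable end to end on a
laptop.

## What it computes

**Lineage specificity.** For transcript *t* with aggregated expression
*x<sub>it</sub>* in lineage *i* (of *N*), the expression ratios are
*p<sub>it</sub> = x<sub>it</sub> / Σ<sub>i</sub> x<sub>it</sub>* and the
specificity score is

  S<sub>t</sub> = log₂(N) − ( −Σ<sub>i</sub> p<sub>it</sub> log₂ p<sub>it</sub> )

i.e. log lineage count minus the Shannon entropy of the ratio
distribution: 0 for uniform expression, log₂ N for single-lineage
expression. A transcript is called lineage specific when its top ratio
exceeds twice the second AND S<sub>t</sub> > 1.

**RBP–transcript regulatory network.** An edge RBP → transcript requires
both |fold change| > 1.5 with FDR < 0.05 upon knockdown of the RBP *and*
at least one of that RBP's binding peaks overlapping the transcript's
exons. Edge direction is the sign of the knockdown response.

**Transcript–drug association.** Per drug: Spearman prefilter
(|ρ| > 0.2, BH FDR < 0.05), per-transcript standardization, elastic-net
hyperparameter search (25 random (α, λ) candidates, 5×10-fold CV minimizing
RMSE), then B bootstrap resamples of the cell lines refit with the tuned
penalty. With F[β>0] and F[β<0] the counts of resamples giving a positive /
negative coefficient, the predictive score is |F[β>0] − F[β<0]| / B; pairs
scoring ≥ 0.7 are called associations.

**Axes.** The relational join of network edges and called associations on
transcript id: a transcript regulated by *r* RBPs and associated with *d*
drugs contributes *r × d* axes.

A transcript-annotation module classifies assembled transcripts against a
reference (exact chain match, junction sharing, intron retention,
within-intron, exon overlap, intergenic), flags readthrough transcripts
(exonic overlap with ≥ 2 same-strand genes), assigns `<gene>-a<k>` /
`<gene>-u<k>` names, and scores CAGE / chromatin transcription evidence in
a ±500 nt window around each TSS.

## Worked example

```sh
python examples/01_lineage_specificity.py
```

```
transcripts scored:          2000
max possible score log2(22): 4.459
lineage-specific calls:      200
planted transcripts found:   200/200 (recall 1.00)
example: TX0006 score=2.32 called=lineage16 (planted: lineage16)
```

2000 synthetic transcripts over 110 cell lines in 22 lineages were scored;
all 200 transcripts planted with an 0.8 home-lineage expression share are
recovered by the entropy score plus 2×-ratio rule, each in its planted
lineage, and no exactly-uniform null transcript is called.

The other examples cover transcript classification (`02`), the regulatory
network (`03`), drug association (`04`), and the full pipeline (`05`). The
CLI mirrors the stages:

```sh
txaxes run --config examples/demo_config.yaml -o runs/demo
```

which writes per-stage TSV tables plus `manifest.json` (seeds, thresholds,
per-stage counts) into `runs/demo`; rerunning with the same config and seed
reproduces every table byte for byte.

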