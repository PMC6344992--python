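# dlocal

Analysis of sub-cellular RNA localization from paired soma/dendrite
RNA-seq of single neurons: which transcripts are dendritically localized,
whether localization is isoform-specific via alternative 3'UTRs, and which
cis-elements (G-quadruplexes, RBP motifs, B1/B2 SINE hairpins) are enriched
in the localized sequences.

It is written for transcriptomics researchers who have (or simulate)
per-feature read counts from paired sub-cellular samples — each cell
contributing one somatic and one dendritic library — and want the full
chain from annotation to motif enrichment as reusable, tested components.

## The statistics at the core

For a gene with counts *d* (dendrite) and *s* (soma) in one cell, the
**dendritic read fraction** is f = d/(d+s); its cross-cell variance
measures localization variability, with a binomial read-downsampling
control for depth effects.

Three localized gene sets are called:

* **deDend** — concentration-enriched in dendrites: exact paired Wilcoxon
  signed-rank test on per-cell differences of size-factor-normalized
  counts, BH-corrected q ≤ 0.05, positive median difference.
* **consDend** — constitutively present: ≥ 1 read in ≥ 90% of dendrite
  samples.
* **isoDend** — isoform-specific: for the top two 3' isoforms of a gene,
  the **distal fraction** DF = distal/(distal+proximal) is computed per
  sample (≥ 10 combined reads), ΔDF = DF_dendrite − DF_soma per cell, and a
  gene is called when the exact Wilcoxon p of its ΔDF vector is < 0.1 over
  ≥ 5 valid pairs. Pairs are classed ALE or tandem from the full-length
  3'UTR geometry.

Motif enrichment uses one hit per gene, Fisher's exact test, and a
background of soma-enriched genes greedily matched within 100 nt of each
foreground gene's 3'UTR length. B1/B2 SINE hairpins are detected by
single-exemplar covariance models (profile SCFGs scored by CYK dynamic
programming in bits; cutoffs 50/35). See `docs/methods.md` for the full
model descriptions.

## Worked example

Simulate a paired study and run the gene- and isoform-level callers:

```python
from dlocal.simulate import SimScenario, simulate_study
from dlocal.quantify import call_de, call_consdend
from dlocal.isoforms import analyze_isoforms, preference_summary

bundle = simulate_study(SimScenario(), seed=42)     # 1000 genes, 16 cells

gene_counts = bundle.matrix.gene_level()
de = call_de(gene_counts)
print((de["call"] == "deDend").sum(), "deDend genes")
print(len(call_consdend(gene_counts)), "consDend genes")

res = analyze_isoforms(bundle.matrix, bundle.features,
                       gene_models=bundle.gene_models)
print(int(res.records["isodend"].sum()), "isoDend genes of",
      int(res.records["p"].notna().sum()), "tested")
print("distal-preference odds ratio:",
      round(preference_summary(res.records)["odds_ratio"], 2))
```

Output for this seed:

```
52 deDend genes
859 consDend genes
157 isoDend genes of 668 tested
distal-preference odds ratio: 1.29
```

All 50 planted dendrite-enriched genes plus two false positives pass the
paired test; 668 multi-isoform genes have enough paired coverage to be
tested and 157 are called isoform-specific (98 of the 100 planted, the
rest false positives at the permissive α = 0.1 the isoform screen uses).
The odds ratio above 1 reflects the planted bias of shifted genes toward
the distal isoform, diluted by those false positives. The same steps run
from the shell:

```bash
dlocal simulate --seed 42 --out sim/
dlocal de --counts sim/counts.tsv --samples sim/samples.tsv --out de.tsv
dlocal isodend --counts sim/counts.tsv --samples sim/samples.tsv \
    --gtf sim/annotation.bed --out isodend.tsv
```

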