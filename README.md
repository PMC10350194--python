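# trap-rescue

Analysis pipeline for TRAP-Seq translatome rescue experiments: which
ribosome-associated transcripts are altered when a receptor's intracellular
domain (ICD) is missing, and which of them return toward wild type when the
soluble ICD is reintroduced?

The concrete design it implements crosses four Apoer2 genotypes — wild type
(`WT`), conditional knockout (`cKO`), and two cleavage-resistant knock-ins
(`KI_plus19`, `KI_delta19`) — with three lentiviral treatments (`Cre` only,
or Cre plus one ICD splice variant, `ICD_plus19` / `ICD_delta19`). Sequencing
data are replaced by a first-class synthetic generator with per-gene ground
truth, so every stage of the inference chain is verifiable at desk scale.

## The statistics at the core

For gene g in mutant genotype *geno* with ICD variant *icd*, three
negative-binomial Wald contrasts are fit (log link, median-of-ratios offsets,
method-of-moments dispersion, no fold-change shrinkage):

* **A** = (geno, Cre) vs (WT, Cre) — the baseline genotype effect
* **B** = (geno, icd) vs (geno, Cre) — the ICD effect within the genotype
* **C** = (geno, icd) vs (WT, Cre) — distance from wild type under treatment

A gene is **basal** when |log2FC_A| > 0.56 and p_A < 0.05. A basal gene is
**rescued** by an ICD when

    |log2FC_C| < |log2FC_A|   and   min(1, (p_A + p_B)^2 / 2) < 0.05,

the second term being the combined genotype-rescue p-value. Per-ICD statuses
fold into the categories `rescued_both`, `rescued_plus19_only`,
`rescued_delta19_only`, `not_rescued`. Genes without a basal call but shifted
by an ICD within their genotype are genotype-independent ICD effects.
Upstream, reads overlapping annotated UTRs are filtered from alignments
(3'-bias correction for amplified RNA) before unique-gene counting;
downstream, supervenn-style set partitions, a relaxed common-module criterion
(|log2FC| > 0.5 in all genotypes), complete-linkage clustering and
hypergeometric gene-set enrichment summarize the calls. See
`docs/methods.md` for the full model.

## Worked example

```sh
trap-rescue run-all --out-dir results/demo --seed 7
```

or, stepwise, the numbered drivers:

```sh
python analysis/01_simulate.py        # truth + design + counts
python analysis/02_filter_count.py    # UTR filter demo on a toy alignment
python analysis/03_differential.py    # 17 NB Wald contrast tables
python analysis/04_classify_rescue.py # rescue categories + truth confusion
python analysis/05_set_overlap.py     # supervenn partition, common module
python analysis/06_enrichment.py      # enrichment against truth-label sets
```

On the default synthetic study (2000 genes, 4 replicates/condition, seed
20260930) the drivers print, among other lines:

```
cKO: 544 basal genes (267 up, 277 down); 86.2% rescued by >=1 ICD;
     categories {'rescued_both': 323, 'rescued_plus19_only': 76,
                 'not_rescued': 75, 'rescued_delta19_only': 70}
basal-significant union across genotypes: 605 genes; 520 significant in all three
relaxed common module: 259 up, 264 down
  truth_rescued_both: overlap 200/200, q = 6.45e-189
```

Reading: of the 544 transcripts altered at baseline in the knockout, 86%
move back toward wild type under at least one ICD variant; all 200 genes
simulated as fully rescued by both variants are recovered in the
`rescued_both` query set (the enrichment q-value is the BH-adjusted
hypergeometric tail); and the three mutant genotypes share a common
regulatory module of ~520 genes, as simulated.

The CLI also exposes each stage on real inputs: `simulate`, `filter-utr`,
`count`, `de`, `classify`, `sets`, `enrich`, `run-all` (see `--help`).
Counts are TSV (genes x samples), designs TSV, alignments SAM/BAM,
annotations GTF, gene sets GMT.

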