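# Methods

## The analysis in one paragraph

TRAP (translating ribosome affinity purification) isolates ribosome-associated
mRNA from genetically marked hippocampal cells, giving a translatome rather
than a transcriptome readout. The study design crossed four Apoer2 genotypes —
wild type (`WT`), a conditional knockout (`cKO`), and two cleavage-resistant
knock-ins (`KI_plus19`, `KI_delta19`, i.e. Δ16 with or without exon 19) — with
three lentiviral treatments: Cre only (`Cre`), or Cre plus one splice variant
of the Apoer2 intracellular domain (`ICD_plus19`, `ICD_delta19`). A transcript
altered at baseline in a mutant (mutant+Cre vs WT+Cre) is *rescued* by an ICD
variant when reintroducing the soluble ICD moves its ribosome loading back
toward wild type. This package implements that entire inference chain —
UTR-filtered counting, negative-binomial (NB) differential testing over the
contrast lattice, the combined genotype-rescue p-value, and the rescue
categories — against synthetic data with known ground truth.

## Count model and simulator

Counts are NB with variance mu + alpha\*mu^2; the same parameterization is
assumed by the testing stage, so simulator and tests cannot silently
disagree. Effects are additive on the log2 scale. For gene g in genotype
geno under ICD treatment icd the expected count at unit depth is

    mu = base_mean * 2^( beta_geno * (1 - rho_geno_icd) + gamma_icd )

where `beta` is the baseline genotype effect (log2), `rho` in [0,1] the
rescue fraction (1 = full return to wild type), and `gamma` a
genotype-independent ICD effect applied in every genotype, including WT.
Rescue as multiplicative shrinkage of `beta` makes the downstream criterion
("smaller |log2FC| vs wild type") literally true of fully rescued genes.

Generator defaults (the study conditions for all tests and the acceptance
run): 2000 genes; 4 replicates per condition — the paper-scale cohort of
6–9 animals per genotype splits across three treatments to roughly this
many — with per-sample depth multipliers log-uniform in [0.5, 2] so that
normalization is actually exercised; base means log-normal (median 150,
sigma_log = 1); dispersion 0.05, typical of bulk brain RNA-Seq; baseline
effects |beta| = 1.5 with random sign, shared across the three mutant
genotypes (which gives the cross-genotype set operations non-trivial
structure); full rescue rho = 1, none rho = 0. Truth labels: `null` (69%),
`basal_only` (5%, partial rescue rho = 0.5 — genes whose ICD response is
real but incomplete), `rescued_both` (10%), `rescued_plus19_only` /
`rescued_delta19_only` (3% each), `not_rescued` (5%), `icd_effect_only`
(5%, |gamma| = 1.0). Label allocation is exact by construction
(`round(G * proportion)` genes per label), not a stochastic draw.

What the simulator does **not** model: read sequences, positional bias
beyond whole-read UTR placement, correlated genes, batch structure,
sample-level outliers, or genotype-specific effect sizes. Passing the
recovery tests therefore demonstrates that the decision procedure is
correct and well calibrated under its stated model, not that real
hippocampal data meet that model.

## UTR filter and counting

Amplified RNA is 3'-biased, so reads overlapping annotated UTRs are removed
before counting. "Overlapping" is >= 1 bp of any aligned block against any
UTR interval (5' or 3'); whether the original filter used partial or full
containment, or excluded 5'UTRs, is not decidable from its description, so
both choices are explicit flags (`--utr3-only`; containment is not offered —
partial overlap is the conservative reading). Strand is ignored by default
(`--stranded` enables matching). Counting assigns a read to a gene only if
it overlaps intervals of exactly that one gene; multi-gene reads are
dropped, matching the default of the standard counting tools. GTF
coordinates (1-based inclusive) are converted to 0-based half-open exactly
once at parse time; bare GENCODE-style `UTR` features are classed 5' or 3'
from their position relative to the CDS span and the strand.

## Differential testing

* **Size factors** — median-of-ratios to the geometric-mean pseudo-reference,
  over genes with no zero count; a `pseudo_reference` flag switches to a
  nonzero-entry geometric mean for sparse matrices.
* **Dispersion** — method of moments on normalized counts:
  alpha = max(1e-8, (pooled within-condition variance - mean)/mean^2),
  variances pooled across all 12 conditions weighted by degrees of freedom
  (36 df at 4 replicates), estimated once and shared by every contrast.
  This trades the sophistication of shrinkage estimators for transparency;
  at 36 df the estimates are stable enough that the Wald test holds its
  nominal size (verified in the calibration tests).
* **Wald test** — per gene and contrast, a two-group NB fit with log link,
  offsets log(size factor) and fixed alpha, solved by Fisher scoring
  (score sum (y - mu)/(1 + alpha mu), information sum mu/(1 + alpha mu)).
  log2FC = (beta_num - beta_den)/ln 2, SE from the inverse information of
  both groups, two-sided normal tail. No fold-change shrinkage: the rescue
  rule compares absolute fold changes across contrasts, and shrinkage
  strength varying with group size would bias that comparison. Genes with
  zero counts throughout either group are flagged not-testable rather than
  dropped (their log fold change is unbounded). BH q-values are computed
  per contrast with not-testable genes excluded from the test count.

## Rescue classification

For genotype geno and ICD variant icd, with A = (geno,Cre) vs (WT,Cre),
B = (geno,icd) vs (geno,Cre), C = (geno,icd) vs (WT,Cre):

* **Basal**: up if log2FC_A > 0.56 and p_A < 0.05; down if < -0.56; both
  strict. Raw Wald p is used, per the criterion's wording; a
  `use_adjusted` flag switches every p input to BH q.
* **Combined genotype-rescue p-value**: min(1, (p_A + p_B)^2 / 2) — the sum
  of the baseline and within-genotype ICD p-values, squared, divided by
  their number. The unclamped formula exceeds 1 whenever the sum exceeds
  sqrt(2); a probability must live in [0,1], hence the clamp. Its null
  calibration is characterized empirically in the tests (it is mildly
  anticonservative near 0 relative to a uniform p, which is why it gates
  rescue jointly with the fold-change condition rather than alone).
* **Rescued**: |log2FC_C| strictly smaller than |log2FC_A| (a tie is not a
  rescue — "smaller" read strictly) and combined p < 0.05. An optional
  `strict` mode additionally requires C itself not to be significant by the
  full basal criterion. Genes not testable in B or C are `not_rescued` with
  a missing-data flag.
* **Categories**: `rescued_both`, `rescued_plus19_only`,
  `rescued_delta19_only`, `not_rescued` partition the basal-significant
  genes; all others are `not_applicable`.
* **Genotype-independent ICD effects**: for basal-ns genes, the same
  thresholds applied to B; an `icd_opposite` flag marks genes the two
  variants move in opposite directions.
* **Relaxed common module**: within genes basal-significant in at least one
  genotype, common-up/-down means log2FC beyond ±0.5 in all three, with no
  p requirement on the relaxed members.

Note that a gene with a genuine partial rescue (rho = 0.5 in truth) usually
satisfies the rescue rule — its fold change halves and the combined p is
small. The classifier is a decision procedure about movement toward wild
type, not an estimator of rho.

## Set operations and enrichment

Membership partitioning enumerates all 2^k - 1 patterns over k gene sets
(the supervenn backbone), ordered by descending count then pattern, with
empty patterns reported. Direction concordance buckets genes significant
in all genotypes into all-up / all-down / opposing (keyed by the
disagreeing genotype). Heatmap row ordering uses complete-linkage
agglomerative clustering with Euclidean distance on log2FC matrices (not
counts), via scipy; complete linkage admits no height inversions, and
scipy's ordering is deterministic for our inputs; missing values are
imputed as 0 with a warning. Dendrograms are exported as Newick.
Enrichment is a one-sided upper-tail hypergeometric test per GMT set with
BH across sets; the universe defaults to the testable genes of the DE
stage, not all annotated genes, to avoid detection-bias inflation.

## Contrast lattice

With all four genotypes present the pipeline builds 17 contrasts: 11
against (WT, Cre) — three per mutant genotype plus the two WT ICD
conditions — and 6 within-genotype ICD contrasts, which the combined
p-value requires. A missing condition fails validation with every
unbuildable contrast named.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; no global RNG state is used.
Tables are written with a fixed float format, so identical configs and
seeds reproduce byte-identical artifacts, checked via SHA-256 in the run
manifest. The default test and acceptance problem sizes (2000 genes, 48
samples, 17 contrasts; 10,000 genes only for the Poisson mean check) keep
a full run to a couple of seconds while leaving every calibration
assertion comfortably powered; these sizes are the package's chosen study
scale for desk verification.

## Known limitations

* The dispersion estimator has no shrinkage toward a mean–dispersion
  trend; with fewer than ~3 replicates per condition across few conditions
  it becomes noisy and the Wald test can drift anticonservative.
* The Wald test offers no outlier handling (no Cook's distance) and no
  independent filtering.
* Genes with all-zero counts in one group are not testable rather than
  reported with an infinite fold change; a pseudocount route was rejected
  because it would bias the |log2FC| comparisons that rescue calls rest on.
* The combined p-value is used as the study used it — a decision statistic;
  it is not a calibrated p-value in the Fisher/Stouffer sense and should
  not be interpreted as one.
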