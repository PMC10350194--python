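"""Synthetic TRAP-Seq data with known ground truth.

Counts follow a negative-binomial model, variance = mu + alpha * mu**2, the
same parameterization the differential-expression stage assumes.  Effects are
additive on the log2 scale: a mutant genotype carries a baseline log2 effect
beta relative to (WT, Cre), and an ICD treatment shrinks that baseline
multiplicatively by its rescue fraction rho, so the residual genotype effect
under treatment is beta * (1 - rho).  A genotype-independent ICD effect gamma
adds on top.  This makes the downstream rescue criterion ("smaller log2 fold
change after ICD reintroduction") literally recoverable from the truth table.

Truth labels
------------
null                 no effects at all
basal_only           baseline effect, partial ICD response (rho = partial level)
rescued_both         baseline effect fully reversed by both ICD variants
rescued_plus19_only  fully reversed by ICD[+19] only
rescued_delta19_only fully reversed by ICD[d19] only
not_rescued          baseline effect, no ICD response (rho = 0)
icd_effect_only      no baseline effect, ICD shifts the gene in every genotype
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trap_rescue.design import GENOTYPES, ICD_VARIANTS, validate_design
from trap_rescue.errors import ConfigError, DataError

TRUTH_LABELS = (
    "null",
    "basal_only",
    "rescued_both",
    "rescued_plus19_only",
    "rescued_delta19_only",
    "not_rescued",
    "icd_effect_only",
)

MUTANT_GENOTYPES = tuple(g for g in GENOTYPES if g != "WT")


@dataclass
class SimulationConfig:
    """Ground-truth generator settings.

    ``proportions`` allocates genes to non-null truth labels; the remainder is
    null.  ``baseline_lfc`` is the |log2| magnitude of baseline genotype
    effects (sign drawn at random per gene, shared across the three mutant
    genotypes).  ``icd_lfc`` is the |log2| magnitude of genotype-independent
    ICD effects.  ``full_rescue`` / ``partial_rescue`` are the rescue
    fractions used for fully-rescued and partially-responding genes.
    """

    n_genes: int = 2000
    proportions: dict[str, float] = field(
        default_factory=lambda: {
            "basal_only": 0.05,
            "rescued_both": 0.10,
            "rescued_plus19_only": 0.03,
            "rescued_delta19_only": 0.03,
            "not_rescued": 0.05,
            "icd_effect_only": 0.05,
        }
    )
    baseline_lfc: float = 1.5
    icd_lfc: float = 1.0
    full_rescue: float = 1.0
    partial_rescue: float = 0.5
    dispersion: float = 0.05
    dispersion_log_sd: float = 0.0
    base_mean_log_mean: float = np.log(150.0)
    base_mean_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(TRUTH_LABELS)
        if unknown:
            raise ConfigError(f"unknown truth labels in proportions: {sorted(unknown)}")
        if any(p < 0 for p in self.proportions.values()):
            raise ConfigError("label proportions must be nonnegative")
        if sum(self.proportions.values()) > 1 + 1e-12:
            raise ConfigError(
                f"label proportions sum to {sum(self.proportions.values()):.4f} > 1"
            )
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be nonnegative")


def _rho_columns() -> list[str]:
    return [f"rho_{g}_{icd}" for g in MUTANT_GENOTYPES for icd in ICD_VARIANTS]


def make_truth(config: SimulationConfig) -> pd.DataFrame:
    """Allocate truth labels and per-gene parameters; exact and seed-deterministic.

    Exactly ``round(n_genes * proportion)`` genes receive each non-null label
    (allocation order follows ``TRUTH_LABELS``); remaining genes are null.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    width = len(str(g))
    truth = pd.DataFrame(
        {
            "gene_id": [f"gene{str(i + 1).zfill(width)}" for i in range(g)],
            "label": "null",
        }
    )
    pos = 0
    for label in TRUTH_LABELS:
        if label == "null":
            continue
        k = int(round(g * config.proportions.get(label, 0.0)))
        if pos + k > g:
            raise ConfigError("label proportions allocate more genes than exist")
        truth.loc[pos : pos + k - 1, "label"] = label
        pos += k

    truth["base_mean"] = np.exp(
        rng.normal(config.base_mean_log_mean, config.base_mean_log_sd, g)
    )
    if config.dispersion_log_sd > 0:
        truth["dispersion"] = config.dispersion * np.exp(
            rng.normal(0.0, config.dispersion_log_sd, g)
            - config.dispersion_log_sd**2 / 2
        )
    else:
        truth["dispersion"] = config.dispersion

    signs = rng.choice([-1.0, 1.0], size=g)
    has_beta = ~truth["label"].isin(["null", "icd_effect_only"])
    beta = np.where(has_beta, signs * config.baseline_lfc, 0.0)
    for geno in MUTANT_GENOTYPES:
        truth[f"beta_{geno}"] = beta

    rho_by_label = {
        "basal_only": (config.partial_rescue, config.partial_rescue),
        "rescued_both": (config.full_rescue, config.full_rescue),
        "rescued_plus19_only": (config.full_rescue, 0.0),
        "rescued_delta19_only": (0.0, config.full_rescue),
    }
    for geno in MUTANT_GENOTYPES:
        for j, icd in enumerate(ICD_VARIANTS):
            col = np.zeros(g)
            for label, rhos in rho_by_label.items():
                col[truth["label"].to_numpy() == label] = rhos[j]
            truth[f"rho_{geno}_{icd}"] = col

    icd_signs = rng.choice([-1.0, 1.0], size=g)
    is_icd = (truth["label"] == "icd_effect_only").to_numpy()
    for icd in ICD_VARIANTS:
        truth[f"gamma_{icd}"] = np.where(is_icd, icd_signs * config.icd_lfc, 0.0)

    return truth.set_index("gene_id")


def expected_mean(truth: pd.DataFrame, genotype: str, treatment: str) -> np.ndarray:
    """Per-gene expected count at unit depth for one (genotype, treatment) cell."""
    effect = np.zeros(len(truth))
    if genotype != "WT":
        effect = effect + truth[f"beta_{genotype}"].to_numpy()
    for icd, icd_treat in ICD_VARIANTS.items():
        if treatment == icd_treat:
            if genotype != "WT":
                rho = truth[f"rho_{genotype}_{icd}"].to_numpy()
                effect = effect - truth[f"beta_{genotype}"].to_numpy() * rho
            effect = effect + truth[f"gamma_{icd}"].to_numpy()
    return truth["base_mean"].to_numpy() * np.exp2(effect)


def simulate_counts(truth: pd.DataFrame, design: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Draw the NB count matrix (genes x samples) implied by truth and design."""
    design = validate_design(design)
    if (truth["base_mean"] <= 0).any():
        raise DataError("base_mean must be positive")
    if (truth["dispersion"] < 0).any():
        raise DataError("dispersion must be nonnegative")
    rng = np.random.default_rng(seed)
    alpha = truth["dispersion"].to_numpy()
    over = alpha > 0
    counts = np.empty((len(truth), len(design)), dtype=np.int64)
    mean_cache: dict[tuple[str, str], np.ndarray] = {}
    for j, row in enumerate(design.itertuples(index=False)):
        key = (row.genotype, row.treatment)
        if key not in mean_cache:
            mean_cache[key] = expected_mean(truth, *key)
        mu = row.size_multiplier * mean_cache[key]
        lam = mu.copy()
        if over.any():
            # gamma-Poisson mixture: lambda ~ Gamma(1/alpha, scale=alpha*mu)
            lam[over] = rng.gamma(1.0 / alpha[over], alpha[over] * mu[over])
        counts[:, j] = rng.poisson(lam)
    return pd.DataFrame(counts, index=truth.index, columns=design["sample_id"].tolist())


# ---------------------------------------------------------------------------
# alignment fixtures for the UTR-filter stage
# ---------------------------------------------------------------------------


def make_toy_annotation(
    n_genes: int = 5,
    chromosome: str = "chr1",
    utr5_len: int = 200,
    cds_len: int = 600,
    utr3_len: int = 400,
    spacing: int = 1000,
):
    """Build a toy annotation: each gene is 5'UTR | CDS | 3'UTR on one strand.

    Returns a :class:`~trap_rescue.readfilter.GeneAnnotation`.  Coordinates
    follow GTF convention (1-based inclusive).
    """
    from trap_rescue.readfilter import GeneAnnotation

    records = []
    start = 1
    for i in range(n_genes):
        gid = f"gene{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        u5 = (start, start + utr5_len - 1, "UTR5")
        cds = (start + utr5_len, start + utr5_len + cds_len - 1, "CDS")
        u3 = (start + utr5_len + cds_len, start + utr5_len + cds_len + utr3_len - 1, "UTR3")
        if strand == "-":  # 5'UTR sits at the right end on the minus strand
            u5, u3 = (u3[0], u3[1], "UTR5"), (u5[0], u5[1], "UTR3")
        for s, e, cls in (u5, cds, u3):
            records.append((gid, chromosome, strand, s, e, cls))
        start += utr5_len + cds_len + utr3_len + spacing
    return GeneAnnotation.from_records(records)


def simulate_alignment_fixture(
    annotation,
    reads_per_gene: int,
    utr_fraction: float,
    seed: int,
    read_length: int = 50,
) -> tuple[list, pd.Series]:
    """Place single-end ungapped reads wholly inside CDS or UTR intervals.

    Exactly ``round(reads_per_gene * utr_fraction)`` reads per gene fall
    wholly within UTR intervals; the rest fall wholly within CDS.  Returns the
    read records and the exact expected per-gene count after UTR filtering.
    """
    from trap_rescue.readfilter import AlignedRead

    if not 0 <= utr_fraction <= 1:
        raise ConfigError("utr_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    reads: list[AlignedRead] = []
    expected: dict[str, int] = {}
    n_utr = int(round(reads_per_gene * utr_fraction))
    n_cds = reads_per_gene - n_utr
    for gid in annotation.gene_ids:
        gene = annotation.genes[gid]
        cds = [iv for iv in gene.intervals if iv[2] == "CDS"]
        utr = [iv for iv in gene.intervals if iv[2] in ("UTR5", "UTR3")]
        if not cds and utr_fraction < 1:
            raise DataError(f"gene {gid} has no CDS interval; cannot place CDS reads")
        for k, (pool, n) in enumerate(((cds, n_cds), (utr, n_utr))):
            for r in range(n):
                s1, e1, _cls = pool[rng.integers(len(pool))]
                lo, hi = s1 - 1, e1  # 0-based half-open
                if hi - lo < read_length:
                    raise DataError(
                        f"interval of {gid} shorter than read length {read_length}"
                    )
                pos = int(rng.integers(lo, hi - read_length + 1))
                reads.append(
                    AlignedRead(
                        read_id=f"{gid}.{'utr' if k else 'cds'}.{r}",
                        chromosome=gene.chromosome,
                        blocks=[(pos, pos + read_length)],
                        strand=gene.strand,
                    )
                )
        expected[gid] = n_cds
    rng.shuffle(reads)  # interleave genes so ordering carries no signal
    return reads, pd.Series(expected, name="expected_count")
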