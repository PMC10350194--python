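"""Experimental design: sample sheets and the contrast lattice.

The study design crosses four Apoer2 genotypes with three lentiviral
treatments.  ``Cre`` is the control treatment (lentivirus expressing Cre
only); the two ICD treatments co-express one splice variant of the Apoer2
intracellular domain (with or without exon 19).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trap_rescue.errors import ConfigError

GENOTYPES = ("WT", "cKO", "KI_plus19", "KI_delta19")
TREATMENTS = ("Cre", "ICD_plus19", "ICD_delta19")

#: ICD splice variants, keyed by short name -> treatment level.
ICD_VARIANTS = {"plus19": "ICD_plus19", "delta19": "ICD_delta19"}

DESIGN_COLUMNS = ["sample_id", "genotype", "treatment", "replicate", "size_multiplier"]


@dataclass(frozen=True)
class Contrast:
    """A two-group contrast: numerator condition vs denominator condition.

    ``family`` is ``"vs_wt"`` for contrasts against (WT, Cre) and
    ``"within_genotype"`` for (genotype, ICD) vs (genotype, Cre).
    """

    numerator: tuple[str, str]
    denominator: tuple[str, str]
    family: str = "vs_wt"

    @property
    def name(self) -> str:
        n, d = self.numerator, self.denominator
        return f"{n[0]}:{n[1]}_vs_{d[0]}:{d[1]}"

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ConfigError(f"contrast numerator equals denominator: {self.numerator}")


def make_design(
    replicates: int = 4,
    genotypes: tuple[str, ...] = GENOTYPES,
    treatments: tuple[str, ...] = TREATMENTS,
    seed: int = 0,
    depth_range: tuple[float, float] = (0.5, 2.0),
) -> pd.DataFrame:
    """Build a full-factorial sample sheet with per-sample library-depth truth.

    Size multipliers are drawn log-uniform in ``depth_range`` so that
    median-of-ratios normalization is exercised; they are the simulation's
    ground-truth library depths and have no meaning for real data.
    """
    if replicates < 2:
        raise ConfigError("each condition needs at least 2 replicates for DE")
    rng = np.random.default_rng(seed)
    rows = []
    for geno in genotypes:
        for treat in treatments:
            for rep in range(1, replicates + 1):
                rows.append((f"{geno}.{treat}.r{rep}", geno, treat, rep))
    frame = pd.DataFrame(rows, columns=DESIGN_COLUMNS[:4])
    lo, hi = depth_range
    if not (0 < lo <= hi):
        raise ConfigError(f"invalid depth_range {depth_range}")
    frame["size_multiplier"] = np.exp(rng.uniform(np.log(lo), np.log(hi), len(frame)))
    return frame


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS[:4] if c not in design.columns]
    if missing:
        raise ConfigError(f"design is missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dupes = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ConfigError(f"duplicate sample_id values: {dupes}")
    bad_geno = set(design["genotype"]) - set(GENOTYPES)
    if bad_geno:
        raise ConfigError(f"unknown genotypes: {sorted(bad_geno)}")
    bad_treat = set(design["treatment"]) - set(TREATMENTS)
    if bad_treat:
        raise ConfigError(f"unknown treatments: {sorted(bad_treat)}")
    if "size_multiplier" not in design.columns:
        design = design.copy()
        design["size_multiplier"] = 1.0
    return design


def conditions(design: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Map (genotype, treatment) -> sample_ids."""
    out: dict[tuple[str, str], list[str]] = {}
    for (geno, treat), grp in design.groupby(["genotype", "treatment"], sort=False):
        out[(geno, treat)] = grp["sample_id"].tolist()
    return out


def contrast_lattice(
    genotypes: tuple[str, ...] = GENOTYPES,
    wt: str = "WT",
    control_treatment: str = "Cre",
) -> list[Contrast]:
    """Enumerate every contrast the analysis needs.

    For each mutant genotype: the baseline contrast (geno, Cre) vs (WT, Cre);
    each ICD condition vs (WT, Cre); and each ICD condition vs its own
    genotype's Cre baseline.  For WT itself: each ICD condition vs (WT, Cre).
    With all four genotypes present this yields 11 vs-WT contrasts plus 6
    within-genotype contrasts.
    """
    ref = (wt, control_treatment)
    out: list[Contrast] = []
    for geno in genotypes:
        if geno == wt:
            continue
        out.append(Contrast((geno, control_treatment), ref, "vs_wt"))
        for icd_treat in ICD_VARIANTS.values():
            out.append(Contrast((geno, icd_treat), ref, "vs_wt"))
            out.append(Contrast((geno, icd_treat), (geno, control_treatment), "within_genotype"))
    for icd_treat in ICD_VARIANTS.values():
        out.append(Contrast((wt, icd_treat), ref, "vs_wt"))
    return out


def check_lattice_buildable(design: pd.DataFrame, lattice: list[Contrast]) -> None:
    """Raise naming every contrast whose conditions are absent or underpowered."""
    cond = conditions(design)
    broken = []
    for c in lattice:
        for side in (c.numerator, c.denominator):
            if len(cond.get(side, [])) < 2:
                broken.append(c.name)
                break
    if broken:
        raise ConfigError(
            f"{len(broken)} contrast(s) cannot be built (condition missing or <2 "
            f"replicates): {', '.join(broken)}"
        )
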