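"""Rescue classification across the contrast lattice.

For each mutant genotype three differential tables drive the calls:

* A — baseline: (genotype, Cre) vs (WT, Cre)
* B — ICD within genotype: (genotype, ICD) vs (genotype, Cre)
* C — ICD vs wild type: (genotype, ICD) vs (WT, Cre)

A gene has a *basal* call when |log2FC_A| > 0.56 and p_A < 0.05 (both strict).
A basal gene is *rescued* by an ICD variant when its translatome moved back
toward wild type — |log2FC_C| strictly smaller than |log2FC_A| — and the
combined genotype-rescue p-value (sum of p_A and p_B, squared, divided by the
number of p-values, clamped to [0, 1]) is below 0.05.  Genes without a basal
call but shifted by an ICD within their genotype are genotype-independent ICD
effects.  The relaxed common-module criterion pools genes basal-significant
in at least one genotype and asks for |log2FC| > 0.5 in all three.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from trap_rescue.errors import DataError

LFC_THRESHOLD = 0.56
RELAXED_LFC_THRESHOLD = 0.5
P_THRESHOLD = 0.05

CATEGORIES = (
    "rescued_both",
    "rescued_plus19_only",
    "rescued_delta19_only",
    "not_rescued",
    "not_applicable",
)


def combined_p(pvals) -> float:
    """Combined genotype-rescue p-value: min(1, (sum p_i)^2 / n).

    With n = 2 the inputs are the baseline p-value of genotype vs wild type
    and the p-value of the ICD effect within the genotype; combining them
    raises power over filtering on either alone.  The raw formula exceeds 1
    when sum(p) > sqrt(n), hence the clamp.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise DataError("combined_p needs at least one p-value")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    return float(min(1.0, p.sum() ** 2 / p.size))


def _combined_p_pair(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    return np.minimum(1.0, (pa + pb) ** 2 / 2.0)


def _pcol(use_adjusted: bool) -> str:
    return "bh_q" if use_adjusted else "wald_p"


def call_basal(
    de: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    use_adjusted: bool = False,
) -> pd.Series:
    """Per-gene basal direction (up / down / ns), strict thresholds.

    Not-testable genes are ns.
    """
    lfc = de["log2fc"]
    p = de[_pcol(use_adjusted)]
    sig = (p < p_threshold) & de["testable"]
    out = pd.Series("ns", index=de.index, name="basal_direction")
    out[sig & (lfc > lfc_threshold)] = "up"
    out[sig & (lfc < -lfc_threshold)] = "down"
    return out


def call_rescue(
    basal_de: pd.DataFrame,
    icd_vs_wt_de: pd.DataFrame,
    icd_within_de: pd.DataFrame,
    basal_direction: pd.Series | None = None,
    p_threshold: float = P_THRESHOLD,
    use_adjusted: bool = False,
    strict: bool = False,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """Rescue status for one ICD variant in one genotype.

    rescued iff the gene has a basal call, |log2FC_C| < |log2FC_A| (strict:
    a tie is not a rescue), and combined_p(p_A, p_B) < 0.05.  ``strict=True``
    additionally requires C not to be basal-significant itself (the rescued
    gene must be indistinguishable from wild type by the full criterion).
    Genes not testable in B or C are not_rescued with ``missing_data=True``.
    """
    if basal_direction is None:
        basal_direction = call_basal(basal_de, use_adjusted=use_adjusted)
    idx = basal_de.index
    pa = basal_de[_pcol(use_adjusted)].to_numpy(dtype=float)
    pb = icd_within_de[_pcol(use_adjusted)].reindex(idx).to_numpy(dtype=float)
    lfc_a = basal_de["log2fc"].to_numpy(dtype=float)
    lfc_c = icd_vs_wt_de["log2fc"].reindex(idx).to_numpy(dtype=float)
    has_basal = basal_direction.reindex(idx).isin(["up", "down"]).to_numpy()
    missing = ~(
        icd_within_de["testable"].reindex(idx).fillna(False).to_numpy(dtype=bool)
        & icd_vs_wt_de["testable"].reindex(idx).fillna(False).to_numpy(dtype=bool)
    )
    comb = np.where(
        np.isnan(pa) | np.isnan(pb), np.nan, _combined_p_pair(np.nan_to_num(pa), np.nan_to_num(pb))
    )
    smaller = np.abs(lfc_c) < np.abs(lfc_a)
    rescued = has_basal & ~missing & smaller & (comb < p_threshold)
    if strict:
        pc = icd_vs_wt_de[_pcol(use_adjusted)].reindex(idx).to_numpy(dtype=float)
        still_sig = (np.abs(lfc_c) > lfc_threshold) & (pc < p_threshold)
        rescued &= ~still_sig
    status = np.where(
        has_basal, np.where(rescued, "rescued", "not_rescued"), "not_applicable"
    )
    return pd.DataFrame(
        {
            "rescue_status": status,
            "combined_p": comb,
            "missing_data": missing & has_basal,
            "log2fc_icd_vs_wt": lfc_c,
        },
        index=idx,
    )


def categorize(status_plus19: pd.Series, status_delta19: pd.Series) -> pd.Series:
    """Fold the two per-ICD rescue statuses into one category per gene."""
    a = status_plus19 == "rescued"
    b = status_delta19.reindex(status_plus19.index) == "rescued"
    na = (status_plus19 == "not_applicable") & (
        status_delta19.reindex(status_plus19.index) == "not_applicable"
    )
    out = pd.Series("not_rescued", index=status_plus19.index, name="category")
    out[a & b] = "rescued_both"
    out[a & ~b] = "rescued_plus19_only"
    out[~a & b] = "rescued_delta19_only"
    out[na] = "not_applicable"
    return out


def call_icd_effect(
    icd_within_de: pd.DataFrame,
    basal_direction: pd.Series,
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    use_adjusted: bool = False,
) -> pd.Series:
    """Genotype-independent ICD effects: basal-ns genes shifted by the ICD
    within the genotype, at the same thresholds as the basal call."""
    direction = call_basal(
        icd_within_de, lfc_threshold=lfc_threshold, p_threshold=p_threshold,
        use_adjusted=use_adjusted,
    ).rename("icd_direction")
    gated = basal_direction.reindex(direction.index) == "ns"
    return direction.where(gated, "ns")


def classify_genotype(
    basal_de: pd.DataFrame,
    icd_tables: dict[str, dict[str, pd.DataFrame]],
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    use_adjusted: bool = False,
    strict: bool = False,
) -> pd.DataFrame:
    """Full per-gene classification for one mutant genotype.

    ``icd_tables`` maps icd name ('plus19', 'delta19') to
    ``{"vs_wt": DEResult C, "within": DEResult B}``.
    """
    basal_dir = call_basal(basal_de, lfc_threshold, p_threshold, use_adjusted)
    master = pd.DataFrame(
        {"basal_direction": basal_dir, "log2fc_basal": basal_de["log2fc"],
         "p_basal": basal_de[_pcol(use_adjusted)]}
    )
    statuses = {}
    for icd, tabs in icd_tables.items():
        res = call_rescue(
            basal_de, tabs["vs_wt"], tabs["within"], basal_direction=basal_dir,
            p_threshold=p_threshold, use_adjusted=use_adjusted, strict=strict,
            lfc_threshold=lfc_threshold,
        )
        statuses[icd] = res["rescue_status"]
        master[f"log2fc_icd_vs_wt_{icd}"] = res["log2fc_icd_vs_wt"]
        master[f"combined_p_{icd}"] = res["combined_p"]
        master[f"rescue_status_{icd}"] = res["rescue_status"]
        master[f"icd_direction_{icd}"] = call_icd_effect(
            tabs["within"], basal_dir, lfc_threshold, p_threshold, use_adjusted
        )
    master["category"] = categorize(statuses["plus19"], statuses["delta19"])
    up = master["icd_direction_plus19"].isin(["up", "down"])
    dn = master["icd_direction_delta19"].isin(["up", "down"])
    master["icd_opposite"] = (
        up & dn & (master["icd_direction_plus19"] != master["icd_direction_delta19"])
    )
    return master


def expanded_common(
    basal_tables: dict[str, pd.DataFrame],
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    relaxed_threshold: float = RELAXED_LFC_THRESHOLD,
    use_adjusted: bool = False,
) -> dict[str, list[str]]:
    """Relaxed common regulatory module across all mutant genotypes.

    Within genes basal-significant (full criterion) in >= 1 genotype, a gene
    is common-up when log2FC > ``relaxed_threshold`` in every genotype, and
    common-down when below the negated threshold in every genotype; no
    p-value requirement applies to the relaxed members.
    """
    names = list(basal_tables)
    sig_any = None
    lfcs = {}
    for g, de in basal_tables.items():
        d = call_basal(de, lfc_threshold, p_threshold, use_adjusted) != "ns"
        sig_any = d if sig_any is None else (sig_any | d.reindex(sig_any.index, fill_value=False))
        lfcs[g] = de["log2fc"]
    lfc = pd.DataFrame({g: lfcs[g] for g in names}).reindex(sig_any.index)
    eligible = sig_any & lfc.notna().all(axis=1)
    common_up = eligible & (lfc > relaxed_threshold).all(axis=1)
    common_down = eligible & (lfc < -relaxed_threshold).all(axis=1)
    return {
        "common_up": sorted(common_up.index[common_up]),
        "common_down": sorted(common_down.index[common_down]),
    }
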