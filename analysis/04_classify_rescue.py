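"""Classify every gene in each mutant genotype: basal direction, per-ICD
rescue status with the combined genotype-rescue p-value, genotype-independent
ICD effects, and a confusion table against the simulation's truth labels.
Reads results/data/ and results/de/, writes results/rescue/."""

from pathlib import Path

import pandas as pd

import trap_rescue as tr
from trap_rescue import io
from trap_rescue.design import ICD_VARIANTS
from trap_rescue.pipeline import MUTANTS

ROOT = Path(__file__).resolve().parent.parent / "results"


def load(num, den):
    return io.read_de_table(ROOT / "de" / f"{num[0]}:{num[1]}_vs_{den[0]}:{den[1]}.tsv")


def main() -> None:
    truth = pd.read_csv(ROOT / "data" / "truth.tsv", sep="\t", index_col=0)
    ref = ("WT", "Cre")
    for geno in MUTANTS:
        basal = load((geno, "Cre"), ref)
        icd_tables = {
            icd: {"vs_wt": load((geno, treat), ref),
                  "within": load((geno, treat), (geno, "Cre"))}
            for icd, treat in ICD_VARIANTS.items()
        }
        master = tr.classify_genotype(basal, icd_tables)
        io.write_table(master, ROOT / "rescue" / f"rescue_{geno}.tsv")

        called = master[master["basal_direction"] != "ns"]
        cats = called["category"].value_counts()
        rescued = called["category"].isin(
            ["rescued_both", "rescued_plus19_only", "rescued_delta19_only"]
        ).mean()
        print(f"{geno}: {len(called)} basal genes "
              f"({(called['basal_direction'] == 'up').sum()} up, "
              f"{(called['basal_direction'] == 'down').sum()} down); "
              f"{100 * rescued:.1f}% rescued by >=1 ICD; categories {dict(cats)}")

        confusion = pd.crosstab(truth["label"], master["category"])
        io.write_table(confusion, ROOT / "rescue" / f"confusion_{geno}.tsv",
                       index_label="truth_label")
    print(f"wrote master tables and confusion matrices under {ROOT}/rescue/")


if __name__ == "__main__":
    main()
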