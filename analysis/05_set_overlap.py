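"""Cross-genotype set structure of the basal translatome: supervenn-style
membership partition, direction concordance, the relaxed common regulatory
module (|log2FC| > 0.5 in all genotypes within genes significant in >= 1),
and a complete-linkage dendrogram of basal log2 fold changes."""

from pathlib import Path

import pandas as pd

import trap_rescue as tr
from trap_rescue import io
from trap_rescue.pipeline import MUTANTS

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    basal_tables = {
        g: io.read_de_table(ROOT / "de" / f"{g}:Cre_vs_WT:Cre.tsv") for g in MUTANTS
    }
    dirs = {g: tr.call_basal(t) for g, t in basal_tables.items()}
    sets = {g: set(d.index[d != "ns"]) for g, d in dirs.items()}

    partition = tr.membership_partition(sets)
    io.write_table(partition, ROOT / "sets" / "basal_partition.tsv", index_label=None)
    in_all = partition.loc[partition["pattern"] == "111", "count"].iloc[0]
    union = partition["count"].sum()
    print(f"basal-significant union across genotypes: {union} genes; "
          f"{in_all} significant in all three")

    concordance = tr.direction_concordance(
        dirs, {g: t["log2fc"] for g, t in basal_tables.items()}
    )
    for bucket, genes in concordance.items():
        print(f"  {bucket}: {len(genes)}")

    common = tr.expanded_common(basal_tables)
    for key, genes in common.items():
        (ROOT / "sets").mkdir(parents=True, exist_ok=True)
        (ROOT / "sets" / f"{key}.txt").write_text("".join(g + "\n" for g in genes))
    print(f"relaxed common module: {len(common['common_up'])} up, "
          f"{len(common['common_down'])} down")

    members = sorted(set().union(*sets.values()))
    lfc = pd.DataFrame({g: basal_tables[g]["log2fc"].reindex(members) for g in MUTANTS})
    z = tr.hcluster_complete(lfc)
    (ROOT / "sets" / "basal_dendrogram.nwk").write_text(
        tr.linkage_to_newick(z, members) + "\n"
    )
    print(f"wrote partition, common-module lists and dendrogram under {ROOT}/sets/")


if __name__ == "__main__":
    main()
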