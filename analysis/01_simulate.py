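"""Generate the synthetic TRAP-Seq study: 2000 genes, 4 genotypes x 3
lentiviral treatments x 4 replicates, with ground-truth baseline and rescue
effects.  Writes truth, design and counts under results/data/."""

from pathlib import Path

import trap_rescue as tr
from trap_rescue import io

SEED = 20260930
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    config = tr.SimulationConfig(n_genes=2000, seed=SEED)
    truth = tr.make_truth(config)
    design = tr.make_design(replicates=4, seed=SEED + 1)
    counts = tr.simulate_counts(truth, design, seed=SEED + 2)

    io.write_table(truth, OUT / "truth.tsv")
    io.write_design(design, OUT / "design.tsv")
    io.write_counts(counts, OUT / "counts.tsv")

    tally = truth["label"].value_counts()
    print(f"simulated {len(counts)} genes x {counts.shape[1]} samples (seed {SEED})")
    print("truth labels:", dict(tally))
    print(f"wrote {OUT}/truth.tsv, design.tsv, counts.tsv")


if __name__ == "__main__":
    main()
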