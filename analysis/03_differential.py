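"""Differential ribosome loading over the full contrast lattice: median-of-
ratios normalization, pooled method-of-moments dispersion, and an NB Wald
test per contrast.  Reads results/data/, writes results/de/."""

from pathlib import Path

import trap_rescue as tr
from trap_rescue import io
from trap_rescue.design import contrast_lattice

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = io.read_counts(ROOT / "data" / "counts.tsv")
    design = io.read_design(ROOT / "data" / "design.tsv")

    factors = tr.size_factors(counts)
    dispersions = tr.estimate_dispersion(counts, factors, design)
    io.write_table(factors.to_frame(), ROOT / "de" / "size_factors.tsv",
                   index_label="sample_id")
    io.write_table(dispersions.to_frame(), ROOT / "de" / "dispersions.tsv")
    print(f"size factors span [{factors.min():.3f}, {factors.max():.3f}]; "
          f"median dispersion {dispersions.median():.4f}")

    lattice = contrast_lattice()
    for contrast in lattice:
        res = tr.wald_test(counts, factors, dispersions, design, contrast)
        io.write_table(res, ROOT / "de" / f"{contrast.name}.tsv")
        n_sig = int(((res["wald_p"] < 0.05) & (res["log2fc"].abs() > 0.56)).sum())
        print(f"  {contrast.name}: {n_sig} genes at |log2FC|>0.56, p<0.05")
    print(f"wrote {len(lattice)} contrast tables under {ROOT}/de/")


if __name__ == "__main__":
    main()
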