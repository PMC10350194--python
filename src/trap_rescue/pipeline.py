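"""End-to-end orchestration: simulate (or load) -> [filter/count] -> DE over
the contrast lattice -> rescue classification -> set operations -> enrichment.

Every stage writes plain TSV under the output directory and the run ends
with a JSON manifest (config echo, seed, per-stage row counts, SHA-256 of
every artifact).  Re-running with an identical config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from trap_rescue import io
from trap_rescue.design import (
    GENOTYPES,
    ICD_VARIANTS,
    check_lattice_buildable,
    contrast_lattice,
    make_design,
    validate_design,
)
from trap_rescue.diffexpr import estimate_dispersion, size_factors, wald_test
from trap_rescue.errors import ConfigError
from trap_rescue.rescue import (
    LFC_THRESHOLD,
    P_THRESHOLD,
    RELAXED_LFC_THRESHOLD,
    call_basal,
    classify_genotype,
    expanded_common,
)
from trap_rescue.setops import (
    direction_concordance,
    hcluster_complete,
    linkage_to_newick,
    membership_partition,
)
from trap_rescue.simulate import SimulationConfig, make_truth, simulate_counts

MUTANTS = tuple(g for g in GENOTYPES if g != "WT")


@dataclass
class PipelineConfig:
    """Declarative run configuration (YAML-loadable via :meth:`from_yaml`)."""

    out_dir: str = "results/run"
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    n_genes: int = 2000
    replicates: int = 4
    sim_overrides: dict = field(default_factory=dict)
    # ... or load
    counts_path: str | None = None
    design_path: str | None = None
    # thresholds and flags
    lfc_threshold: float = LFC_THRESHOLD
    relaxed_threshold: float = RELAXED_LFC_THRESHOLD
    p_threshold: float = P_THRESHOLD
    use_adjusted: bool = False
    strict_rescue: bool = False
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.relaxed_threshold <= 0:
            raise ConfigError("fold-change thresholds must be positive")
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p_threshold must be in (0, 1)")
        if not self.simulate and not (self.counts_path and self.design_path):
            raise ConfigError("need counts_path and design_path when simulate=False")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "seed": config.seed,
        "stages": {},
    }
    artifacts: list[Path] = []

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.simulate:
        sim = SimulationConfig(
            n_genes=config.n_genes, seed=config.seed, **config.sim_overrides
        )
        truth = make_truth(sim)
        design = make_design(replicates=config.replicates, seed=config.seed + 1)
        counts = simulate_counts(truth, design, seed=config.seed + 2)
        io.write_table(truth, out / "truth.tsv")
        artifacts.append(out / "truth.tsv")
    else:
        counts = io.read_counts(config.counts_path)
        design = io.read_design(config.design_path)
        manifest["stages"]["inputs"] = {
            "counts_sha256": io.sha256_file(config.counts_path),
            "design_sha256": io.sha256_file(config.design_path),
        }
    design = validate_design(design)
    io.write_counts(counts, out / "counts.tsv")
    io.write_design(design, out / "design.tsv")
    artifacts += [out / "counts.tsv", out / "design.tsv"]
    manifest["stages"]["counts"] = {"genes": len(counts), "samples": counts.shape[1]}

    # --- differential expression over the lattice -------------------------
    present = tuple(g for g in GENOTYPES if g in set(design["genotype"]))
    lattice = contrast_lattice(genotypes=present)
    check_lattice_buildable(design, lattice)
    factors = size_factors(counts)
    dispersions = estimate_dispersion(counts, factors, design)
    io.write_table(factors.to_frame(), out / "size_factors.tsv", index_label="sample_id")
    io.write_table(dispersions.to_frame(), out / "dispersions.tsv")
    artifacts += [out / "size_factors.tsv", out / "dispersions.tsv"]

    de_dir = out / "de"
    de_tables: dict[str, pd.DataFrame] = {}
    for contrast in lattice:
        res = wald_test(counts, factors, dispersions, design, contrast)
        de_tables[contrast.name] = res
        path = de_dir / f"{contrast.name}.tsv"
        io.write_table(res, path)
        artifacts.append(path)
    manifest["stages"]["de"] = {
        "contrasts": len(lattice),
        "vs_wt_contrasts": sum(c.family == "vs_wt" for c in lattice),
    }

    # --- rescue classification --------------------------------------------
    def _name(num, den):
        return f"{num[0]}:{num[1]}_vs_{den[0]}:{den[1]}"

    ref = ("WT", "Cre")
    masters: dict[str, pd.DataFrame] = {}
    basal_tables: dict[str, pd.DataFrame] = {}
    for geno in MUTANTS:
        if geno not in present:
            continue
        basal = de_tables[_name((geno, "Cre"), ref)]
        icd_tables = {
            icd: {
                "vs_wt": de_tables[_name((geno, treat), ref)],
                "within": de_tables[_name((geno, treat), (geno, "Cre"))],
            }
            for icd, treat in ICD_VARIANTS.items()
        }
        master = classify_genotype(
            basal, icd_tables, config.lfc_threshold, config.p_threshold,
            config.use_adjusted, config.strict_rescue,
        )
        masters[geno] = master
        basal_tables[geno] = basal
        path = out / f"rescue_{geno}.tsv"
        io.write_table(master, path)
        artifacts.append(path)
        manifest["stages"][f"rescue_{geno}"] = {
            "basal_genes": int((master["basal_direction"] != "ns").sum()),
            "categories": master.loc[master["basal_direction"] != "ns", "category"]
            .value_counts().to_dict(),
        }

    # --- set operations ----------------------------------------------------
    if basal_tables:
        dirs = {
            g: call_basal(t, config.lfc_threshold, config.p_threshold, config.use_adjusted)
            for g, t in basal_tables.items()
        }
        sets = {g: set(d.index[d != "ns"]) for g, d in dirs.items()}
        partition = membership_partition(sets)
        io.write_table(partition, out / "basal_partition.tsv", index_label=None)
        artifacts.append(out / "basal_partition.tsv")

        concordance = direction_concordance(
            dirs, {g: t["log2fc"] for g, t in basal_tables.items()}
        )
        manifest["stages"]["concordance"] = {k: len(v) for k, v in concordance.items()}

        common = expanded_common(
            basal_tables, config.lfc_threshold, config.p_threshold,
            config.relaxed_threshold, config.use_adjusted,
        )
        for key, genes in common.items():
            path = out / f"{key}.txt"
            path.write_text("".join(g + "\n" for g in genes))
            artifacts.append(path)
        manifest["stages"]["expanded_common"] = {k: len(v) for k, v in common.items()}

        union = sorted(set().union(*sets.values()))
        if len(union) >= 2:
            lfc_matrix = pd.DataFrame(
                {g: t["log2fc"].reindex(union) for g, t in basal_tables.items()}
            )
            z = hcluster_complete(lfc_matrix)
            (out / "basal_dendrogram.nwk").write_text(linkage_to_newick(z, union) + "\n")
            artifacts.append(out / "basal_dendrogram.nwk")

    # --- enrichment ---------------------------------------------------------
    if config.gmt_path:
        from trap_rescue.enrichment import hypergeom_enrich, read_gmt

        collection = read_gmt(config.gmt_path)
        universe = sorted(
            set().union(*[set(t.index[t["testable"]]) for t in basal_tables.values()])
        )
        for geno, master in masters.items():
            query = sorted(master.index[master["basal_direction"] != "ns"])
            table = hypergeom_enrich(query, collection, universe)
            path = out / f"enrichment_{geno}.tsv"
            io.write_table(table, path, index_label=None)
            artifacts.append(path)

    # --- truth-based confusion (synthetic runs only) ------------------------
    if truth is not None:
        confusion = {}
        for geno, master in masters.items():
            joined = pd.DataFrame(
                {"truth": truth["label"], "called": master["category"]}
            )
            confusion[geno] = (
                joined.groupby(["truth", "called"], observed=True).size()
                .rename("n").reset_index().to_dict("records")
            )
        manifest["stages"]["truth_confusion"] = confusion

    manifest["artifacts"] = {
        str(p.relative_to(out)): io.sha256_file(p) for p in artifacts
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
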