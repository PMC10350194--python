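import pandas as pd
import pytest

import trap_rescue as tr
from trap_rescue.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def toy_annotation():
    return tr.make_toy_annotation(n_genes=5)


@pytest.fixture(scope="session")
def small_simulation():
    """300-gene synthetic dataset with truth, design and counts."""
    truth = tr.make_truth(tr.SimulationConfig(n_genes=300, seed=10))
    design = tr.make_design(replicates=4, seed=11)
    counts = tr.simulate_counts(truth, design, seed=12)
    return truth, design, counts


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Full pipeline on the study-scale synthetic dataset (2000 genes,
    |baseline log2FC| = 1.5, full/no rescue, 4 replicates, alpha = 0.05)."""
    out = tmp_path_factory.mktemp("recovery") / "run"
    config = PipelineConfig(out_dir=str(out), seed=11, n_genes=2000)
    manifest = run_pipeline(config)
    truth = pd.read_csv(out / "truth.tsv", sep="\t", index_col=0)
    masters = {
        geno: pd.read_csv(out / f"rescue_{geno}.tsv", sep="\t", index_col=0)
        for geno in ("cKO", "KI_plus19", "KI_delta19")
    }
    return truth, masters, manifest, out


@pytest.fixture(scope="session")
def null_de():
    """Wald results for one 4v4 contrast on a global-null NB matrix."""
    from trap_rescue.design import contrast_lattice

    truth = tr.make_truth(tr.SimulationConfig(n_genes=2000, seed=5, proportions={}))
    design = tr.make_design(replicates=4, seed=6)
    counts = tr.simulate_counts(truth, design, seed=7)
    factors = tr.size_factors(counts)
    disp = tr.estimate_dispersion(counts, factors, design)
    contrast = next(
        c for c in contrast_lattice() if c.name == "cKO:Cre_vs_WT:Cre"
    )
    return tr.wald_test(counts, factors, disp, design, contrast)
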