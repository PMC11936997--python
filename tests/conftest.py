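import json
from pathlib import Path

import pandas as pd
import pytest

import pooldeg as pdg


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded simulation shared by cheap structural tests."""
    cfg = pdg.SimConfig(n_genes=300, n_true_de=20, n_outlier_genes=20, seed=42)
    counts, design, truth = pdg.generate_counts(cfg)
    return cfg, counts, design, truth


def run_synthetic(seed, outdir, **sim_overrides):
    """Full pipeline run in synthetic mode; returns report, consensus table
    and ground truth read back from the stage outputs."""
    sim = pdg.SimConfig(**sim_overrides)
    cfg = pdg.PipelineConfig(sim=sim, seed=seed, outdir=str(outdir))
    report = pdg.run_pipeline(cfg)
    consensus = pd.read_csv(Path(outdir) / "consensus.tsv", sep="\t")
    truth = json.loads((Path(outdir) / "truth.json").read_text())
    return {"report": report, "consensus": consensus, "truth": truth,
            "outdir": Path(outdir)}


@pytest.fixture(scope="session")
def headline_runs(tmp_path_factory):
    """Ten seeded runs of the reference study conditions (2,000 genes,
    100 group-effect genes at |beta|=2, 100 single-genotype outliers at
    gamma=4, phi=0.1, 3+3 genotypes x 2 libraries)."""
    base = tmp_path_factory.mktemp("headline")
    runs = []
    for seed in range(10):
        runs.append(run_synthetic(seed, base / f"s{seed}"))
    return runs
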