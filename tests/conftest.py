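import pandas as pd
import pytest
from hypothesis import settings

from aluexon.pipeline import RunConfig, run_pipeline
from aluexon.simulate import SimulationConfig

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """A full simulate->detect->classify->abundance run on 60 genes."""
    outdir = tmp_path_factory.mktemp("simrun")
    cfg = RunConfig(outdir=str(outdir), seed=5, sim=SimulationConfig(n_genes=60))
    paths = run_pipeline(cfg)
    return cfg, paths


@pytest.fixture(scope="session")
def sim_frames(sim_run):
    _, paths = sim_run
    return {
        "calls": pd.read_csv(paths["calls_tsv"], sep="\t", comment="#"),
        "truth": pd.read_csv(paths["truth_tsv"], sep="\t", comment="#"),
        "summary": pd.read_csv(paths["summary_tsv"], sep="\t", comment="#"),
        "fpkm": pd.read_csv(paths["fpkm_tsv"], sep="\t", comment="#"),
        "fpkm_truth": pd.read_csv(paths["fpkm_truth_tsv"], sep="\t", comment="#"),
        "relabund": pd.read_csv(paths["relabund_tsv"], sep="\t", comment="#"),
    }
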