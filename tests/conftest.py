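import numpy as np
import pandas as pd
import pytest

from immigratio import CountTable, PipelineConfig, SimConfig
from immigratio.pipeline import run_simulation
from immigratio.synthetic import make_dataset


def make_counts(data: dict, taxonomy: dict | None = None) -> CountTable:
    """Build a CountTable from {otu: {sample: count}} (missing cells = 0)."""
    df = pd.DataFrame(data).T.fillna(0).astype(np.int64)
    tax = pd.Series(
        {otu: (taxonomy or {}).get(otu, "k__Bacteria;p__;c__;o__;f__;g__;s__")
         for otu in df.index}
    )
    return CountTable(df, tax)


@pytest.fixture
def toy_counts() -> CountTable:
    """4 OTUs x 6 samples at depth 1000; OTU_A's digester/influent ratio is 10."""
    cols = ["D1", "D2", "P1", "P2", "S1", "S2"]
    rows = {
        "OTU_A": [50, 50, 4, 4, 6, 6],
        "OTU_B": [10, 10, 0, 0, 0, 0],       # digester-only
        "OTU_C": [0, 0, 10, 10, 10, 10],     # influent-only
        "OTU_D": [940, 940, 986, 986, 984, 984],
    }
    tax = {
        "OTU_A": "k__Archaea;p__Euryarchaeota;c__Methanomicrobia;o__Methanosarcinales;"
                 "f__Methanosaetaceae;g__Methanosaeta;s__",
        "OTU_B": "k__Bacteria;p__Chloroflexi;c__Anaerolineae;o__Anaerolineales;"
                 "f__Anaerolineaceae;g__;s__",
        "OTU_C": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                 "f__Lachnospiraceae;g__Blautia;s__",
        "OTU_D": "k__Bacteria;p__Actinobacteria;c__Actinobacteria;o__Micrococcales;"
                 "f__Intrasporangiaceae;g__Tetrasphaera;s__",
    }
    df = pd.DataFrame(rows, index=cols).T.astype(np.int64)
    return CountTable(df, pd.Series(tax))


@pytest.fixture
def toy_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["D1", "D2", "P1", "P2", "S1", "S2"],
            "plant": ["Aalborg", "Aalborg", "Aalborg", "Odense", "Aalborg", "Odense"],
            "reactor": ["R1", "R2", "", "", "", ""],
            "sample_type": ["digester", "digester", "primary", "primary",
                            "surplus", "surplus"],
            "process_type": ["mesophilic", "mesophilic", "na", "na", "na", "na"],
            "date": [""] * 6,
        }
    )


SMALL_SIM = SimConfig(
    n_otus=300, n_plants=2, digester_samples_per_group=12,
    primary_samples=8, surplus_samples=8, depth=3000, seed=11,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic dataset + truth shared across read-only tests."""
    return make_dataset(SMALL_SIM)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full default-scale simulation -> analysis -> recovery report."""
    outdir = tmp_path_factory.mktemp("default_run")
    return run_simulation(SimConfig(seed=1), PipelineConfig(outdir=str(outdir), seed=1))
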