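import numpy as np
import pandas as pd
import pytest

from fosmidscreen import panel as pnl
from fosmidscreen import screening as sc
from fosmidscreen import synthetic as syn


@pytest.fixture(scope="session")
def substrate_panel():
    return pnl.load_substrate_panel()


@pytest.fixture(scope="session")
def liquid_panel(substrate_panel):
    return substrate_panel[substrate_panel["assay_type"] == "liquid"].reset_index(
        drop=True
    )


@pytest.fixture(scope="session")
def family_map():
    return pnl.load_family_substrate_map()


@pytest.fixture(scope="session")
def small_library(family_map):
    """Two-taxon, 304-clone library with short inserts (screening-scale tests)."""
    models = syn.random_taxon_models(2, seed=11)
    params = syn.LibraryParams(
        n_clones=304,
        taxon_mix={"taxon_00": 0.5, "taxon_01": 0.5},
        insert_size_range=(5000, 8000),
        genome_length=50_000,
        active_gene_rate=0.08,
        library_id="T",
    )
    return syn.build_library(params, models, family_map, seed=12)


def make_plate_readings(values, plate="P0", substrate="PNP-b-D-Glucoside",
                        timepoint="24h", modality="absorbance"):
    """One plate of readings from a value vector (well order A1..H12)."""
    wells = sc.WELLS[: len(values)]
    return pd.DataFrame(
        {
            "plate_id": plate,
            "well": list(wells),
            "substrate": substrate,
            "timepoint": timepoint,
            "modality": modality,
            "value": np.asarray(values, dtype=float),
        }
    )
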