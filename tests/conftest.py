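import numpy as np
import pytest

from strpopgen import GenotypeTable, MarkerDef, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def sim_table():
    """Moderate synthetic study table shared across tests (fixed seed)."""
    table, truth = generate_dataset(SimConfig(n_samples=240, n_males=200, seed=7))
    return table, truth


@pytest.fixture()
def tiny_panel():
    return {
        "AUT1": MarkerDef("AUT1", "autosomal", 4),
        "AUT2": MarkerDef("AUT2", "autosomal", 4),
        "YS1": MarkerDef("YS1", "y_single", 4),
        "YM1": MarkerDef("YM1", "y_multicopy", 4),
    }


@pytest.fixture()
def tiny_table(tiny_panel):
    """Hand-built 4-sample table: 3 males, 1 female, one missing call."""
    samples = ["s1", "s2", "s3", "s4"]
    sex = {"s1": "M", "s2": "M", "s3": "M", "s4": "F"}
    diploid = {
        "AUT1": {
            "s1": ("[AGAT]9", "[AGAT]9"),
            "s2": ("[AGAT]9", "[AGAT]8[TCTG]1"),
            "s3": ("[AGAT]10", "[AGAT]9 AGA"),
            "s4": ("[AGAT]9", "[AGAT]10"),
        },
        "AUT2": {  # s4 missing here
            "s1": ("12", "12"),
            "s2": ("12", "13"),
            "s3": ("13", "14"),
        },
    }
    haploid = {
        "YS1": {"s1": ("15",), "s2": ("15",), "s3": ("16",)},
        "YM1": {"s1": ("14", "17"), "s2": ("17", "14"), "s3": ("14", "18")},
    }
    return GenotypeTable.from_calls(tiny_panel, samples, sex, diploid, haploid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
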