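import numpy as np
import pytest

from sortbind import (SimConfig, design_library, dose_response_table,
                      load_default_wildtypes, quantify, simulate_sortseq,
                      tilde_matrix)
from sortbind.synth import library_frame


@pytest.fixture(scope="session")
def wildtypes():
    return load_default_wildtypes()


def _simulate(wildtypes, n_sites, seed):
    records = design_library(wildtypes, n_sites=n_sites, control_counts=(15, 30),
                             seed=seed, n_barcodes=1, prefixes=("C",))
    cfg = SimConfig(seed=seed)
    means = dose_response_table(records, cfg)
    tensor = simulate_sortseq(means, cfg)
    lib = library_frame(records)
    return {"records": records, "cfg": cfg, "means": means, "tensor": tensor,
            "library": lib,
            "negative_ids": set(lib.loc[lib.control == "negative", "variant_id"]),
            "positive_ids": set(lib.loc[lib.control == "positive", "variant_id"])}


@pytest.fixture(scope="session")
def recovery_sim(wildtypes):
    """200 mutated sites (100 binders / 100 non-binders) plus controls."""
    return _simulate(wildtypes, n_sites=200, seed=11)


@pytest.fixture(scope="session")
def scoring_sim(wildtypes):
    """400 mutated sites (200 binders / 200 non-binders) plus controls."""
    return _simulate(wildtypes, n_sites=400, seed=1)


@pytest.fixture(scope="session")
def scoring_quantified(scoring_sim):
    dose = quantify(scoring_sim["tensor"], scoring_sim["negative_ids"],
                    scoring_sim["positive_ids"])
    return {"dose": dose, "tilde": tilde_matrix(dose), **scoring_sim}
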