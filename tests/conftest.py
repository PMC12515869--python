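import numpy as np
import pandas as pd
import pytest

import lactylome as lm


@pytest.fixture(scope="session")
def proteome_500():
    """Medium proteome reused across catalog/motif/simulation tests."""
    return lm.generate_proteome(500, 400, seed=7)


@pytest.fixture(scope="session")
def default_catalog(proteome_500):
    return lm.generate_lactylome(proteome_500, lm.SyntheticDesign(seed=7))


@pytest.fixture(scope="session")
def synthetic_run():
    """Default-condition spiked dataset with corrected table and truth."""
    proteome = lm.generate_proteome(400, 400, seed=3)
    design = lm.SyntheticDesign(seed=3)
    cat = lm.generate_lactylome(proteome, design)
    site_raw, prot_raw, truth = lm.generate_intensities(cat, design)
    corrected = lm.quantify_pipeline(site_raw, prot_raw,
                                     cat.site_protein_map(),
                                     design.group_design())
    return {
        "proteome": proteome, "design": design, "catalog": cat,
        "site_raw": site_raw, "prot_raw": prot_raw, "truth": truth,
        "corrected": corrected,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_table(values, samples=("c1", "c2", "c3", "m1", "m2", "m3"),
              features=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=features, columns=list(samples)[:values.shape[1]])


@pytest.fixture()
def design_3v3():
    return lm.GroupDesign(control=("c1", "c2", "c3"), case=("m1", "m2", "m3"))
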