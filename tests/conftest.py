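import numpy as np
import pandas as pd
import pytest

from pdxmeth import synth


@pytest.fixture(scope="session")
def annotation():
    return synth.generate_annotation(2_000, seed=11)


@pytest.fixture(scope="session")
def model(annotation):
    return synth.MethylomeModel(n_probes=len(annotation), seed=11)


@pytest.fixture(scope="session")
def beta(model, annotation):
    return synth.generate_pool(model, 4, annotation)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def toy_annotation():
    """Tiny handcrafted manifest with known feature/island structure."""
    ids = pd.Index([f"cg{i:08d}" for i in range(10)], name="probe_id")
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4 + ["chr2"] * 3 + ["chrX", "chrY", "chr3"],
            "pos": [100, 200, 300, 400, 150, 250, 350, 500, 600, 700],
            "feature": ["TSS200", "TSS200", "Body", "Body", "IGR", "IGR", "3UTR",
                        "TSS1500", "Body", "IGR"],
            "island_relation": ["Island", "Island", "None", "None", "None", "Shore",
                                "Shelf", "Island", "None", "None"],
        },
        index=ids,
    )
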