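import numpy as np
import pandas as pd
import pytest

from xenodeconv import SimulationConfig, generate_bundle
from xenodeconv.pipeline import expression_for_species, mask_species


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    """The study-design bundle: 2 lines x 4 animals x 3 regions."""
    return generate_bundle(default_config)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes_per_species=40, probes_per_set=5,
                            transcript_length=200, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def default_masks(default_bundle):
    out = {}
    for sp in ("human", "mouse"):
        _, mask = mask_species(default_bundle, sp, 15, 0.75, 3)
        out[sp] = mask
    return out


@pytest.fixture(scope="session")
def default_expression(default_bundle, default_masks):
    """Masked, reference-normalized, gene-level expression per species."""
    return {sp: expression_for_species(default_bundle, sp, default_masks[sp])
            for sp in ("human", "mouse")}


def make_sample_sheet(n_per_group=4, species="human", line="L1"):
    """Minimal one-line sample sheet with the two contrast regions."""
    regions = ("B", "A") if species == "human" else ("B", "C")
    rows = []
    for region in regions:
        for i in range(n_per_group):
            rows.append((f"{line}_M{i}_{region}", line, str(i), region, species))
    return pd.DataFrame(rows, columns=["sample_id", "line", "animal",
                                       "region", "array_species"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
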