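import numpy as np
import pandas as pd
import pytest

import citrusid as c


@pytest.fixture(scope="session")
def reference_matrix():
    """Packaged 26-cultivar reference panel (14 markers incl. rbcL)."""
    return c.load_reference_genotypes()


@pytest.fixture(scope="session")
def published_kits(reference_matrix):
    """The eight published strip kits, assembled from packaged metadata."""
    kits = {}
    for target, members in c.PUBLISHED_MARKER_SETS.items():
        unique, _ = c.verify_uniqueness(reference_matrix, target, members)
        mset = c.MarkerSet(target=target, members=tuple(sorted(members)),
                           unique=unique)
        kits[target] = c.design_kit(mset, c.kit_sizes(target))
    return kits


@pytest.fixture(scope="session")
def noisefree_sim(tmp_path_factory):
    """Small error-free simulated dataset shared across stage tests."""
    scape = c.simulate_landscape(5, 12, specific_fraction=0.25, seed=11)
    config = c.SimConfig(depth=12, error_rate=0.0, duplicate_multiplier=(1, 1),
                         qv_fail_rate=0.0, background_fraction=0.0, seed=11)
    out = tmp_path_factory.mktemp("noisefree_sim")
    paths = c.generate_reads(scape, config, out)
    return scape, config, out, paths


def random_genotype_matrix(rng: np.random.Generator, n_cultivars: int,
                           n_markers: int) -> c.GenotypeMatrix:
    data = pd.DataFrame(
        rng.integers(0, 2, size=(n_cultivars, n_markers)),
        index=[f"cv{i:02d}" for i in range(n_cultivars)],
        columns=[f"m{j:02d}" for j in range(n_markers)])
    return c.GenotypeMatrix(data)
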