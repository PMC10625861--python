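import numpy as np
import pandas as pd
import pytest

from midwater.io import DEFAULT_STRATA, ReadMatrix, build_sample_meta
from midwater.synthetic import PlantingConfig, SurveyDesign, simulate_survey


@pytest.fixture(scope="session")
def small_survey():
    """A modest synthetic survey shared by read-only tests."""
    return simulate_survey(
        60,
        SurveyDesign(reads_per_sample=20_000, seed=3),
        PlantingConfig(),
    )


@pytest.fixture(scope="session")
def meta3():
    """Metadata for the default three-province, eight-stratum survey."""
    return build_sample_meta(("Subarctic", "Transition", "Subtropical"))


@pytest.fixture()
def tiny_counts():
    """A hand-sized counts matrix over one province's day/night tows."""
    meta = build_sample_meta(("A",), strata=DEFAULT_STRATA)
    data = pd.DataFrame(
        np.zeros((3, len(meta)), dtype=int),
        index=["tx1", "tx2", "tx3"],
        columns=meta["sample_id"].tolist(),
    )
    return data, meta


def random_count_matrix(rng, n_taxa, sample_ids, max_count=50, marker="M1"):
    data = pd.DataFrame(
        rng.integers(0, max_count, size=(n_taxa, len(sample_ids))),
        index=[f"t{i}" for i in range(n_taxa)],
        columns=list(sample_ids),
    )
    return ReadMatrix(data, marker=marker)
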