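import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from agrimet import FeatureTable, StudyDesignConfig, generate_study

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


def make_table(feature_rows, intensity_rows, injections=None):
    """Build a FeatureTable from literal rows.

    ``feature_rows``: list of (feature_id, mode, mz, rt_s);
    ``intensity_rows``: list of per-feature intensity lists.
    """
    feats = pd.DataFrame(feature_rows, columns=["feature_id", "mode", "mz", "rt_s"])
    feats = feats.set_index("feature_id")
    if injections is None:
        injections = [f"I{j + 1:02d}" for j in range(len(intensity_rows[0]))]
    inten = pd.DataFrame(np.asarray(intensity_rows, dtype=float),
                         index=feats.index, columns=injections)
    return FeatureTable(feats, inten)


def make_meta(rows):
    """Metadata frame from dicts keyed by injection_id (missing fields filled)."""
    defaults = {"biological_sample_id": "S", "role": "sample", "system": "C",
                "year": 2007, "plot": 1, "extraction_batch": 1,
                "technical_replicate": 1, "sampling_duplicate": False,
                "ionization_mode": "pos"}
    full = {iid: {**defaults, **row} for iid, row in rows.items()}
    return pd.DataFrame.from_dict(full, orient="index").rename_axis("injection_id")


@pytest.fixture(scope="session")
def small_config():
    return StudyDesignConfig(n_features_pos=400, n_features_neg=200, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)
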