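import numpy as np
import pandas as pd
import pytest

import aelead as ae


@pytest.fixture(scope="session")
def sib_vocab():
    return ae.default_vocabulary("sibutramine")


@pytest.fixture(scope="session")
def ator_vocab():
    return ae.default_vocabulary("atorvastatin")


@pytest.fixture(scope="session")
def sib_config():
    # study-condition preset with the injection fractions the filter tests use
    return ae.preset_config(
        "sibutramine", n_months=137, seed=7, hearsay_frac=0.10, duplicate_frac=0.05
    )


@pytest.fixture(scope="session")
def sib_dataset(tmp_path_factory, sib_config):
    """Written synthetic CSVs for the coupled sibutramine-like scenario."""
    outdir = tmp_path_factory.mktemp("sib_data")
    paths = ae.write_dataset(sib_config, outdir)
    return paths


@pytest.fixture(scope="session")
def sib_clean(sib_dataset, sib_vocab):
    return ae.ingest(sib_dataset["reviews"], sib_dataset["reports"], sib_vocab)


def make_counts(values, start="2001-01", stream="social_media"):
    idx = pd.period_range(start, periods=len(values), freq="M")
    return ae.CountSeries(pd.Series(list(values), index=idx), stream=stream)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
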