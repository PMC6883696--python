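import numpy as np
import pandas as pd
import pytest

from intronscore import simdata, workflow
from intronscore.rbp import RbpPwm


@pytest.fixture(scope="session")
def toy_pwm():
    """Single-position PWM with counts (A:4, C:0, G:0, T:0), N=4."""
    return RbpPwm("toy", np.array([[4.0, 0.0, 0.0, 0.0]]), 4.0)


@pytest.fixture(scope="session")
def small_cfg():
    return simdata.SimConfig(seed=5, n_genes=20, n_pathogenic=150,
                             n_neutral=150)


@pytest.fixture(scope="session")
def small_bundle_paths(small_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_bundle")
    return simdata.simulate_bundle(small_cfg, out)


@pytest.fixture(scope="session")
def small_bundle(small_bundle_paths):
    return workflow.load_bundle(small_bundle_paths["fasta"].parent)


@pytest.fixture(scope="session")
def small_features(small_bundle, small_bundle_paths):
    df = workflow.feature_table(small_bundle, small_bundle_paths["vcf"])
    labels = pd.read_csv(small_bundle_paths["labels"], sep="\t")
    return df, labels


@pytest.fixture(scope="session")
def small_labels(small_features):
    _, labels = small_features
    return labels.set_index("variant_id")
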