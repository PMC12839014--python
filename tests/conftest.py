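import numpy as np
import pytest

from cdk9screen import datasets, synthdata


@pytest.fixture(scope="session")
def synth_cfg():
    return synthdata.SynthConfig(n_compounds=200, seed=11)


@pytest.fixture(scope="session")
def synth_library(synth_cfg):
    return synthdata.generate_library(synth_cfg)


@pytest.fixture(scope="session")
def activity_table(synth_library, synth_cfg):
    return synthdata.assign_activities(synth_library, synth_cfg)


@pytest.fixture(scope="session")
def decoy_smiles():
    return synthdata.generate_decoys(400, seed=12)


@pytest.fixture(scope="session")
def dataset_pairs(activity_table, decoy_smiles):
    pairs, report = datasets.build_datasets(activity_table, decoy_smiles, seed=13)
    return pairs, report


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def partition_of(labels):
    """Canonical set-of-frozensets form of a cluster labeling."""
    labels = np.asarray(labels)
    return {frozenset(np.where(labels == c)[0].tolist()) for c in set(labels.tolist())}
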