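"""Shared fixtures: synthetic pockets, campaigns and small libraries.

Everything is generated programmatically with fixed seeds; no stored data.
"""

import numpy as np
import pytest

from zincscreen.funnel import run_funnel
from zincscreen.records import MoleculeRecord
from zincscreen.synthetic import LibrarySpec, gen_campaign, gen_pocket


@pytest.fixture(scope="session")
def pocket():
    return gen_pocket(seed=42)


@pytest.fixture(scope="session")
def campaign():
    """A 200-ligand synthetic screening campaign with planted composition."""
    return gen_campaign(LibrarySpec(n=200, seed=202))


@pytest.fixture(scope="session")
def funnel_report(campaign):
    return run_funnel(
        campaign.config, campaign.records, campaign.receptors, campaign.backend
    )


@pytest.fixture()
def benzohydroxamate_anion():
    return MoleculeRecord.from_smiles("bha-anion", "[O-]NC(=O)c1ccccc1")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
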