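import numpy as np
import pytest

import wgdscan as w

FOUR_TAXON_NEWICK = "((A:0.3,B:0.3)AB:0.4,(C:0.5,O:0.5)CO:0.2)R;"


@pytest.fixture(scope="session")
def four_taxon_newick():
    return FOUR_TAXON_NEWICK


@pytest.fixture(scope="session")
def four_taxon_spec():
    return w.SpeciesTreeSpec(FOUR_TAXON_NEWICK)


@pytest.fixture(scope="session")
def planted_dataset(four_taxon_spec):
    """A desk-scale dataset with one WGD planted at the A+B ancestor
    (pair age Ks 1.1, retention 0.8)."""
    episode = w.WGDEpisode("AB", 1.1, 0.8, id="e1")
    return w.simulate_wgd_dataset(
        four_taxon_spec, [episode], n_families=150,
        ssd_rate=0.05, loss_rate=0.02, mean_length_codons=150, seed=11,
    )


@pytest.fixture(scope="session")
def clean_dataset(four_taxon_spec):
    """No duplications at all: single copy everywhere."""
    return w.simulate_wgd_dataset(
        four_taxon_spec, [], n_families=40,
        ssd_rate=0.0, loss_rate=0.0, mean_length_codons=120, seed=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_sense_cds(n_codons, rng):
    from wgdscan import codons as ct

    idx = rng.choice(ct.SENSE_CODONS, size=n_codons)
    return "".join(ct.CODONS[i] for i in idx)
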