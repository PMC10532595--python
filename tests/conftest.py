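import numpy as np
import pytest

from fucomass import (
    GeneratorParams,
    GlycanStructure,
    sample_structure,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230912)


def random_oligo(rng, min_dp=3, max_dp=5, p_gal_branch=0.3, labeled=True) -> GlycanStructure:
    """A small sulfated oligosaccharide from the generative model."""
    params = GeneratorParams(
        min_dp=min_dp, max_dp=max_dp, p_gal_branch=p_gal_branch,
        p_sulf_2=0.6, p_sulf_4=0.3,
    )
    s = sample_structure(params, seed=rng)
    s.labeled = labeled
    return s


def random_sulfated_oligo(rng, **kwargs) -> GlycanStructure:
    """Like :func:`random_oligo` but guaranteed to carry >= 1 sulfate."""
    while True:
        s = random_oligo(rng, **kwargs)
        if s.composition().n_sulf >= 1:
            return s


@pytest.fixture
def pentasaccharide() -> GlycanStructure:
    """The linear Gal-(1->3)-[Fuc-(1->3)]3-Fuc-(1->4) pentasaccharide variant
    discussed for the tetrasulfated Fuc4Gal precursor (sulfates on the Gal
    4-position and the internal fucose 2-positions)."""
    from fucomass import parse_structure

    return parse_structure(
        "Gal(4S)a1-3Fuc(2S)a1-3Fuc(2S)a1-3Fuc(2S)a1-4Fuc!18O"
    )
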