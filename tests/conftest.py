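import numpy as np
import pytest

from slc_evo.synthetic import (DEFAULT_FAMILY_SPECS, NeighborhoodSpec,
                               balanced_tree, family_seed, make_family,
                               make_neighborhood, synthetic_references)

BASE_SEED = 5

# genomic-context templates for the two context-dependent families: the
# candidate gene sits near its diagnostic neighbors (TOP3B for VpreB1;
# SLC5A4 / the lambda locus for VpreB2)
CONTEXT_GENES = {
    "VpreB1": (("MIF", "+"), ("CANDIDATE", "-"), ("IGLL1", "-"),
               ("TOP3B", "+")),
    "VpreB2": (("SLC5A1", "+"), ("SLC5A4", "+"), ("CANDIDATE", "-"),
               ("IGL", "+")),
}


@pytest.fixture(scope="session")
def references():
    return synthetic_references(BASE_SEED)


@pytest.fixture(scope="session")
def benchmark_families():
    """5 families x 20 leaves at substitution rate 0.1, with ground truth."""
    tree = balanced_tree(20, 0.05)
    out = {}
    for label, spec in DEFAULT_FAMILY_SPECS.items():
        spec = type(spec)(**{**spec.__dict__, "substitution_rate": 0.1})
        out[label] = make_family(spec, tree, family_seed(label, BASE_SEED))
    return out


@pytest.fixture(scope="session")
def family_contexts():
    out = {}
    for label, genes in CONTEXT_GENES.items():
        spec = NeighborhoodSpec(gene_order=genes,
                                anchors=(genes[0][0], genes[-1][0]))
        _, ctx, _ = make_neighborhood(spec, 0)
        out[label] = ctx
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(BASE_SEED)
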