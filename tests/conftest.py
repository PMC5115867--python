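import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message=".*Bio.codonalign.*")
warnings.filterwarnings("ignore", message=".*fewer than 8 samples.*")


@pytest.fixture(scope="session")
def species_tree():
    from edsnet.simulate import make_species_tree

    return make_species_tree("nicotiana6")


@pytest.fixture(scope="session")
def seed1_expression(species_tree):
    """The canonical seed-1 six-species count experiment."""
    from edsnet.simulate import simulate_expression

    counts, lengths, meta, truth = simulate_expression(species_tree, seed=1)
    return counts, lengths, meta, truth


@pytest.fixture(scope="session")
def seed1_adjusted(seed1_expression):
    """Seed-1 data carried through TMM/FPKM/log2/batch adjustment."""
    from edsnet import expression as ex

    counts, lengths, meta, _ = seed1_expression
    fpkm = ex.fpkm_matrix(counts, lengths, ex.tmm_factors(counts))
    logf = np.log2(fpkm + 1.0)
    return ex.batch_adjust(logf, meta["species"], meta["treatment"]), meta


@pytest.fixture(scope="session")
def seed1_modules(seed1_adjusted):
    """Seed-1 network, detected modules and module statistics."""
    from edsnet import coexpression as cx

    adjusted, meta = seed1_adjusted
    net = cx.build_network(adjusted, 6)
    modules = cx.detect_modules(net, 30, 0.98)
    modules = cx.module_statistics(adjusted, net, modules)
    return net, modules
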