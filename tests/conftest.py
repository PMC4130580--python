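import numpy as np
import pytest

from plaskew import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def model_mixture_community():
    """Two-plasmid model mixture: 4.4 kb high-copy vector + 56 kb conjugative
    plasmid, no gDNA, mixed 1:1 by mass downstream."""
    return sim.sample_community(
        n_plasmids=2,
        sizes=[4400, 56000],
        copy_numbers=[20.0, 4.0],
        gdna_mass_fraction=0.0,
        seed=1,
    )


@pytest.fixture
def model_mixture_pool(model_mixture_community):
    return sim.to_pool(model_mixture_community)


@pytest.fixture
def two_mode_community():
    """Bimodal community: small cryptic plasmids (1.2-2.5 kb) and large
    conjugative plasmids (55-90 kb). The modes sit far enough apart on the
    gel-recovery curve that size selection flips which mode dominates the
    sequenced library, driving the two exclusivity fractions apart."""
    rng = np.random.default_rng(7)
    n_small, n_large = 8, 8
    sizes = [int(x) for x in rng.integers(1200, 2501, n_small)]
    sizes += [int(x) for x in rng.integers(55000, 90001, n_large)]
    copy_numbers = [float(cn) for cn in rng.uniform(15, 20, n_small)]
    copy_numbers += [float(cn) for cn in rng.uniform(4, 7, n_large)]
    return sim.sample_community(
        n_plasmids=n_small + n_large,
        sizes=sizes,
        copy_numbers=copy_numbers,
        gdna_mass_fraction=0.0,
        seed=7,
    )
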