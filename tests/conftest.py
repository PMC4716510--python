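import itertools

import numpy as np
import pytest

from kindyad import Locus, gen_frequencies
from kindyad.genotype_io import make_genotype


@pytest.fixture(scope="session")
def equifreq_panel():
    """18 loci x 8 equally frequent alleles — the reference test panel."""
    return gen_frequencies(18, 8, float("inf"), seed=11)


@pytest.fixture(scope="session")
def dirichlet_panel():
    """18 loci x 8 alleles, Dirichlet(2) frequencies."""
    return gen_frequencies(18, 8, 2.0, seed=12)


@pytest.fixture
def triallelic_locus():
    return Locus("tri", (1, 2, 3), (0.5, 0.3, 0.2))


def enumerate_pair_distribution(k, locus):
    """Independent oracle: exact distribution of an unordered genotype pair
    under the dyad generative model, by brute-force enumeration of the gene
    draws for each IBD state."""
    dist = {}
    p = dict(zip(locus.alleles, locus.freqs))
    alleles = locus.alleles

    def add(g1, g2, prob):
        key = (g1, g2)
        dist[key] = dist.get(key, 0.0) + prob

    # state 2: both genotypes are the same pair {x,y}
    for x, y in itertools.product(alleles, repeat=2):
        g = make_genotype(x, y)
        add(g, g, k[2] * p[x] * p[y])
    # state 1: shared gene x; genotypes {x,y} and {x,z}
    for x, y, z in itertools.product(alleles, repeat=3):
        add(make_genotype(x, y), make_genotype(x, z),
            k[1] * p[x] * p[y] * p[z])
    # state 0: four independent genes
    for x, y, z, w in itertools.product(alleles, repeat=4):
        add(make_genotype(x, y), make_genotype(z, w),
            k[0] * p[x] * p[y] * p[z] * p[w])
    return dist


def grid_search_dyadml(dyad, freqs, step=0.01):
    """Independent oracle: dense simplex grid search of the dyad likelihood.

    Per-locus pair probabilities are linear in (k0,k1,k2), so the grid
    log-likelihood is accumulated from the three mixture components.
    """
    from kindyad.relatedness import locus_component_probs

    ks = []
    n = int(round(1.0 / step))
    for i in range(n + 1):
        for j in range(n + 1 - i):
            ks.append((i * step, j * step, 1.0 - i * step - j * step))
    ks = np.asarray(ks)
    lls = np.zeros(len(ks))
    for name in freqs.names:
        g1, g2 = dyad.g1.get(name), dyad.g2.get(name)
        if g1 is None or g2 is None:
            continue
        c = np.asarray(locus_component_probs(g1, g2, freqs[name]))
        with np.errstate(divide="ignore"):
            lls += np.log(ks @ c)
    m = int(np.argmax(lls))
    k = ks[m]
    return float(k[1] / 2.0 + k[2]), float(lls[m])
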