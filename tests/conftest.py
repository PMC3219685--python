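import numpy as np
import pytest

from cvarkit.io_formats import FeatureTable, GeneFeature, Replicon
from cvarkit.regulon import BASES, BindingSiteSet, build_pwm


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def random_protein(rng, n):
    return "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n - 1))


@pytest.fixture
def toy_replicon(rng):
    return Replicon(id="toy", seq=random_dna(rng, 10_000))


@pytest.fixture
def strong_pwm():
    """A sharply informative 14-bp PWM (consensus-dominated columns)."""
    consensus = "TTAGGTTAGCCTAA"
    sites = []
    for i in range(10):
        s = list(consensus)
        if i % 2:  # one off-consensus base in alternating sites
            s[i % len(s)] = BASES[(BASES.index(s[i % len(s)]) + 1) % 4]
        sites.append("".join(s))
    return build_pwm(BindingSiteSet("toyTF", sites), pseudocount=0.5)


def make_table(genes, replicon_id="toy"):
    """genes: iterable of (tag, start, end, strand[, ftype])."""
    feats = [GeneFeature(*g) if len(g) > 4 else GeneFeature(*g, "CDS") for g in genes]
    return FeatureTable(replicon_id=replicon_id, features=feats)
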