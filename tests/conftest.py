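import numpy as np
import pytest

from microinv.io import Alignment, parse_tree, packaged_locus_table
from microinv.simulate import yule_tree


@pytest.fixture(scope="session")
def avian_records():
    """The packaged 17-locus avian summary table."""
    return packaged_locus_table()


@pytest.fixture
def balanced_tree():
    """((A,B),(C,D)) with unit branch lengths."""
    return parse_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


def plant_inversion(seq, start, length):
    """Return seq with [start, start+length) reverse-complemented."""
    from microinv.detect import reverse_complement
    seg = seq[start:start + length]
    return seq[:start] + reverse_complement(seg) + seq[start + length:]


@pytest.fixture
def zero_divergence_alignment(rng):
    """Factory: n-taxon alignment, identical but for one planted inversion."""
    def make(n_taxa=6, n_carriers=3, length=500, inv_start=200, inv_len=22,
             seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        base = random_sequence(local, length)
        # block chance complementarity across the tract boundary, which
        # would legitimately (and correctly) extend the detected endpoints
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        end = inv_start + inv_len
        if base[inv_start - 1] == comp[base[end]]:
            repl = {"A": "C", "C": "A", "G": "T", "T": "G"}[base[inv_start - 1]]
            base = base[:inv_start - 1] + repl + base[inv_start:]
        inverted = plant_inversion(base, inv_start, inv_len)
        taxa = [f"t{i}" for i in range(n_taxa)]
        rows = [inverted if i < n_carriers else base for i in range(n_taxa)]
        return Alignment("sim", taxa, rows), set(taxa[:n_carriers])
    return make
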