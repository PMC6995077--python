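import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from peakscreen.io import GenomeSequence, GenomicInterval, GeneAnnotation
from peakscreen.motifs import compile_pattern


@pytest.fixture(scope="session")
def default_pattern():
    return compile_pattern()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture()
def tiny_genome():
    """One contig with a planted dyad motif (CATG-AA-CATG) flanked so that a
    single AGG PAM sits a few bp right of the motif."""
    left = "T" * 40
    motif = "CATGAACATG"
    # AGG PAM 5 bp right of the motif end; protospacer extends left over it
    right = "TTTTTAGG" + "T" * 40
    seq = left + motif + right
    return GenomeSequence({"c1": seq}), GenomicInterval("c1", 30, 70, ".", "peak_1")


@pytest.fixture()
def small_annotation():
    genes = [
        GeneAnnotation("g1", GenomicInterval("c1", 100, 500, "+", "g1"), True),
        GeneAnnotation("g2", GenomicInterval("c1", 900, 1400, "-", "g2"), False),
    ]
    return genes
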