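"""Shared fixtures: toy genomes, a hand-built gene fixture, signature matrices."""

import numpy as np
import pandas as pd
import pytest

from malspectra import Genome, random_genome
from malspectra.annotation import GeneModel
from malspectra.signatures import SignatureMatrix
from malspectra.spectra import CHANNELS_96, revcomp


@pytest.fixture(scope="session")
def toy_genome():
    """Small multi-chromosome genome with a mitochondrial chromosome."""
    return random_genome(
        {"chrI": 60_000, "chrII": 80_000, "chrIII": 100_000, "chrM": 20_000},
        seed=11,
        mito_id="chrM",
    )


@pytest.fixture(scope="session")
def yeast_scale_genome():
    """Nuclear genome at the callable length of the real reference (~12.07 Mb)."""
    return random_genome({"chr1": 6_000_000, "chr2": 6_071_326}, seed=42)


@pytest.fixture(scope="session")
def mito_scale_genome():
    """One nuclear chromosome plus a yeast-mtDNA-sized chromosome (~75 kb)."""
    return random_genome(
        {"chr1": 100_000, "chrM": 75_000}, seed=7, mito_id="chrM"
    )


# Hand-built two-gene fixture. The minus-strand gene's coding sequence reads
# ATG GCT AAA TGG CAT CAA GAT TTC GGA CCC GTT TAA
# (M A K W H Q D F G P V *), placed reverse-complemented at chrT:[10, 46).
MINUS_CODING = "ATGGCTAAATGGCATCAAGATTTCGGACCCGTTTAA"
PLUS_CODING = "ATGAAACCCTAA"  # M K P * at chrP:[4, 16)


@pytest.fixture(scope="session")
def gene_fixture():
    chr_t = "ACGTACGTAC" + revcomp(MINUS_CODING) + "GATCGATCGATCGATCGATCGATCGATCGATCGA"
    chr_p = "TTTT" + PLUS_CODING + "GGGGCCCCAAAATTTTGGGG"
    genome = Genome({"chrT": chr_t, "chrP": chr_p})
    minus_gene = GeneModel("gMinus", "chrT", "-", ((10, 46),))
    plus_gene = GeneModel("gPlus", "chrP", "+", ((4, 16),))
    return genome, [minus_gene, plus_gene]


def make_signature_matrix(k: int = 4, seed: int = 0, concentration: float = 0.3):
    """Random dirichlet signature columns over the 96 canonical channels."""
    rng = np.random.default_rng(seed)
    cols = {
        f"SBS{i + 1}": rng.dirichlet(np.full(96, concentration)) for i in range(k)
    }
    return SignatureMatrix(pd.DataFrame(cols, index=list(CHANNELS_96)))


@pytest.fixture(scope="session")
def signature_matrix():
    return make_signature_matrix(k=4, seed=0)
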