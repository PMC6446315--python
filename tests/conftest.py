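import numpy as np
import pandas as pd
import pytest

from popscan.core_io import GenotypeMatrix, PopulationManifest


def build_matrix(
    dosages,
    positions=None,
    contig="chr1",
    length=None,
    is_indel=False,
    sample_prefix="s",
):
    """GenotypeMatrix from a (sites x samples) dosage list for toy tests."""
    d = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = d.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    positions = np.asarray(positions)
    if length is None:
        length = int(positions.max()) + 1000 if len(positions) else 1000
    sites = pd.DataFrame(
        {
            "contig": contig,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "is_indel": is_indel,
        }
    )
    samples = [f"{sample_prefix}{i}" for i in range(n_samples)]
    return GenotypeMatrix([(contig, length)], sites, d, samples)


@pytest.fixture
def two_pop_manifest():
    pops = {f"a{i}": "popA" for i in range(3)} | {f"b{i}": "popB" for i in range(3)}
    return PopulationManifest(populations=pops)
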