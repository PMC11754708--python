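import numpy as np
import pandas as pd
import pytest

from transpoly.io_core import GenotypeMatrix, make_sample_table, make_site_table


@pytest.fixture
def small_gm():
    """3 samples x 2 sites with genotypes (0,1,2) at site 1, (1,-1,0) at 2."""
    samples = make_sample_table(["s1", "s2", "s3"], species=["A", "A", "B"],
                                mean_coverage=[10.0, 20.0, 15.0])
    sites = make_site_table(["chr1", "chr1"], [100, 200], ["A", "C"],
                            ["G", "T"], annotation=["SYN", "NS"])
    g = np.array([[0, 1], [1, -1], [2, 0]], dtype=np.int8)
    return GenotypeMatrix(samples, sites, g)


def build_gm(genotypes, species, allele_depths=None, annotation=None,
             coverage=None):
    """Genotype matrix from a raw (n_samples, n_sites) array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, s = g.shape
    samples = make_sample_table([f"s{i:03d}" for i in range(n)],
                                species=species, mean_coverage=coverage)
    sites = make_site_table(["chr1"] * s, np.arange(1, s + 1) * 10,
                            ["A"] * s, ["T"] * s, annotation=annotation)
    return GenotypeMatrix(samples, sites, g, allele_depths=allele_depths)
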