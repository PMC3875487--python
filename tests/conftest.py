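import numpy as np
import pytest

from gulo_phylogeo.distance import pairwise_differences
from gulo_phylogeo.samples import tabulate_regions
from gulo_phylogeo.synthetic import make_fixture


@pytest.fixture(scope="session")
def mng():
    """Six individuals, haplotype counts {5, 1}, two substitution differences."""
    aln, records = make_fixture("MNG")
    samples = tabulate_regions(records, include_pooled=False)
    return aln, samples[0], pairwise_differences(aln)


@pytest.fixture(scope="session")
def swe_nor():
    """61+1 vs 108 individuals; the rare haplotype differs by two
    substitutions plus one indel."""
    aln, records = make_fixture("SWE_NOR")
    samples = tabulate_regions(records, include_pooled=False)
    swe = next(s for s in samples if s.region == "SWE")
    nor = next(s for s in samples if s.region == "NOR")
    return aln, swe, nor


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2013)


def random_alignment(rng, n_haps, L=40, n_var=8):
    """Small random alignment with a handful of variable positions."""
    base = rng.choice(list("ACGT"), size=L)
    seqs = []
    var_pos = rng.choice(L, size=n_var, replace=False)
    for _ in range(n_haps):
        s = base.copy()
        for p in var_pos:
            if rng.random() < 0.5:
                s[p] = rng.choice([c for c in "ACGT" if c != base[p]])
        seqs.append("".join(s))
    from gulo_phylogeo.alignment import collapse_haplotypes

    ids = [f"s{i}" for i in range(n_haps)]
    return collapse_haplotypes(list(zip(ids, seqs)))
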