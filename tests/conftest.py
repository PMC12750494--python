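import numpy as np
import pytest

import introscan as isc


@pytest.fixture(scope="session")
def default_panel():
    """Default 30-line panel with one segment, one translocation and one
    contig haplotype; shared across tests because it is deterministic."""
    config = isc.default_config(seed=1)
    refs, truth = isc.build_panel(config)
    return config, refs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def brute_force_site_pi(column) -> float:
    """Mean pairwise difference over all pairs of called alleles."""
    alleles = []
    for g in column:
        if g == -1:  # missing
            continue
        alleles.extend({0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(g)])
    n = len(alleles)
    assert n >= 2
    diffs = [
        int(alleles[i] != alleles[j]) for i in range(n) for j in range(i + 1, n)
    ]
    return sum(diffs) / len(diffs)


def brute_force_filter(matrix, config):
    """Site-by-site reimplementation of the MAF/missing/het filter."""
    keep = []
    for col in matrix.genotypes:
        n_total = len(col)
        called = [g for g in col if g != -1]
        if not called:
            keep.append(False)
            continue
        alt = sum(int(g) for g in called)
        total = 2 * len(called)
        alt_freq = alt / total
        maf = 1.0 - max(alt_freq, 1.0 - alt_freq)
        missing_frac = (n_total - len(called)) / n_total
        het_frac = sum(1 for g in called if g == 1) / len(called)
        keep.append(
            maf >= config.maf_min
            and missing_frac <= config.max_missing
            and het_frac <= config.max_het
        )
    return np.array(keep)
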