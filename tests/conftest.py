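import numpy as np
import pandas as pd
import pytest

from pedscan.genio import GenotypeMatrix


def make_matrix(calls, positions=None, chrom="chr1", chrom_size=None,
                ref="A", alt="T"):
    """Build a single-chromosome GenotypeMatrix from a calls array.

    ``calls`` is (n_sites, n_samples) with -1 for missing; positions
    default to 10, 20, 30, ...
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if positions is None:
        positions = [10 * (i + 1) for i in range(n_sites)]
    if chrom_size is None:
        chrom_size = (max(positions) if len(positions) else 0) + 10
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": positions,
            "ref": [ref] * n_sites,
            "alt": [alt] * n_sites,
        }
    )
    samples = [f"S{i:02d}" for i in range(n_samples)]
    return GenotypeMatrix(variants, samples, calls, {chrom: chrom_size})


def brute_force_pi(calls, length):
    """Independent π oracle: per site, the mean mismatch over all
    mutually non-missing sample pairs; summed and divided by length."""
    calls = np.asarray(calls)
    n_sites, n_samples = calls.shape
    total = 0.0
    for s in range(n_sites):
        num = den = 0
        for i in range(n_samples):
            for j in range(i + 1, n_samples):
                if calls[s, i] >= 0 and calls[s, j] >= 0:
                    den += 1
                    num += int(calls[s, i] != calls[s, j])
        if den > 0:
            total += num / den
    return total / length


@pytest.fixture(scope="session")
def standard_sim():
    """One standard-scale simulated dataset shared across tests."""
    from pedscan import pedsim

    return pedsim.simulate_dataset(pedsim.standard_config(11))
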