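import numpy as np
import pytest

from hotspotclass import simulate as sim


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic dataset (50/20/30 class 1/2A/2B per strain).

    The genome in the bundle carries the planted motifs.
    """
    config = sim.SimulationConfig(seed=7)
    genome = sim.simulate_genome(config)
    data = sim.simulate_sites_and_peaks(config, genome)
    return data


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def brute_force_overlaps(set_a, set_b, min_overlap=1):
    """All-pairs overlap oracle, independent of the interval-tree path.

    Returns, for each interval of (sorted) A, the sorted list of
    overlapping B intervals, using numpy broadcasting per chromosome.
    """
    a_ivs = list(set_a)
    b_ivs = list(set_b)
    out = [[] for _ in a_ivs]
    chroms = {iv.chrom for iv in a_ivs} | {iv.chrom for iv in b_ivs}
    for chrom in chroms:
        ai = [i for i, iv in enumerate(a_ivs) if iv.chrom == chrom]
        bi = [i for i, iv in enumerate(b_ivs) if iv.chrom == chrom]
        if not ai or not bi:
            continue
        a_start = np.array([a_ivs[i].start for i in ai])
        a_end = np.array([a_ivs[i].end for i in ai])
        b_start = np.array([b_ivs[i].start for i in bi])
        b_end = np.array([b_ivs[i].end for i in bi])
        ov = np.minimum(a_end[:, None], b_end[None, :]) - np.maximum(
            a_start[:, None], b_start[None, :]
        )
        for r, c in zip(*np.nonzero(ov >= min_overlap)):
            out[ai[r]].append(b_ivs[bi[c]])
    key = lambda iv: (iv.chrom, iv.start, iv.end, iv.name or "")
    return [sorted(hits, key=key) for hits in out]
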