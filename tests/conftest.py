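import numpy as np
import pandas as pd
import pytest

from admixbreed import FounderModel, cwd_schedule, simulate_breed
from admixbreed.containers import GeneticMap, GenotypeMatrix, HaplotypeSet


def build_gm(calls, groups=None, chrom=None, pos=None, sample_ids=None):
    """Construct a small GenotypeMatrix from a 2-D call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if groups is None:
        groups = ["other"] * n
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = []
        counter = {}
        for c in chrom:
            counter[c] = counter.get(c, 0) + 1
            pos.append(counter[c] * 1000)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    sites = pd.DataFrame({"chrom": np.asarray(chrom, dtype=object),
                          "pos": np.asarray(pos, dtype=np.int64),
                          "allele1": "A", "allele2": "B"})
    return GenotypeMatrix(sample_ids=sample_ids,
                          groups=np.asarray(groups, dtype=object),
                          sites=sites, calls=calls)


@pytest.fixture
def make_gm():
    return build_gm


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale breed simulation shared across the session."""
    return simulate_breed(FounderModel(seed=11), cwd_schedule(), GeneticMap(),
                          seed=11)


@pytest.fixture(scope="session")
def small_model():
    """Desk-scale founder model for multi-seed loops."""
    def factory(seed, n_sites=800, n_chrom=3):
        return FounderModel(
            n_sites=n_sites,
            chrom_lengths={str(c): 50_000_000 for c in range(1, n_chrom + 1)},
            seed=seed)
    return factory


@pytest.fixture(scope="session")
def deconvolved(default_sim):
    """Reference panel, breed query and ancestry track on the default sim."""
    from admixbreed import ancestry as anc
    sim = default_sim
    haps = sim.haplotypes
    panel_groups = {s: g for s, g in zip(sim.genotypes.sample_ids,
                                         sim.genotypes.groups)
                    if g in ("wild_parent", "dom_parent")}
    pidx = [haps.sample_ids.index(s) for s in panel_groups]
    prows = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in pidx]))
    panel = HaplotypeSet([haps.sample_ids[i] for i in pidx], haps.sites,
                         haps.haplotypes[prows])
    ref = anc.build_reference(panel, panel_groups)
    breed = sim.breed_sample_ids()
    bidx = [haps.sample_ids.index(s) for s in breed]
    brows = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in bidx]))
    query = HaplotypeSet([haps.sample_ids[i] for i in bidx], haps.sites,
                         haps.haplotypes[brows])
    track = anc.deconvolve(query, ref)
    return sim, ref, track
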