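import numpy as np
import pytest

from popdiag import filters as flt
from popdiag import synthetic as syn


def make_table(dosages, populations, chrom=None, pos=None, polarized=True,
               ref="A", alt="G"):
    """Small VariantTable from a nested dosage list (sites x samples).

    ``populations`` is a list of labels, one per sample column; sample
    ids are generated as <pop>_<k>.
    """
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    counters: dict = {}
    samples, popmap = [], {}
    for p in populations:
        k = counters.get(p, 0)
        counters[p] = k + 1
        s = f"{p}_{k}"
        samples.append(s)
        popmap[s] = p
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if chrom is None:
        chrom = ["chr1"] * n_sites
    return flt.VariantTable(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        dosage=dosages,
        samples=samples,
        populations=popmap,
        ref=np.array([ref] * n_sites, dtype=object),
        alt=np.array([alt] * n_sites, dtype=object),
        ancestral=np.array([ref] * n_sites, dtype=object) if polarized else None,
        polarized=polarized,
    )


@pytest.fixture
def toy_pattern_table():
    """3 populations x 1 individual, 5 sites: A-only, A+B, B-only,
    C-only, all -- unique counts A=1, B=1, C=1 of 5 retained."""
    return make_table(
        [
            [2, 0, 0],
            [1, 1, 0],
            [0, 2, 0],
            [0, 0, 1],
            [1, 1, 2],
        ],
        ["A", "B", "C"],
    )


@pytest.fixture
def focal_model():
    return syn.star_model({"focal": 0.5, "popA": 0.05, "popB": 0.05},
                          outgroup="og")


@pytest.fixture
def small_sim(focal_model):
    cfg = syn.SimConfig(n_sites=2000, n_per_pop=5, seed=11,
                        missing_rate=0.02)
    vt, truth = syn.simulate_genotypes(focal_model, cfg)
    return vt, truth, cfg


@pytest.fixture
def polarized_sim(small_sim):
    vt, truth, cfg = small_sim
    og = [s for s in vt.samples if vt.populations[s] == "og"]
    return flt.polarize(vt, og), truth
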