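import numpy as np
import pandas as pd
import pytest

from evopot import GenotypeTable, LineageMap, SynthSpec, simulate_structured_genotypes


def make_table(genotypes, pos=None, chrom="1", ref="A", alt="T", samples=None,
               depth=None):
    """Small helper: build a GenotypeTable from a (sites x samples) list."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 1000
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeTable(sites, list(samples), g, depth)


@pytest.fixture(scope="session")
def two_lineage_panel():
    """Balding-Nichols panel with F=0.4, two lineages, outgroup."""
    spec = SynthSpec(
        n_lineages=2,
        samples_per_lineage=(25, 25),
        target_fst=0.4,
        n_sites=20_000,
        seed=11,
    )
    return simulate_structured_genotypes(spec)


@pytest.fixture(scope="session")
def four_lineage_panel():
    """Diversity-graded four-lineage panel mimicking increasing drift
    (CongoBasin least drifted ... Nigeria most drifted)."""
    spec = SynthSpec(
        n_lineages=4,
        samples_per_lineage=(12, 12, 12, 12),
        target_fst=(0.05, 0.15, 0.45, 0.65),
        lineage_names=("CongoBasin", "CameroonGabon", "WestAfrica", "Nigeria"),
        n_sites=12_000,
        seed=13,
    )
    return simulate_structured_genotypes(spec)
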