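import numpy as np
import pytest

import azcma
from azcma import synthetic_data as sd


@pytest.fixture(scope="session")
def small_spec():
    return azcma.GenomeSpec(
        chromosome_lengths=[("chr1", 120_000), ("chr2", 80_000)],
        pr_fraction=0.10,
        h3k9me3_genome_fraction=0.30,
        cds_count=12,
        cds_length_mean=600,
        gc_content=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return azcma.generate_genome(small_spec)


@pytest.fixture(scope="session")
def small_injection(small_bundle):
    # rates scaled up so the 200-kb toy genome yields a few hundred mutations
    model = azcma.MutagenesisModel(
        rates={"PR": 2.1e-5, "nonPR_H3K9me3": 1.4e-5, "non_H3K9me3": 6.0e-6},
        seed=11,
    )
    return model, azcma.inject_mutations(small_bundle, model)


@pytest.fixture(scope="session")
def small_mutations(small_bundle, small_injection):
    _, res = small_injection
    calls = [v for line in res.variants.values() for v in line]
    retained, _ = azcma.apply_ma_filters(calls, res.ancestor)
    muts = azcma.annotate_mutations(
        retained, small_bundle.sequences, small_bundle.transcripts,
        small_bundle.h3k9me3, small_bundle.pr,
    )
    return azcma.mutations_to_frame(muts)


@pytest.fixture(scope="session")
def small_regions(small_bundle):
    return azcma.RegionAnnotation.from_bundle(small_bundle)
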