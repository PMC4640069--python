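import numpy as np
import pytest

from metacomm import CountTable, generate_cohort, rarefy
from metacomm.simulate import CohortSpec


@pytest.fixture(scope="session")
def small_cohort():
    """A small, well-separated 3-metacommunity paired cohort."""
    spec = CohortSpec(
        n_taxa=50, K=3, n_controls=24, n_adenoma_pairs=12, n_carcinoma_pairs=12,
        depth_mean=3000, seed=11,
    )
    table, records, truth = generate_cohort(spec)
    return spec, table, records, truth


@pytest.fixture(scope="session")
def small_rarefied(small_cohort):
    """The small cohort rarefied to depth 500, metadata pruned to kept pairs."""
    _, table, records, _ = small_cohort
    rt, _ = rarefy(table, 500, seed=1)
    keep = set(rt.sample_ids)
    kept = [r for r in records if r.sample_id in keep]
    per_pair = {}
    for r in kept:
        if r.pair_id:
            per_pair[r.pair_id] = per_pair.get(r.pair_id, 0) + 1
    kept = [r for r in kept if r.pair_id is None or per_pair[r.pair_id] == 2]
    return rt, kept


@pytest.fixture
def tiny_table():
    return CountTable(
        ["t1", "t2", "t3"],
        ["s1", "s2"],
        np.array([[5, 0], [3, 2], [2, 8]]),
    )
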