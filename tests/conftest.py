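import numpy as np
import pandas as pd
import pytest

from exsitu_audit.genotype_io import MISSING, META_COLUMNS, GenotypeMatrix


def make_gm(calls_by_individual, loci=None, meta=None):
    """Build a GenotypeMatrix from {individual: [(a1, a2), ...]}.

    ``meta`` maps individual -> dict of metadata fields; unspecified fields
    default to a single in situ East population.
    """
    individuals = list(calls_by_individual)
    n_loci = len(next(iter(calls_by_individual.values())))
    loci = loci or [f"loc{l + 1}" for l in range(n_loci)]
    calls = np.array([calls_by_individual[i] for i in individuals])
    meta = meta or {}
    records = {}
    for ind in individuals:
        rec = {"population": "pop_1", "region": "East", "cohort": "in_situ",
               "garden": None, "maternal_line": None, "source_population": None}
        rec.update(meta.get(ind, {}))
        records[ind] = rec
    meta_df = pd.DataFrame.from_dict(records, orient="index")[META_COLUMNS]
    meta_df.index.name = "id"
    return GenotypeMatrix(individuals, loci, calls, meta_df)


M = (MISSING, MISSING)


@pytest.fixture
def five_ind_fixture():
    """Five individuals, two loci; one missing call; one clonal pair."""
    return make_gm({
        "i1": [(1, 2), (5, 5)],
        "i2": [(1, 2), (5, 5)],            # clone of i1
        "i3": [(2, 2), (5, 6)],
        "i4": [(1, 3), M],                 # missing at locus 2
        "i5": [(3, 3), (6, 6)],
    })


@pytest.fixture
def two_cohort_fixture():
    """Wild reference plus an ex situ cohort holding a strict allele subset."""
    wild = {
        "w1": [(1, 1), (5, 5)],
        "w2": [(1, 2), (5, 6)],
        "w3": [(1, 3), (5, 5)],
        "w4": [(2, 2), (6, 7)],
    }
    ex = {
        "x1": [(1, 2), (5, 5)],
        "x2": [(1, 1), (5, 6)],
    }
    meta = {k: {"cohort": "ex_situ", "garden": "g1", "source_population": "pop_1",
                "maternal_line": "m1"} for k in ex}
    return make_gm({**wild, **ex}, meta=meta)
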