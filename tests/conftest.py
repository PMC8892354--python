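import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import odomorph as om

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def design():
    return om.gen_design()


@pytest.fixture(scope="session")
def small_sim(design):
    """Small seeded generation for mechanics tests (not recovery tests)."""
    cm, truth = om.gen_counts(design, n_features=300, seed=42)
    return cm, truth


@pytest.fixture(scope="session")
def screen_fixture():
    return om.plant_screen_cases()


@pytest.fixture()
def toy_counts():
    counts = pd.DataFrame(
        {"s1": [10, 20], "s2": [5, 40]},
        index=pd.Index(["f1", "f2"], name="feature_id"),
    )
    lengths = pd.Series([1000.0, 500.0], index=counts.index)
    return om.CountMatrix(counts, lengths)


def synthetic_domain_alignment(rng, n_clades=5, refs_per_clade=3, n_queries=7,
                               length=60, clade_divergence=18, query_mutations=2):
    """Clade-structured amino-acid alignment with queries derived from clades.

    Each clade descends from a common ancestor by ``clade_divergence`` fixed
    substitutions; references within a clade differ by a couple of private
    substitutions, and each query is a lightly mutated copy of a clade seed.
    Returns (alignment dict, reference->clade map, query->true clade map).
    """
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    ancestor = rng.choice(aa, size=length)
    aln, refs, truth = {}, {}, {}

    def mutate(seq, k):
        seq = seq.copy()
        pos = rng.choice(length, size=k, replace=False)
        for p in pos:
            choices = aa[aa != seq[p]]
            seq[p] = rng.choice(choices)
        return seq

    seeds = {}
    for c in range(n_clades):
        clade = f"ZF{c + 1}"
        seeds[clade] = mutate(ancestor, clade_divergence)
        for r in range(refs_per_clade):
            name = f"{clade}_ref{r + 1}"
            aln[name] = "".join(mutate(seeds[clade], 2))
            refs[name] = clade
    clades = [f"ZF{(i % n_clades) + 1}" for i in range(n_queries)]
    for i, clade in enumerate(clades):
        name = f"query{i + 1}"
        aln[name] = "".join(mutate(seeds[clade], query_mutations))
        truth[name] = clade
    return aln, refs, truth
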