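import numpy as np
import pandas as pd
import pytest

from tmeprofiler import ExpressionMatrix, SignatureCollection, SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Structured three-group cohort with planted immune/genomic/survival truth."""
    params = SimulationParams(n_adc=30, n_sqcc=30, n_genes=3000,
                              signature_size=15, delta=2.0, seed=11)
    return generate_cohort(params)


@pytest.fixture()
def small_expr():
    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        rng.lognormal(2.0, 1.0, size=(50, 5)),
        index=[f"G{i:03d}" for i in range(50)],
        columns=[f"S{j}" for j in range(5)],
    )
    return ExpressionMatrix(values=values)


@pytest.fixture()
def small_sets(small_expr):
    rng = np.random.default_rng(7)
    genes = list(small_expr.gene_ids)
    sigs, cats = {}, {}
    for i, cat in enumerate(["adaptive", "innate", "other"]):
        members = rng.choice(genes, size=8, replace=False)
        sigs[f"sig{i}"] = frozenset(members)
        cats[f"sig{i}"] = cat
    return SignatureCollection(signatures=sigs, category=cats)
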