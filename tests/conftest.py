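import warnings

import numpy as np
import pandas as pd
import pytest

import lupusmod as lm


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared across tests: metadata, modules,
    expression with the default planted effects."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = lm.CohortConfig(n_aa=40, n_ea=40, n_naa=20, n_hc=10, seed=11)
        metadata = lm.generate_metadata(cfg)
        modules = lm.default_modules()
        expr = lm.generate_expression(
            metadata, modules, lm.default_effect_table(), n_genes=900, seed=12
        )
    return metadata, modules, expr


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    metadata, modules, expr = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = lm.score_modules(expr, modules)
    return metadata, scores


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_modules(*gene_lists, names=None):
    from lupusmod.modules import GeneModule, ModuleCollection
    names = names or [f"M{i}" for i in range(len(gene_lists))]
    return ModuleCollection(
        [GeneModule(n, "", tuple(g)) for n, g in zip(names, gene_lists)]
    )
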