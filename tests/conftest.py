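"""Shared fixtures: small expression matrices and a session-scoped
planted-structure run used by the network and comparison tests."""

import numpy as np
import pandas as pd
import pytest

from conet import netbuild as nb
from conet.expr import ExpressionMatrix
from conet.pipeline import build_network
from conet.simulate import generate, recovery_spec


def make_expr(values, gene_ids=None, sample_ids=None, genotype="WT",
              tissue="cortex", age=4, unit="log-intensity"):
    """Wrap a 2-D array as an ExpressionMatrix with uniform metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {"genotype": genotype, "tissue": tissue, "age_months": age,
         "replicate_id": range(1, n_samples + 1)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        meta, unit=unit)


@pytest.fixture(scope="session")
def planted():
    """The planted-structure recovery scenario: five 100-gene modules, one
    KO module split, one hub shift, DE genes and seeded markers."""
    matrices, truth = generate(recovery_spec(seed=1))
    return matrices, truth


@pytest.fixture(scope="session")
def planted_networks(planted):
    """Both condition networks built with default settings."""
    matrices, truth = planted
    nets = {}
    for cond in ("WT", "KO"):
        corr = nb.correlation_matrix(matrices[cond])
        power, _ = nb.pick_soft_threshold(
            corr, n_samples=matrices[cond].n_samples)
        cfg = {"power": power, "min_module_size": 30, "deep_split": 2,
               "merge_height": 0.25, "tom": True, "corr_method": "bicor"}
        nets[cond] = build_network(matrices[cond], cfg, None, cond)
    return nets


@pytest.fixture(scope="session")
def noise_diss():
    """TOM dissimilarity of a pure-noise expression matrix (no modules)."""
    rng = np.random.default_rng(0)
    em = make_expr(rng.standard_normal((500, 60)))
    corr = nb.correlation_matrix(em)
    adj = nb.adjacency(corr, 6)
    tom = nb.tom_similarity(adj)
    return 1.0 - tom
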