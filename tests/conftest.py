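import numpy as np
import pandas as pd
import pytest

from mantlescreen.formats import ExpressionPanel, GeneModel, SampleMeta, assign_ranks


def make_genes(spec):
    """GeneModels from (gene_id, chrom, start, end, strand, biotype) tuples."""
    return assign_ranks(
        GeneModel(gene_id=g, chrom=c, start=s, end=e, strand=st, biotype=b)
        for g, c, s, e, st, b in spec
    )


def nb_panel(seed, n_genes=2000, mu_range=(10.0, 1000.0), dispersion=0.1,
             lib_sigma=0.2, group_lfc=0.0, n_affected=0, reps=3):
    """Two-group NB count panel; first n_affected genes get group_lfc."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mu_range[0]), np.log(mu_range[1]), n_genes))
    fa = np.ones(n_genes)
    fb = np.ones(n_genes)
    fa[:n_affected] = 2.0 ** (group_lfc / 2.0)
    fb[:n_affected] = 2.0 ** (-group_lfc / 2.0)
    lib = np.exp(rng.normal(0.0, lib_sigma, 2 * reps))
    cols = []
    for i, lf in enumerate(lib):
        m = mu * (fa if i < reps else fb) * lf
        cols.append(rng.negative_binomial(1.0 / dispersion, 1.0 / (1.0 + dispersion * m)))
    names = [f"a{i}" for i in range(reps)] + [f"b{i}" for i in range(reps)]
    df = pd.DataFrame(
        np.column_stack(cols),
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=names,
    )
    metas = [SampleMeta(sample_id=s) for s in names]
    return ExpressionPanel(df, metas), names[:reps], names[reps:]


@pytest.fixture(scope="session")
def small_sim():
    """One small but complete simulated dataset shared across tests."""
    from mantlescreen.synthio import SimConfig, simulate

    cfg = SimConfig(
        seed=42, n_chroms=2, genes_per_chrom=150, n_planted_modules=4,
        n_conserved_modules=3,
    )
    return simulate(cfg)
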