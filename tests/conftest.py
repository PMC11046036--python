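import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def tiny_resource():
    return pd.DataFrame(
        {
            "ligand": ["VIM", "A_B", "TGFB1"],
            "receptor": ["CD44", "C", "TGFBR1_TGFBR2"],
        }
    )


@pytest.fixture
def two_cluster_adata():
    """Two samples x two clusters with block-structured expression.

    Gene LIG is high in cluster c1, gene REC high in cluster c2, so the
    pair LIG^REC from c1 to c2 is the planted interaction.  Values are
    already on a normalized-log-like scale.
    """
    import anndata as ad

    rng = np.random.default_rng(7)
    n_per = 20
    genes = ["LIG", "REC", "OTH1", "OTH2"]
    blocks = []
    obs_rows = []
    for sample in ("S1", "S2"):
        for cluster, (lig_mu, rec_mu) in (("c1", (3.0, 0.2)), ("c2", (0.3, 2.5))):
            X = np.column_stack(
                [
                    rng.gamma(4, lig_mu / 4, n_per),
                    rng.gamma(4, rec_mu / 4, n_per),
                    rng.gamma(2, 0.5, n_per),
                    rng.gamma(2, 0.5, n_per),
                ]
            )
            blocks.append(X)
            obs_rows += [(sample, cluster)] * n_per
    X = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows, columns=["sample", "cell_type"])
    obs.index = [f"cell{i}" for i in range(len(obs))]
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


@pytest.fixture(scope="session")
def small_simulation():
    """One small simulated dataset with its LR network, reused read-only."""
    from cellcomm.synthetic import SimulationConfig, attach_lr_network, simulate_counts

    cfg = SimulationConfig(n_genes=400, n_cells=900, n_celltypes=6, n_samples=5, seed=11)
    return attach_lr_network(simulate_counts(cfg), net_seed=11, n_net_genes=60)
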