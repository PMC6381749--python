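import numpy as np
import pytest

import hetrank as hr


@pytest.fixture(scope="session")
def planted():
    """Default planted dataset: 4 matched clusters, 80 lncRNAs x 60 diseases."""
    return hr.generate_planted_dataset(hr.PlantedConfig(seed=7))


@pytest.fixture(scope="session")
def evidence_networks(planted):
    """The three lncRNA and three disease similarity networks of the planted data."""
    lnc_nets = [
        hr.pearson_similarity_network(planted.expression),
        hr.gip_kernel_matrix(planted.lnc_mirna),
        hr.gip_kernel_matrix(planted.lnc_protein),
    ]
    dis_terms = hr.NodeIndex.from_ids(planted.associations.disease_index.ids, "disease")
    dis_nets = [
        hr.ontology_similarity_matrix(planted.ontology, dis_terms),
        hr.gip_kernel_matrix(planted.dis_mirna),
        hr.gip_kernel_matrix(planted.dis_gene),
    ]
    return lnc_nets, dis_nets


@pytest.fixture(scope="session")
def fused_ts(planted, evidence_networks):
    lnc_nets, dis_nets = evidence_networks
    ul = planted.associations.lncRNA_index
    ud = planted.associations.disease_index
    return hr.topo_fuse(lnc_nets, ul), hr.topo_fuse(dis_nets, ud)


def random_hetero_instance(rng, n_l, n_d, assoc_density=0.1, zero_row_frac=0.1):
    """Random heterogeneous network with some all-zero similarity rows."""
    def sym(n):
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        kill = rng.random(n) < zero_row_frac
        a[kill, :] = 0
        a[:, kill] = 0
        return a

    A_L, A_D = sym(n_l), sym(n_d)
    A_LD = (rng.random((n_l, n_d)) < assoc_density).astype(float)
    li = hr.NodeIndex.from_ids((f"L{i}" for i in range(n_l)), "lncRNA")
    di = hr.NodeIndex.from_ids((f"D{i}" for i in range(n_d)), "disease")
    return hr.HeteroNetwork(li, di, A_L, A_D, A_LD)
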