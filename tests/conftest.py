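import numpy as np
import pandas as pd
import pytest

import toxomix as tx
from toxomix import diffabund as da
from toxomix import factors as fa


@pytest.fixture(scope="session")
def default_study():
    """Default desk-scale study; shared across tests (read-only)."""
    return tx.simulate_study(tx.SimConfig(seed=7))


@pytest.fixture(scope="session")
def prepped_layers(default_study):
    return [da.preprocess_layer(ly, default_study.sheet) for ly in default_study.layers]


@pytest.fixture(scope="session")
def mofa_results(default_study, prepped_layers):
    return fa.fit_mofa(prepped_layers, default_study.sheet, k_init=10, max_iter=300, seed=0)


@pytest.fixture(scope="session")
def default_contrasts(default_study, prepped_layers):
    out = []
    for ly in prepped_layers:
        for g in ("3R4F", "CHTP", "THS", "Cessation", "Switch"):
            for tp in (3, 4, 6):
                ct = da.fit_contrast(ly, default_study.sheet, g, tp)
                if ct.status == "ok":
                    out.append(ct)
    return out


@pytest.fixture(scope="session")
def default_network(default_study, prepped_layers):
    from toxomix import netbuild as nb
    from toxomix import syndata as sd

    inter = sd.simulate_interactions(default_study, seed=202)
    net = nb.assign_edge_weights(nb.filter_interactions(inter))
    node_map, unmapped = nb.harmonize_ids(prepped_layers, net)
    return net, node_map, unmapped


def make_contrast(logfc, s2=None, n1=5, n2=5, group="3R4F", timepoint=6, modality="mrna", index=None):
    """Small hand-built ContrastTable for unit tests."""
    logfc = np.asarray(logfc, dtype=float)
    if s2 is None:
        s2 = np.full_like(logfc, 0.1)
    idx = index if index is not None else [f"g{i}" for i in range(len(logfc))]
    se = np.sqrt(np.asarray(s2) * (1 / n1 + 1 / n2))
    t = logfc / se
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "df": float(n1 + n2 - 2),
            "t": t,
            "P.Value": 0.5,
            "adj.P.Val": 0.5,
            "significant": False,
        },
        index=pd.Index(idx, name="feature_id"),
    )
    return da.ContrastTable(table=table, group=group, timepoint=timepoint, modality=modality, n_treat=n1, n_sham=n2)
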