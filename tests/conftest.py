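import numpy as np
import pandas as pd
import pytest

import comboseq as cs


@pytest.fixture(scope="session")
def sim_config():
    return cs.SimulationConfig(
        n_genes=1200,
        cell_lines=("L1",),
        dispersion=0.1,
        seed=3,
        n_pathways=15,
        pathway_size=20,
        pathway_purity=1.0,
    )


@pytest.fixture(scope="session")
def sim_data(sim_config):
    cm, truth = cs.simulate_counts(sim_config)
    db = cs.emit_pathways(truth, sim_config)
    return cm, truth, db


@pytest.fixture(scope="session")
def de_results(sim_data):
    """DE results for the three contrasts the combination analysis needs."""
    cm, _, _ = sim_data
    sub = cm.subset(cell_line="L1")
    factors = cs.size_factors(sub)
    disp = cs.estimate_dispersion(sub, factors=factors)
    return {
        role: cs.wald_test(sub, (role, "control"), factors=factors,
                           dispersions=disp)
        for role in ("monoA", "monoB", "comboA", "comboB")
    }


def make_de_result(rows, contrast=("comboA", "control")):
    """Hand-build a DEResult from (gene, log2fc, p, padj) tuples."""
    t = pd.DataFrame(
        [
            {
                "base_mean": 100.0,
                "log2fc": lfc,
                "se": 0.3,
                "stat": lfc / 0.3,
                "p_value": p,
                "padj": padj,
                "status": "tested",
                "separated": False,
                "converged": True,
            }
            for _, lfc, p, padj in rows
        ],
        index=pd.Index([g for g, *_ in rows], name="gene_id"),
    )
    return cs.DEResult(contrast=contrast, table=t, cell_line="L1")
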