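import numpy as np
import pytest

from hypersyn.data_io import (Cohort, DiseaseEmbeddingTable, DrugRecord,
                              ExpressionMatrix, IndicationPair, SynergySample)


@pytest.fixture()
def toy_cohort() -> Cohort:
    """A tiny, fully consistent hand-built cohort (no dangling references)."""
    drugs = [DrugRecord("A", "CCO"), DrugRecord("B", "c1ccccc1"),
             DrugRecord("C", "CC(=O)O")]
    samples = [
        SynergySample("A", "B", "c1", 45.0),
        SynergySample("A", "C", "c1", 12.0),
        SynergySample("B", "C", "c2", 31.5),
        SynergySample("A", "B", "c2", -3.0),
    ]
    expr = ExpressionMatrix(["c1", "c2"], ["g1", "g2", "g3"],
                            np.array([[1.0, 3.0, 5.0], [3.0, 1.0, 5.0]]))
    pairs = [IndicationPair("A", "d1"), IndicationPair("B", "d2")]
    emb = DiseaseEmbeddingTable(["d1", "d2"],
                                np.array([[0.1, 0.2], [0.3, -0.4]]))
    return Cohort(samples, drugs, expr, pairs, emb)


@pytest.fixture(scope="session")
def small_synth_cohort():
    """A small generated cohort shared by pipeline tests (session-scoped:
    generation is deterministic and read-only)."""
    from hypersyn.synthetic import SynthConfig, generate_cohort
    cfg = SynthConfig(n_drugs=10, n_cell_lines=6, n_diseases=4, n_genes=20,
                      embedding_dim=8, n_samples=220, seed=11)
    return cfg, generate_cohort(cfg)
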