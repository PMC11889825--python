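import numpy as np
import pytest

from patientkg.expression_io import ExpressionDataset
from patientkg.kg_builder import KnowledgeGraph


@pytest.fixture
def tiny_dataset():
    """2 patients x 3 genes with labels, hand-set values."""
    return ExpressionDataset(
        dataset_id="toy",
        patient_ids=("p1", "p2"),
        gene_ids=("gA", "gB", "gC"),
        values=np.array([[1.0, 3.0, 2.0], [4.0, 0.0, 2.0]]),
        labels={"p1": "case", "p2": "control"},
    )


@pytest.fixture
def chain_graph():
    """Directed chain a -> b -> c -> d -> e over a single relation."""
    kg = KnowledgeGraph()
    for s, o in zip("abcd", "bcde"):
        kg.add(f":e/{s}", ":r", f":e/{o}")
    return kg


@pytest.fixture
def toy_train_graph():
    """Small multi-relation graph with enough entities for corruption."""
    kg = KnowledgeGraph()
    rng = np.random.default_rng(7)
    ents = [f":e/{i}" for i in range(8)]
    rels = [":r/0", ":r/1"]
    for _ in range(24):
        s, o = rng.choice(8, size=2, replace=False)
        kg.add(ents[s], rels[int(rng.integers(2))], ents[o])
    return kg
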