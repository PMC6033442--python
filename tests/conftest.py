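import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pasi.expression import CASE, CONTROL, ExpressionMatrix, ScaledMatrix
from pasi.kgml import Pathway, PathwayNode, Relation

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def labels_for(n_case: int, n_control: int) -> pd.Series:
    samples = [f"case_{i}" for i in range(n_case)] + [f"ctrl_{i}" for i in range(n_control)]
    return pd.Series([CASE] * n_case + [CONTROL] * n_control, index=samples)


def expression_from(array, n_case=2, n_control=2, genes=None) -> ExpressionMatrix:
    array = np.asarray(array, dtype=float)
    labels = labels_for(n_case, n_control)
    genes = genes if genes is not None else list(range(1, array.shape[0] + 1))
    values = pd.DataFrame(array, index=genes, columns=labels.index)
    return ExpressionMatrix(values, labels)


def scaled_from(array, n_case=2, n_control=2, genes=None) -> ScaledMatrix:
    array = np.asarray(array, dtype=float)
    labels = labels_for(n_case, n_control)
    genes = genes if genes is not None else list(range(1, array.shape[0] + 1))
    values = pd.DataFrame(array, index=genes, columns=labels.index)
    return ScaledMatrix(values, labels)


def gene_chain(member_lists, relation_pairs, signs=None, pathway_id="toy") -> Pathway:
    """Pathway of single/multi-gene nodes named A, B, C, ... with given edges."""
    names = [chr(ord("A") + i) for i in range(len(member_lists))]
    nodes = [
        PathwayNode(name, "gene", frozenset(members))
        for name, members in zip(names, member_lists)
    ]
    signs = signs or [1] * len(relation_pairs)
    rels = [Relation(a, b, s) for (a, b), s in zip(relation_pairs, signs)]
    return Pathway(pathway_id, pathway_id, nodes, rels)


@pytest.fixture
def toy_scaled() -> ScaledMatrix:
    """4 genes x 6 samples (3 case + 3 control), values in [0, 1]."""
    rng = np.random.default_rng(42)
    return scaled_from(rng.uniform(size=(4, 6)), n_case=3, n_control=3)
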