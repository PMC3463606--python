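import numpy as np
import pandas as pd
import pytest

from retnetdyn import ExpressionMatrix, TypedNetwork
from retnetdyn.network import GENE, MIRNA, TF


@pytest.fixture
def toy_net():
    """T1 -> {G1, M1}; M1 -> G1."""
    return TypedNetwork(
        {"T1": TF, "M1": MIRNA, "G1": GENE},
        [("T1", "G1"), ("T1", "M1"), ("M1", "G1")],
    )


@pytest.fixture
def chain_net():
    """a -> b -> c with a, b TFs and c a gene."""
    return TypedNetwork({"a": TF, "b": TF, "c": GENE}, [("a", "b"), ("b", "c")])


@pytest.fixture
def star_net():
    """One TF regulating three genes."""
    return TypedNetwork(
        {"T": TF, "g1": GENE, "g2": GENE, "g3": GENE},
        [("T", "g1"), ("T", "g2"), ("T", "g3")],
    )


def make_expr(values: dict, types: dict, timepoints=None) -> ExpressionMatrix:
    ids = list(values)
    mat = pd.DataFrame([values[i] for i in ids], index=ids)
    if timepoints is None:
        timepoints = [f"t{j}" for j in range(mat.shape[1])]
    mat.columns = timepoints
    return ExpressionMatrix(mat, pd.Series({i: types[i] for i in ids}))


@pytest.fixture
def make_expression():
    return make_expr


def random_typed_net(rng: np.random.Generator, n_nodes: int = 12, p: float = 0.25) -> TypedNetwork:
    """Random typed digraph: regulator sources only, no self-loops."""
    types = {}
    for i in range(n_nodes):
        r = rng.random()
        types[f"n{i:02d}"] = TF if r < 0.3 else (MIRNA if r < 0.55 else GENE)
    ids = sorted(types)
    regs = [v for v in ids if types[v] != GENE]
    arcs = [
        (s, t)
        for s in regs
        for t in ids
        if s != t and rng.random() < p
    ]
    return TypedNetwork(types, arcs)


@pytest.fixture
def make_random_net():
    return random_typed_net
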