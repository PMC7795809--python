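import numpy as np
import pandas as pd
import pytest

from cdei.expression import ExpressionMatrix, SampleDesign
from cdei.pathway import Pathway


@pytest.fixture
def chain_pathway():
    """A -> B -> C, both activating."""
    return Pathway(
        id="chain",
        name="chain",
        genes=("A", "B", "C"),
        edges=(("A", "B", 1), ("B", "C", 1)),
    )


@pytest.fixture
def fan_pathway():
    """A activates both B and C (n_down(A) = 2)."""
    return Pathway(
        id="fan",
        name="fan",
        genes=("A", "B", "C"),
        edges=(("A", "B", 1), ("A", "C", 1)),
    )


@pytest.fixture
def cycle_pathway():
    """A <-> B activation cycle; (I - B) is singular."""
    return Pathway(
        id="cycle",
        name="cycle",
        genes=("A", "B"),
        edges=(("A", "B", 1), ("B", "A", 1)),
    )


@pytest.fixture
def toy_matrix():
    """4 genes x 6 samples: 2 controls, 2 untreated, 2 treated (one drug)."""
    data = pd.DataFrame(
        {
            "c1": [4.0, 8.0, 2.0, 10.0],
            "c2": [4.0, 8.0, 2.0, 10.0],
            "u1": [16.0, 8.0, 2.0, 10.0],
            "u2": [16.0, 8.0, 2.0, 10.0],
            "t1": [4.0, 8.0, 2.0, 10.0],
            "t2": [4.0, 8.0, 2.0, 10.0],
        },
        index=pd.Index(["A", "B", "C", "D"], name="gene"),
    )
    return ExpressionMatrix(data)


@pytest.fixture
def toy_design():
    return SampleDesign(
        conditions={
            "c1": "control",
            "c2": "control",
            "u1": "untreated",
            "u2": "untreated",
            "t1": "treated",
            "t2": "treated",
        },
        drug_of={"t1": "ext1", "t2": "ext1"},
    )


def random_acyclic_pathway(rng: np.random.Generator, n_max: int = 12) -> Pathway:
    """Random DAG with random signs; edges run low -> high index."""
    n = int(rng.integers(2, n_max + 1))
    genes = tuple(f"g{i}" for i in range(n))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                edges.append((genes[i], genes[j], int(rng.choice([-1, 1]))))
    return Pathway(id="rand", name="rand", genes=genes, edges=tuple(edges))
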