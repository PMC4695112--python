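import numpy as np
import pandas as pd
import pytest

from pasqc.expression import ExpressionMatrix, SampleTable
from pasqc.pathway_db import GeneRole, Pathway, PathwayDB


@pytest.fixture
def tiny_db() -> PathwayDB:
    """Two small pathways with mixed activator/repressor roles."""
    return PathwayDB(
        [
            Pathway("P1", [GeneRole("G1", 1.0), GeneRole("G2", -1.0)]),
            Pathway("P2", [GeneRole("G3", 0.5), GeneRole("G4", -0.5)]),
        ]
    )


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """Four genes × four lines; CTRL1/CTRL2 serve as controls."""
    data = pd.DataFrame(
        {
            "CTRL1": [10.0, 10.0, 10.0, 10.0],
            "CTRL2": [10.0, 10.0, 10.0, 10.0],
            "CASE1": [20.0, 10.0, 10.0, 10.0],
            "CASE2": [10.0, 5.0, 40.0, 10.0],
        },
        index=["G1", "G2", "G3", "G4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_samples() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["CTRL1", "CTRL2", "CASE1", "CASE2"],
                "line_id": ["CTRL1", "CTRL2", "CASE1", "CASE2"],
                "group": ["FIB", "FIB", "iPSC", "iPSC"],
            }
        )
    )


def random_db(rng: np.random.Generator, n_pathways: int = 4, max_genes: int = 8) -> PathwayDB:
    """A random valid pathway DB for round-trip and oracle tests."""
    from pasqc.pathway_db import ALLOWED_ARR

    pathways = []
    counter = 0
    for i in range(n_pathways):
        size = int(rng.integers(1, max_genes + 1))
        members = []
        for _ in range(size):
            counter += 1
            arr = float(rng.choice(ALLOWED_ARR))
            members.append(GeneRole(f"g{counter}", arr))
        pathways.append(Pathway(f"pw{i}", members))
    return PathwayDB(pathways)


def random_matrix(
    rng: np.random.Generator, genes, n_samples: int = 4, prefix: str = "S"
) -> ExpressionMatrix:
    values = np.power(10.0, rng.normal(2.0, 0.5, size=(len(genes), n_samples)))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=list(genes),
            columns=[f"{prefix}{j}" for j in range(n_samples)],
        )
    )
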