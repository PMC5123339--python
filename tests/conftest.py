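import numpy as np
import pandas as pd
import pytest

from pathcrosstalk import ExpressionMatrix, GeneSetCollection
from pathcrosstalk.synthetic_data import Regulator, SyntheticDesign


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 features x 4 samples, 2 case + 2 control."""
    values = pd.DataFrame(
        [[10.0, 20.0, 5.0, 8.0], [1.0, 2.0, 3.0, 4.0], [100.0, 90.0, 110.0, 95.0]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    labels = pd.Series(
        ["case", "case", "control", "control"], index=values.columns, name="label"
    )
    return ExpressionMatrix(values, labels)


@pytest.fixture
def tiny_collection() -> GeneSetCollection:
    return GeneSetCollection(
        {
            "P1": ("first", ("G1", "G2", "G3")),
            "P2": ("second", ("G3", "G4", "G5")),
            "P3": ("third", ("G6", "G7")),
        }
    )


def small_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """A reduced cohort for fast end-to-end unit tests: 200 genes, 20 miRNAs,
    30+30 samples, 10 pathways, one planted pair, one decoy, one regulator."""
    fields = dict(
        n_genes=200,
        n_mirnas=20,
        n_case=30,
        n_control=30,
        n_pathways=10,
        pathway_size_range=(10, 14),
        overlap_fraction=0.1,
        crosstalk_pairs=[("PW01", "PW03", 1.2)],
        decoy_pathways=("PW05",),
        regulators=[Regulator(0, ("PW01", "PW03"), 0.8, 4)],
        seed=seed,
    )
    fields.update(overrides)
    return SyntheticDesign(**fields)


@pytest.fixture
def small_cohort():
    from pathcrosstalk.synthetic_data import simulate

    return simulate(small_design(seed=11))
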