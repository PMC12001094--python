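import numpy as np
import pandas as pd
import pytest

from pathdose import (
    GeneSetSim,
    SimulationSpec,
    simulate_dataset,
    transform_dataset,
)


@pytest.fixture(scope="session")
def small_doses():
    """Six half-log-spaced doses, enough for spline fits at desk scale."""
    return tuple(np.round(10.0 ** np.linspace(-2.5, 1.0, 6), 6))


@pytest.fixture(scope="session")
def linear_pathway(small_doses):
    """A linear-response pathway plus a flat one, transformed for modeling."""
    spec = SimulationSpec(
        genesets=(
            GeneSetSim("lin", 12, "linear", 2.0),
            GeneSetSim("flat", 12, "flat", 0.0),
        ),
        doses=small_doses,
        seed=101,
    )
    dataset, sets, truth = simulate_dataset(spec)
    transformed = transform_dataset(dataset, use_log10=True)
    return transformed, sets, truth


@pytest.fixture
def toy_matrix_file(tmp_path):
    path = tmp_path / "matrix.tsv"
    df = pd.DataFrame(
        [[10, 20, 30, 40], [1, 2, 3, 4], [5, 5, 5, 5]],
        index=["geneA", "geneB", "geneC"],
        columns=["S1", "S2", "S3", "S4"],
    )
    df.to_csv(path, sep="\t")
    return path


@pytest.fixture
def toy_metadata_file(tmp_path):
    path = tmp_path / "meta.tsv"
    pd.DataFrame(
        {"sample": ["S1", "S2", "S3", "S4"], "dose": [0.0, 0.1, 1.0, 10.0]}
    ).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def toy_gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "setA\tfirst set\tgeneA\tgeneB\n"
        "setB\tsecond set\tgeneB\tgeneC\tgeneC\n",
        encoding="utf-8",
    )
    return path
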