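import numpy as np
import pandas as pd
import pytest

from ciliascreen.expression_io import ExpressionMatrix, IsoformTable, StageAxis


@pytest.fixture
def stage_axis() -> StageAxis:
    return StageAxis()


@pytest.fixture
def small_isoform_table(stage_axis) -> IsoformTable:
    """3 genes, mixed isoform counts, hand-set values."""
    rows = {
        "g1.1": ("g1", [1, 2, 3, 4, 5, 6, 7]),
        "g2.1": ("g2", [10, 20, 30, 40, 50, 60, 70]),
        "g2.2": ("g2", [30, 40, 50, 60, 70, 80, 90]),
        "g3.1": ("g3", [5, 5, 5, 5, 5, 5, 5]),
        "g3.2": ("g3", [1, 1, 1, 1, 1, 1, 1]),
        "g3.3": ("g3", [3, 3, 3, 3, 3, 3, 3]),
    }
    data = pd.DataFrame(
        {
            "gene_id": [g for g, _ in rows.values()],
            **{
                stage: [vals[i] for _, vals in rows.values()]
                for i, stage in enumerate(stage_axis.labels)
            },
        },
        index=pd.Index(rows.keys(), name="isoform_id"),
        dtype=object,
    )
    for stage in stage_axis.labels:
        data[stage] = data[stage].astype(float)
    return IsoformTable(data, stage_axis)


def make_matrix(profiles: dict[str, list[float]], stage_axis=None) -> ExpressionMatrix:
    stage_axis = stage_axis or StageAxis()
    data = pd.DataFrame.from_dict(
        profiles, orient="index", columns=list(stage_axis.labels), dtype=float
    )
    data.index.name = "gene_id"
    return ExpressionMatrix(data, stage_axis)


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    """20 genes with seeded lognormal-ish positive profiles."""
    rng = np.random.default_rng(42)
    profiles = {
        f"g{i:02d}": (10 * rng.lognormal(0, 1, size=7)).tolist() for i in range(20)
    }
    return make_matrix(profiles)
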