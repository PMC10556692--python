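import numpy as np
import pytest

from seroprofiler.array_io import IntensityMatrix, SampleManifest


@pytest.fixture
def toy_manifest() -> SampleManifest:
    """4 cases + 4 controls, the smallest cohort the statistics accept."""
    cases = [f"C{i}" for i in range(1, 5)]
    controls = [f"N{i}" for i in range(1, 5)]
    return SampleManifest(
        sample_ids=cases + controls,
        groups={**{s: "case" for s in cases}, **{s: "control" for s in controls}},
    )


@pytest.fixture
def toy_matrix(toy_manifest) -> IntensityMatrix:
    """Two hand-analysable proteins: cases [4,4,1,1] / [4,4,2,2], controls all 1."""
    values = np.array(
        [
            [4.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            [4.0, 4.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0],
        ]
    )
    return IntensityMatrix(
        proteins=["toy8", "toy8c"],
        samples=toy_manifest.sample_ids,
        values=values,
        stage="normalized",
    )


@pytest.fixture
def toy_spots() -> list:
    """A tiny quadruplicate spot set: 2 proteins + 1 control on 2 slides."""
    from seroprofiler.array_io import SpotRecord

    spots = []
    for slide in ("S01", "S02"):
        for protein, base in (("NUBP2", 500.0), ("TK1", 300.0)):
            for rep, jitter in zip(range(1, 5), (0.9, 1.0, 1.1, 1.05)):
                spots.append(
                    SpotRecord(slide, protein, rep, base * jitter, 80.0)
                )
        for rep in range(1, 5):
            spots.append(
                SpotRecord(slide, "CTRL_IgG", rep, 40000.0, 90.0, True, "IgG")
            )
    return spots
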