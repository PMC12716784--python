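import pandas as pd
import pytest

from stinkgland.design import GLAND_TISSUES, SampleDesign


@pytest.fixture
def design():
    return SampleDesign.canonical()


@pytest.fixture
def small_catalog():
    """Three genes; one with two isoforms, one with a length tie."""
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g2", "g3", "g3"],
            "transcript_id": ["g1.t1", "g1.t2", "g2.t1", "g3.tA", "g3.tB"],
            "length_bp": [500, 800, 1200, 600, 600],
            "annotation_version": ["v1"] * 5,
        }
    )


@pytest.fixture
def fc_columns():
    return list(GLAND_TISSUES)


def make_fc(rows: dict[str, list[float]]) -> pd.DataFrame:
    """Fold-change table from transcript -> four gland log2FC values."""
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(GLAND_TISSUES)
    ).rename_axis("transcript_id")
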