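import pandas as pd
import pytest

from cellpath import bundled_driver_panel, bundled_wnt_panel
from cellpath.pathway_model import build_model, read_panel_tsv
from cellpath import variant_panel


@pytest.fixture(scope="session")
def wnt_model():
    return read_panel_tsv(bundled_wnt_panel())


@pytest.fixture(scope="session")
def driver_panel():
    return variant_panel.load_panel(bundled_driver_panel())


@pytest.fixture
def toy_model():
    return build_model(["A", "B", "C"])


@pytest.fixture
def toy_expression_tsv(tmp_path):
    """3-gene x 2-sample log2 expression TSV."""
    path = tmp_path / "expr.tsv"
    df = pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
        index=["g1", "g2", "g3"],
    )
    df.to_csv(path, sep="\t", index_label="gene")
    return path
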