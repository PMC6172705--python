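import networkx as nx
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def path4() -> nx.Graph:
    """Path graph A-B-C-D."""
    g = nx.Graph()
    nx.add_path(g, ["A", "B", "C", "D"])
    return g


@pytest.fixture
def triangle_plus_edge() -> nx.Graph:
    """Triangle A-B-C with a pendant edge C-D."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
    return g


def make_score_table(pmap: dict[str, float]) -> pd.DataFrame:
    """Score table with dummy coordinates for a gene→p mapping."""
    rows = [
        (g, "1", i * 1_000_000 + 1, i * 1_000_000 + 10_000, p)
        for i, (g, p) in enumerate(sorted(pmap.items()))
    ]
    return (
        pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "p"])
        .set_index("gene")
        .astype({"start": float, "end": float})
    )


@pytest.fixture
def score_table():
    return make_score_table
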