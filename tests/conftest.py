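import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def path_graph():
    """A 4-node path a-b-c-d."""
    g = nx.Graph()
    nx.add_path(g, ["a", "b", "c", "d"])
    return g


@pytest.fixture
def write_table(tmp_path):
    """Write association rows to a TSV and return the path."""

    def _write(rows, header="subject\tobject\tsources", name="table.tsv"):
        path = tmp_path / name
        body = "\n".join(rows)
        path.write_text(header + "\n" + body + ("\n" if body else ""), encoding="utf-8")
        return path

    return _write
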