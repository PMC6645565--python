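import pandas as pd
import pytest

from deconcord import DECallSet, DETable, SynthConfig, call_de, generate_contrasts


@pytest.fixture
def small_table() -> DETable:
    return DETable(
        "toy",
        pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d", "e"],
                "log2fc": [0.8, -0.9, 0.1, -0.5, 1.2],
                "pvalue": [0.001, 0.002, 0.5, 0.004, 0.003],
                "padj": [0.01, 0.02, 0.8, 0.04, 0.03],
            }
        ),
    )


def make_calls(name, universe, up=(), down=()):
    return DECallSet(
        contrast_name=name,
        universe=frozenset(universe),
        up=frozenset(up),
        down=frozenset(down),
    )


@pytest.fixture
def three_calls():
    universe = {f"g{i}" for i in range(20)}
    return [
        make_calls("A", universe, up={"g0", "g1", "g2"}, down={"g10", "g11"}),
        make_calls("B", universe, up={"g1", "g2", "g3"}, down={"g10", "g12"}),
        make_calls("C", universe, up={"g2", "g3", "g4"}, down={"g10", "g13"}),
    ]


@pytest.fixture(scope="session")
def default_synth_run():
    """One end-to-end run of the default simulation, shared across tests."""
    config = SynthConfig()
    tables, truth = generate_contrasts(config)
    calls = [call_de(t) for t in tables]
    return config, tables, truth, calls
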