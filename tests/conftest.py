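import networkx as nx
import numpy as np
import pandas as pd
import pytest

from xgage.preprocess import ExpressionDataset


@pytest.fixture
def diamond_dag() -> nx.DiGraph:
    """root <- b, root <- c, b <- d, c <- d (edges child -> parent)."""
    dag = nx.DiGraph()
    for t in ("root", "b", "c", "d"):
        dag.add_node(t, name=t, namespace="biological_process")
    dag.add_edge("b", "root")
    dag.add_edge("c", "root")
    dag.add_edge("d", "b")
    dag.add_edge("d", "c")
    return dag


def make_dataset(
    n_probes: int = 20,
    treatments: tuple[str, ...] = ("C", "E"),
    n_rep: int = 3,
    seed: int = 0,
    paired: bool = False,
) -> ExpressionDataset:
    rng = np.random.default_rng(seed)
    samples = [f"{t}{r + 1}" for t in treatments for r in range(n_rep)]
    design = pd.DataFrame(
        {
            "treatment": [t for t in treatments for _ in range(n_rep)],
            "pair": [str(r + 1) if paired else "" for _ in treatments for r in range(n_rep)],
        },
        index=pd.Index(samples, name="sample"),
    )
    signals = pd.DataFrame(
        2.0 ** rng.normal(8, 1.5, size=(n_probes, len(samples))),
        index=pd.Index([f"p{i:03d}" for i in range(n_probes)], name="probe"),
        columns=samples,
    )
    spots = pd.DataFrame(
        2.0 ** rng.normal(4, 0.5, size=(30, len(samples))),
        index=pd.Index([f"ctrl{i}" for i in range(30)], name="spot"),
        columns=samples,
    )
    return ExpressionDataset(signals=signals, design=design, control_spots=spots)


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    return make_dataset()
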