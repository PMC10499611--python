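import numpy as np
import pandas as pd
import pytest

from mosaicscreen.simulate import (
    ScreenConfig,
    make_guide_library,
    simulate_cells,
    simulate_reads,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_meta(
    n=300,
    n_libs=3,
    labels=("g1", "g2", "control"),
    types=("RGC", "IPC", "L2/3"),
    seed=0,
):
    """Small hand-rolled metadata table for unit tests."""
    r = np.random.default_rng(seed)
    traj = {"RGC": "dorsal", "IPC": "dorsal", "L2/3": "dorsal",
            "v-RGC": "ventral", "INP": "ventral", "astrocyte": "none",
            "OPC": "none"}
    ctypes = r.choice(types, n)
    return pd.DataFrame({
        "cell_id": [f"c{i:04d}" for i in range(n)],
        "library_id": r.choice([f"lib{j}" for j in range(n_libs)], n),
        "batch_id": "b1",
        "induced": True,
        "cell_type": ctypes,
        "trajectory": [traj[t] for t in ctypes],
        "grna_label": r.choice(labels, n),
    })


@pytest.fixture(scope="session")
def mini_screen():
    """One small simulated screen shared by read-cascade tests."""
    config = ScreenConfig(
        seed=77, n_libraries=2, cells_per_library=400, n_grnas=8,
        control_fraction=0.05, doublet_fraction=0.05,
    )
    meta, truth = simulate_cells(config)
    library = make_guide_library(config, np.random.default_rng(99))
    reads = simulate_reads(meta, truth, config, library)
    return {"config": config, "meta": meta, "truth": truth,
            "library": library, "reads": reads}
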