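import numpy as np
import pandas as pd
import pytest

from dualtrace import atlas as atlas_mod
from dualtrace.fixtures import (
    PhantomSpec,
    make_punctate_stack,
    make_soma_process_stack,
    make_toy_atlas_plate,
    toy_grid_layout,
    toy_ontology,
)
from dualtrace.model import RegionCountTable


@pytest.fixture(scope="session")
def ontology():
    return toy_ontology()


@pytest.fixture(scope="session")
def unit_grid():
    """2x2 grid of unit squares A, B, C, D plus its ontology subtree."""
    return make_toy_atlas_plate(toy_grid_layout(side_um=1.0))


@pytest.fixture(scope="session")
def mm_grid():
    """2x2 grid of 1 mm (1000 µm) squares: each region area is 1 mm²."""
    return make_toy_atlas_plate(toy_grid_layout(side_um=1000.0))


@pytest.fixture(scope="session")
def punctate_phantom():
    spec = PhantomSpec(n_cells=20, snr=10.0, seed=1)
    return spec, *make_punctate_stack(spec)


@pytest.fixture(scope="session")
def soma_phantom():
    spec = PhantomSpec(n_cells=15, snr=10.0, seed=3)
    return spec, *make_soma_process_stack(spec)


@pytest.fixture()
def identity_tps():
    src = np.array([[0.0, 0.0], [2000.0, 0.0], [0.0, 2000.0], [2000.0, 2000.0]])
    return atlas_mod.fit_tps(src, src)


def make_table(densities: dict[str, list[float]], group: str = "CT",
               channel: str = "ch1", volume: float = 1.0) -> RegionCountTable:
    """Small helper: build a table from per-region density vectors."""
    rows = []
    n = len(next(iter(densities.values())))
    for region, values in densities.items():
        assert len(values) == n
        for m, v in enumerate(values):
            rows.append(
                {
                    "mouse_id": f"{group}_{m + 1}",
                    "group": group,
                    "region": region,
                    "channel": channel,
                    "count": v * volume,
                    "volume_mm3": volume,
                    "density": v,
                }
            )
    return RegionCountTable(pd.DataFrame(rows))


@pytest.fixture()
def five_mouse_table():
    """A printed 5-mouse toy table used as a correlation oracle fixture."""
    return make_table(
        {
            "ACA": [12.0, 15.5, 9.0, 20.0, 17.5],
            "AI": [30.0, 28.0, 26.5, 41.0, 33.0],
            "dDG": [5.0, 7.2, 4.1, 9.9, 6.3],
        }
    )
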