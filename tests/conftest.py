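import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from karst_gep.geodata import RasterGrid
from karst_gep.synthetic import SyntheticSpec, generate_area


def make_grid(values, cell_area=1.0, nodata=None, crs_tag="t"):
    return RasterGrid(np.asarray(values, dtype=float), cell_area=cell_area,
                      nodata=nodata, crs_tag=crs_tag)


@pytest.fixture(scope="session")
def spec42() -> SyntheticSpec:
    return SyntheticSpec(seed=42)


@pytest.fixture(scope="session")
def bundles42(spec42, tmp_path_factory):
    """The three synthetic area bundles for seed 42, written once per session."""
    root = tmp_path_factory.mktemp("bundles42")
    for i in range(spec42.n_areas):
        generate_area(spec42, i, root / f"area_{i}")
    return root


@pytest.fixture(scope="session")
def results42(bundles42):
    from karst_gep.pipeline import run_pipeline

    return run_pipeline(bundles42)
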