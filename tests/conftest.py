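"""Shared fixtures: one rendered desk-scale study reused across tests.

The default scenario render plus the full quantification pass is the most
expensive artefact; it is produced once per session and shared by the
architecture, growth, gap and acceptance tests.
"""

import numpy as np
import pytest

import porebiofilm as pb


@pytest.fixture(scope="session")
def desk_geometry():
    return pb.desk_geometry()


@pytest.fixture(scope="session")
def desk_study(desk_geometry):
    """Rendered default scenario + segmentation + full quantification."""
    scenario = pb.desk_scenario(seed=11)
    stack, truth = pb.simulate_timelapse(desk_geometry, scenario)
    image_stack = pb.ImageStack(stack, scenario.times_h.astype(float),
                                desk_geometry.pixel_size_um)
    masks = pb.binarize(pb.background_subtract(image_stack), desk_geometry)
    result = pb.quantify_stack(masks, desk_geometry)
    return {
        "geometry": desk_geometry,
        "scenario": scenario,
        "stack": stack,
        "truth": truth,
        "masks": masks,
        "result": result,
    }


@pytest.fixture()
def toy_otu_table():
    import pandas as pd

    return pd.DataFrame(
        {"A": [50, 50, 0], "B": [25, 25, 50]},
        index=["otu1", "otu2", "otu3"],
    )


@pytest.fixture()
def bare_geometry():
    """Grain-free 0.3 mm domain at 1 µm/px for constructed-mask tests."""
    return pb.DeviceGeometry(0.3, 0.3, 1.0, ())


def annulus_mask(shape, center, r_in_px, r_out_px):
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    d = np.hypot(rows - center[0], cols - center[1])
    return (d > r_in_px) & (d <= r_out_px)
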