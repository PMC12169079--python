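import numpy as np
import pandas as pd
import pytest

from clonescape import synthetic, zonation


@pytest.fixture(scope="session")
def small_tissue():
    """A small deterministic tissue geometry (1.5 x 1.5 mm at 2 um/px)."""
    params = synthetic.TissueSimParams(
        width_um=1500, height_um=1500, pixel_size_um=2.0,
        n_portal_tracts=2, portal_radius_um=110.0,
        sinusoid_fraction=0.10, seed=7,
    )
    masks, manifest = synthetic.generate_tissue(params)
    return params, masks, manifest


@pytest.fixture(scope="session")
def small_zone_map(small_tissue):
    _, masks, _ = small_tissue
    return zonation.build_zone_map(masks, band_width_um=50.0)


@pytest.fixture(scope="session")
def small_cells(small_zone_map):
    params = synthetic.CellSimParams(
        base_density_per_mm2={"CD8_T": 800.0, "hepatocyte": 1200.0},
        clone_freq_in_cd8={"clone1": 0.2},
        pi_enrichment_factor=1.0,
        marker_positive_prob={"GranzymeB": {"clone+": 0.22, "CD8_T": 0.13}},
        seed=7,
    )
    cells, manifest = synthetic.generate_cells(small_zone_map, params)
    return params, cells, manifest


def flat_zone_map(side_px=200, pixel_size_um=10.0):
    """All-tissue zone map with a single lobule zone (no portal tracts)."""
    labels = np.full((side_px, side_px), int(zonation.Zone.LOBULE_EXTRASINUSOIDAL),
                     dtype=np.uint8)
    return zonation.ZoneMap(labels=labels, pixel_size_um=pixel_size_um,
                            band_width_um=50.0)


def simple_cells_df(n, cell_type="CD8_T", extent_um=1000.0, seed=0, **extra):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "cell_id": [f"c{i:06d}" for i in range(n)],
        "x_um": rng.uniform(0, extent_um, n),
        "y_um": rng.uniform(0, extent_um, n),
        "cell_type": cell_type,
    })
    for k, v in extra.items():
        df[k] = v
    return df
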