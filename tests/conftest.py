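import numpy as np
import pytest

from damagemap.segmentation import build_cell_table, threshold_channel
from damagemap.synthetic_data import SynthSpec, generate_region
from damagemap.volume_io import ChannelName


#: desk-scale region parameters used across tests: large enough to place
#: 40 nuclei with radii 4-7 voxels without overlap, small enough to be fast
SMALL_REGION_KW = dict(
    shape=(32, 128, 128), n_nuclei=40, frac_gh2ax_pos=0.4, n_cd8=5, radius_range=(4.0, 7.0)
)


@pytest.fixture(scope="session")
def small_region():
    """One seeded synthetic region: (channels, labels, truth)."""
    return generate_region(SynthSpec(rng_seed=7, **SMALL_REGION_KW))


@pytest.fixture(scope="session")
def segmented_region(small_region):
    """The small region plus its thresholds and cell table."""
    channels, labels, truth = small_region
    gh = threshold_channel(channels[ChannelName.GH2AX])
    cd8 = threshold_channel(channels[ChannelName.CD8])
    table = build_cell_table(labels, gh, cd8)
    return dict(channels=channels, labels=labels, truth=truth,
                gh_mask=gh, cd8_mask=cd8, table=table)


def random_cell_table(n=100, seed=0, frac_gh2ax=0.5, frac_cd8=0.2, shape=(30, 120, 120)):
    """Random cell centroids with marker flags, for neighborhood oracles."""
    import pandas as pd

    from damagemap.volume_io import CellTable, Condition

    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "centroid_z": rng.uniform(0, shape[0], n),
            "centroid_y": rng.uniform(0, shape[1], n),
            "centroid_x": rng.uniform(0, shape[2], n),
            "gh2ax_pos": rng.random(n) < frac_gh2ax,
            "cd8_pos": rng.random(n) < frac_cd8,
        }
    )
    return CellTable(df, Condition.UNKNOWN, f"random_{seed}")
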