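import numpy as np
import pandas as pd
import pytest

import slrmig as sm
from slrmig.models import MigrationModel


class StipulatedModel(MigrationModel):
    """Model returning hand-chosen weights per (origin, dest) pair; for toys."""

    kind = "stipulated"

    def __init__(self, weights: dict[tuple[str, str], float]):
        self.weights = weights

    def predict_weights(self, feats: pd.DataFrame) -> np.ndarray:
        return np.array(
            [self.weights.get((o, d), 0.0) for o, d in zip(feats["origin"], feats["dest"])]
        )


@pytest.fixture
def stipulated_model_cls():
    return StipulatedModel


def make_line_toy() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three zones on a line: A (pop 100, 0 km), B (50, 100 km), C (50, 200 km).

    Returns (zones, planar distance matrix).
    """
    zones = sm.validate_zone_table(
        pd.DataFrame(
            {
                "zone_id": ["A", "B", "C"],
                "county_id": ["A", "B", "C"],
                "lat": [0.0, 0.0, 0.0],
                "lon": [0.0, 1.0, 2.0],
                "population": [100.0, 50.0, 50.0],
                "coastal": [True, True, False],
            }
        )
    )
    pos = {"A": 0.0, "B": 100.0, "C": 200.0}
    ids = list(pos)
    dist = pd.DataFrame(
        [[abs(pos[a] - pos[b]) for b in ids] for a in ids], index=ids, columns=ids
    )
    return zones, dist


@pytest.fixture
def line_toy():
    return make_line_toy()


@pytest.fixture
def two_county_toy():
    """Two counties: county c1 partly flooded (theta_A=200, theta_U=800), c2 unflooded (1000)."""
    zones = sm.validate_zone_table(
        pd.DataFrame(
            {
                "zone_id": ["z1", "z2"],
                "county_id": ["c1", "c2"],
                "lat": [29.0, 30.0],
                "lon": [-90.0, -90.0],
                "population": [1000.0, 1000.0],
                "coastal": [True, False],
            }
        )
    )
    exposure = sm.validate_exposure_table(
        pd.DataFrame(
            {
                "subzone_id": ["z1_s0"],
                "zone_id": ["z1"],
                "slr_m": [0.3],
                "population": [1000.0],
                "affected_population": [200.0],
            }
        )
    )
    # a migrant forced out of z1's flooded part: 70% stay within the county
    model_climate = StipulatedModel({("z1", "z1"): 0.7, ("z1", "z2"): 0.3})
    return zones, exposure, model_climate


@pytest.fixture(scope="session")
def small_region():
    """40-zone synthetic coastal region (fast fixture for pipeline tests)."""
    spec = sm.SyntheticSpec(n_zones=40, seed=7)
    zones, exposure = sm.generate_region(spec)
    return zones, exposure


@pytest.fixture(scope="session")
def region200():
    """The 200-zone study region used by the conservation and recovery checks."""
    spec = sm.SyntheticSpec(n_zones=200, seed=11)
    zones, exposure = sm.generate_region(spec)
    return zones, exposure


@pytest.fixture(scope="session")
def region200_features(region200):
    from slrmig.synth import region_features

    zones, _ = region200
    return region_features(zones)


@pytest.fixture(scope="session")
def fitted_neural(region200, region200_features):
    """Neural model fit on flows sampled from extended radiation (alpha=0.5)."""
    zones, _ = region200
    gen = sm.ExtendedRadiationModel(alpha=0.5)
    flows = sm.generate_flows(zones, gen, 0.03, 2004, 123, feats=region200_features)
    model = sm.NeuralMigrationModel(epochs=800, seed=5).fit(region200_features, flows)
    return model, gen, flows
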