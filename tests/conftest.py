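import logging

import numpy as np
import pandas as pd
import pytest

from engineerweb import FoodWebSpec, RunConfig, generate_study
from engineerweb.synthetic import HabitatProfile

logging.getLogger("engineerweb").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced study: fewer species and lengths, fast to analyse."""
    return FoodWebSpec(
        habitats={
            "Haploops": HabitatProfile(n_prey=21, n_predators=8, n_hauls=6,
                                       biomass_factor=8.0,
                                       modal_length_cm=7.0),
            "Sternaspis": HabitatProfile(n_prey=20, n_predators=6,
                                         n_hauls=3, biomass_factor=1.5,
                                         modal_length_cm=9.0),
            "Amphiura_Owenia": HabitatProfile(n_prey=20, n_predators=7,
                                              n_hauls=3,
                                              modal_length_cm=9.0),
        },
        lengths_per_species=10,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    return generate_study(small_spec, RunConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def community_long_df():
    """Two hauls x three species per habitat, three habitats, one bay."""
    rows = []
    rng = np.random.default_rng(5)
    for hab in ("Haploops", "Sternaspis", "Amphiura_Owenia"):
        for haul in range(3):
            for sp in ("sp_a", "sp_b", "sp_c"):
                rows.append(dict(bay="BayA", habitat=hab,
                                 haul=f"{hab}_h{haul}", species=sp,
                                 biomass_kg_km2=float(rng.uniform(0, 10)),
                                 density_n_km2=float(rng.uniform(0, 500))))
    return pd.DataFrame(rows)
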