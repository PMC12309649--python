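import numpy as np
import pytest

from aoh_gapscan.frames import raster_frame
from aoh_gapscan.overlap_engine import SpeciesMap
from aoh_gapscan.synthetic_data import RawSite, ScenarioConfig, generate_scenario


def make_map(cells, shape=(10, 10), cell_km=1.0, map_id="m1", species_id="sp1",
             season="resident"):
    """SpeciesMap from a list of (row, col) suitable cells on a small grid."""
    rows = np.array([r for r, _ in cells], dtype=np.int32)
    cols = np.array([c for _, c in cells], dtype=np.int32)
    return SpeciesMap(map_id=map_id, species_id=species_id, season=season,
                      rows=rows, cols=cols, shape=shape, cell_km=cell_km,
                      frame=raster_frame(shape[0], cell_km))


def make_site(site_id, geometry, **kw):
    return RawSite(site_id=site_id, name=kw.get("name", site_id),
                   country=kw.get("country", "Aldera"), region=kw.get("region", "North"),
                   iba_flag=kw.get("iba_flag", False), geometry=geometry)


@pytest.fixture(scope="session")
def small_scenario():
    """One modest scenario shared by read-only tests."""
    cfg = ScenarioConfig(rows=120, cols=120, n_species=120, n_sites=40,
                         n_invalid_sites=3, n_missing_boundary=2, seed=21)
    return generate_scenario(cfg)
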