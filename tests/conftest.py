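import numpy as np
import pandas as pd
import pytest

from forestflow.data_model import AnnualRecord, CatchmentMeta
from forestflow.hierarchical import RandomStructure
from forestflow.synthetic import GeneratorConfig, default_random_structure


def make_meta(cid="A", **kw):
    defaults = dict(
        catchment_id=cid, country="XX", area_km2=10.0, map_mm=1000.0,
        mean_pet_mm=900.0, fc_s=50.0, historical_forest="absent",
        prior_land_use="agriculture", prior_land_cover="grassland",
        forest_type="coniferous", establishment="planted", design="paired",
    )
    defaults.update(kw)
    return CatchmentMeta(**defaults)


def make_record(cid="A", year=1990, age=1.0, q_f=400.0, q_c=500.0,
                p=1000.0, pet=900.0, cover=50.0, **kw):
    return AnnualRecord(
        catchment_id=cid, hydro_year=year, age_years=age, q_f_mm=q_f,
        q_c_mm=q_c, p_mm=p, pet_mm=pet, forest_cover_pct=cover, **kw
    )


def response_frame(cid, ages, q, p_t=None, pet_t=None, q_c=500.0, years=None):
    """Minimal responses frame for catchment-level model fitting."""
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    p_t = np.zeros(n) if p_t is None else np.asarray(p_t, dtype=float)
    pet_t = np.zeros(n) if pet_t is None else np.asarray(pet_t, dtype=float)
    q = np.asarray(q, dtype=float)
    years = np.arange(1990, 1990 + n) if years is None else np.asarray(years)
    return pd.DataFrame(
        {
            "catchment_id": cid,
            "hydro_year": years,
            "age_years": ages,
            "q_f_mm": q_c + q,
            "q_c_mm": q_c,
            "p_mm": 1000.0 + p_t,
            "pet_mm": 900.0 + pet_t,
            "forest_cover_pct": 50.0,
            "q_mm": q,
            "p_t_mm": p_t,
            "pet_t_mm": pet_t,
            "fc_t_pct": np.zeros(n),
            "q_c_source": "measured",
            "zero_forested_flow": (q_c + q) == 0.0,
        }
    )


def iid_structure(sigma=45.0, sds=None):
    rs0 = default_random_structure()
    return RandomStructure(
        sds=rs0.sds if sds is None else np.asarray(sds, dtype=float),
        corr=np.eye(4) if sds is not None else rs0.corr,
        phi=np.zeros(3),
        sigma=sigma,
    )


@pytest.fixture
def small_panel():
    """A deterministic small synthetic panel with its metadata and truth."""
    from forestflow.synthetic import simulate_covariates, simulate_panel

    cfg = GeneratorConfig(seed=101, n_catchments=10, years_per_catchment=12)
    metas = simulate_covariates(cfg)
    panel, truth = simulate_panel(cfg, metas)
    return cfg, metas, panel, truth
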