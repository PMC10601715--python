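import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_records():
    """A handful of hand-written observations covering the moderator space."""
    from plastmeta.records import ModeratorSet, ObservationRecord

    def rec(study, param, mc, mt, sc, st, nc=4, nt=4, **mods):
        return ObservationRecord(
            study_id=study,
            parameter_name=param,
            mean_control=mc,
            mean_treatment=mt,
            sd_control=sc,
            sd_treatment=st,
            n_control=nc,
            n_treatment=nt,
            moderators=ModeratorSet(**mods),
        )

    return [
        rec("s1", "shannon", 5.0, 5.5, 0.5, 0.6, plastic_type="PE",
            amount_g_per_kg=5.0, size_um=100.0, incubation_days=30.0,
            ecosystem="cropland", microbial_group="bacteria"),
        rec("s1", "biomass", 10.0, 8.0, 1.0, 1.2, plastic_type="PS",
            amount_g_per_kg=20.0, size_um=0.5, incubation_days=7.0,
            ecosystem="bare", microbial_group="fungi"),
        rec("s2", "chao1", 120.0, 110.0, 12.0, None, plastic_type="PLA",
            amount_g_per_kg=10.0, size_um=6000.0, incubation_days=90.0,
            ecosystem="grassland", microbial_group="bacteria"),
        rec("s2", "soil_respiration", 2.0, 2.4, 0.2, 0.3, plastic_type="PET",
            amount_g_per_kg=1.0, size_um=30000.0, incubation_days=365.0,
            ecosystem="forest", microbial_group="whole community"),
    ]
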