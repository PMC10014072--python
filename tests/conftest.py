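import numpy as np
import pytest

import astermodel as am

# Benchmark aster: motor-enriched (inner occupancy ρ/Kd = 4), 2×background
# crossing placed at 85 μm, MT-depleted zone beyond 100 μm.
BENCH_KD = 0.5
BENCH_LAMBDA0 = 20.0
BENCH_C = 1.0
OUTER_TARGET = 85.0


@pytest.fixture(scope="session")
def mt_profile():
    spec = am.MtProfileSpec(
        family="exponential",
        amplitude=2.0,
        background=0.1,
        outer_radius_target=OUTER_TARGET,
        depletion_r=100.0,
    )
    return am.make_mt_profile(spec, bin_width=0.65, r_max=200.0)


@pytest.fixture(scope="session")
def mt_signal(mt_profile):
    """Background-subtracted MT concentration, the model's ρMT(r)."""
    return am.RadialProfile(mt_profile.r_centers, mt_profile.values - mt_profile.background)


@pytest.fixture(scope="session")
def bench_params():
    return am.ModelParams(Kd=BENCH_KD, lambda0=BENCH_LAMBDA0, C=BENCH_C)


@pytest.fixture(scope="session")
def clean_image_pair(mt_profile, bench_params):
    """Noiseless symmetric rendering of the benchmark aster."""
    return am.make_aster_image_pair(
        mt_profile, bench_params, pixel_size=0.65, image_size=384,
        noise=am.NoiseSpec(sd_fraction=0.0),
    )


@pytest.fixture(scope="session")
def profile_families(mt_signal):
    """Three decaying MT families for oracle sweeps, background-free."""
    out = {"exponential": mt_signal}
    for family in ("logistic_decay", "shoulder_plus_decay"):
        spec = am.MtProfileSpec(
            family=family, amplitude=2.0, background=0.1,
            decay_scale=12.0, inflection_r=45.0, depletion_r=100.0,
        )
        p = am.make_mt_profile(spec, bin_width=0.65, r_max=200.0)
        out[family] = am.RadialProfile(p.r_centers, p.values - p.background)
    return out
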