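import numpy as np
import pytest

from rge import SimConfig, TraitSpec, simulate_sibling_cohort


def null_config(**kw) -> SimConfig:
    """A no-rGE configuration: no sorting, no region or nurture effects."""
    base = dict(
        n_families=2000, n_regions=16, n_snps=120, ld_block_size=1, ld_block_r=0.0,
        h2_direct=0.3, w_passive=0.0, w_active=0.0, var_region=0.0,
        var_family=0.2, delta_nurture=0.0, pgs_noise=0.3, seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


def rge_config(**kw) -> SimConfig:
    """A configuration with all rGE channels switched on."""
    base = dict(
        n_families=2000, n_regions=16, n_snps=200, ld_block_size=10,
        ld_block_r=(0.0, 0.8), h2_direct=0.3, w_passive=0.6, w_active=0.6,
        var_region=0.25, var_family=0.1, delta_nurture=0.1, seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


ONE_TRAIT = [TraitSpec("t", h2=0.3, effect_corr=1.0, region_load=0.0, family_var=0.2)]


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size cohort with rGE on, shared across read-only tests."""
    cfg = rge_config(seed=42)
    cohort, layout, extras = simulate_sibling_cohort(cfg)
    return cfg, cohort, layout, extras


@pytest.fixture(scope="session")
def null_cohort():
    cfg = null_config(seed=7)
    cohort, layout, extras = simulate_sibling_cohort(cfg)
    return cfg, cohort, layout, extras
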