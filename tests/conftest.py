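import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from ebmorph.synthetic import (CohortSpec, SectionSpec, StackSpec,
                               gen_diameter_cohort, gen_marker_section,
                               gen_nuclei_stack)


@pytest.fixture(scope="session")
def small_stack():
    """Compact uniform-mode stack with exact planted ground truth."""
    spec = StackSpec(eb_radius_um=80.0, n_nuclei=60, labeled_fraction=0.3,
                     nucleus_area_range_um2=(40.0, 120.0), pixel_size_um=1.0,
                     n_planes=3, seed=11)
    return gen_nuclei_stack(spec)


@pytest.fixture(scope="session")
def archetype_section():
    """Noiseless concentric section: cavity 0.4, Epi-l shell, 30 µm ExEn ring."""
    spec = SectionSpec(total_diameter_um=500.0, cavity_diameter_um=200.0,
                       exen_thickness_um=30.0, boundary_jitter_px=0.0,
                       noise_sd=0.0, seed=0)
    return gen_marker_section(spec)


@pytest.fixture(scope="session")
def two_stage_cohort():
    spec = CohortSpec(stages=(("EB1", 250.0, 0.03), ("EB10", 602.5, 0.03)),
                      n_per_stage=24, seed=5)
    return gen_diameter_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
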