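import numpy as np
import pytest

from hfire_bench.geometry import NeedlePairGeometry, PlateGeometry
from hfire_bench.synth import TissueParams
from hfire_bench.waveforms import BurstProtocol


@pytest.fixture
def plate() -> PlateGeometry:
    """6 mm thick, 6 mm diameter tissue cylinder between flat plates."""
    return PlateGeometry(thickness_m=0.006, diameter_m=0.006)


@pytest.fixture
def needles_1cm() -> NeedlePairGeometry:
    """1 mm diameter monopolar probes, 1 cm spacing, 1 cm exposure."""
    return NeedlePairGeometry(center_spacing_m=0.010, electrode_radius_m=0.0005, exposure_m=0.010)


@pytest.fixture
def potato() -> TissueParams:
    """Tuber tissue preset: per-pulse-width bulk and plateau conductivities."""
    return TissueParams(
        sigma_bulk_by_pw={1.0: 0.13, 10.0: 0.04},
        sigma_max_by_pw={1.0: 0.55, 10.0: 0.67},
    )


@pytest.fixture
def potato_quiet(potato) -> TissueParams:
    """Noiseless, transient-free variant for closed-form comparisons."""
    from dataclasses import replace

    return replace(potato, noise_rel=0.0, cap_transient_frac=0.0)


@pytest.fixture
def proto_2525() -> BurstProtocol:
    return BurstProtocol.from_label("2-5-2-5", cycles=2)
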