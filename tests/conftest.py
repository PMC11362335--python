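import numpy as np
import pytest

from caspm import (
    OpticalConfig,
    PURE_WATER_INDEX,
    SEAWATER_INDEX,
    SizeGrid,
    TypeBoundaries,
    build_lookup_table,
    theoretical_curve,
)


@pytest.fixture(scope="session")
def sw_optics() -> OpticalConfig:
    return OpticalConfig(medium_index=SEAWATER_INDEX)


@pytest.fixture(scope="session")
def pw_optics() -> OpticalConfig:
    return OpticalConfig(medium_index=PURE_WATER_INDEX)


@pytest.fixture(scope="session")
def boundaries_sw(sw_optics) -> TypeBoundaries:
    return TypeBoundaries.from_optics(sw_optics)


@pytest.fixture(scope="session")
def lookup_sw(sw_optics):
    """Full-resolution seawater lookup table, shared across the session."""
    return build_lookup_table(sw_optics)


@pytest.fixture(scope="session")
def psl_curve_pw(pw_optics):
    """Dense PSL S curve in pure water (the calibration medium)."""
    from caspm import PSL_REFRACTIVE_INDEX

    return theoretical_curve(PSL_REFRACTIVE_INDEX.real, pw_optics, 0.1, 10.0, 4000)


@pytest.fixture(scope="session")
def grid16() -> SizeGrid:
    return SizeGrid.from_range(0.1, 10.0, 16)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
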