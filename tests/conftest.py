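import pytest

from formstress import ItcProtocol, PlateGeometry


@pytest.fixture
def plate_geometry() -> PlateGeometry:
    """Standard 7-spot tenfold series, 10 uL spots."""
    return PlateGeometry()


@pytest.fixture
def itc_protocol() -> ItcProtocol:
    """Standard titration: 20 injections of 2 uL of 25 mM ligand into
    400 uL of 50 uM protein, first 0.3 uL throw-away."""
    return ItcProtocol()
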