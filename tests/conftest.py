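import pytest

from mapfp import FPConfig, MinHashedAtomPairFingerprint
from mapfp.registry import fixture_registry


@pytest.fixture(scope="session")
def registry():
    return fixture_registry()


@pytest.fixture(scope="session")
def map4c():
    return MinHashedAtomPairFingerprint("map4c").fit()


@pytest.fixture(scope="session")
def map4c_config():
    return FPConfig.from_variant("map4c")


# Published stereoisomer totals (enumeration + canonical deduplication)
TABLE1_TOTALS = {
    "alpha-d-glucopyranose": 32,
    "lactose": 1024,
    "trehalose": 528,
    "validamycin-a": 16384,
    "inositol": 9,
    "ln65": 2048,
    "nona-arginine": 512,
    "polymyxin-b2": 4096,
    "quinaldopeptin": 136,
    "onchidin": 2080,
    "gramicidin-s": 528,
    "valinomycin": 1376,
    "nonactin": 16456,
    "np213": 20,
}

# Published stereocenter counts (column N)
TABLE1_CENTERS = {
    "alpha-d-glucopyranose": 5,
    "lactose": 10,
    "trehalose": 10,
    "validamycin-a": 14,
    "inositol": 6,
    "ln65": 11,
    "nona-arginine": 9,
    "polymyxin-b2": 12,
    "quinaldopeptin": 8,
    "onchidin": 12,
    "gramicidin-s": 10,
    "valinomycin": 12,
    "nonactin": 16,
    "np213": 7,
}
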