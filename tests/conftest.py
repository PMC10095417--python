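import pytest

from lanthimine import variants
from lanthimine.digest import build_inclusion_list
from lanthimine.io_formats import make_peaklist


@pytest.fixture(scope="session")
def nisin_s():
    return variants.NISIN_S


@pytest.fixture(scope="session")
def nisin_a():
    return variants.NISIN_A


@pytest.fixture(scope="session")
def nisin_f():
    return variants.NISIN_F


@pytest.fixture(scope="session")
def panel():
    return variants.reference_panel()


@pytest.fixture(scope="session")
def nisin_s_targets(nisin_s):
    """Default inclusion list (z 2-4, CAM fixed, <=2 Ox) for the nisin S core."""
    return build_inclusion_list(nisin_s)


@pytest.fixture()
def observed_fragment_peaks():
    """The detected m/z values reported for the tryptic fragments, including
    the one irreproducible low value (339.30) acting as a decoy."""
    return make_peaklist(
        [(693.82, 1.0), (535.24, 1.0), (543.24, 1.0), (551.24, 1.0), (339.30, 1.0)],
        "mz",
    )


@pytest.fixture()
def observed_intact_peaks():
    return make_peaklist([(3347.15, 1.0)], "neutral_mass")
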