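import numpy as np
import pytest

from filaweaver import (
    SyntheticDNASpec,
    SyntheticFilamentSpec,
    make_dna,
    make_filament,
    make_site_template,
    thread_strand,
)

Z = np.array([0.0, 0.0, 1.0])


@pytest.fixture(scope="session")
def regular_filament():
    fil, screw, kink = make_filament(SyntheticFilamentSpec())
    return fil, screw


@pytest.fixture(scope="session")
def kinked_filament():
    spec = SyntheticFilamentSpec(kink_after=5, kink_deg=20.5)
    fil, screw, kink = make_filament(spec)
    return fil, screw, kink


@pytest.fixture(scope="session")
def site_template():
    return make_site_template()


@pytest.fixture(scope="session")
def threaded_strand(regular_filament, site_template):
    fil, _ = regular_filament
    return thread_strand(fil, site_template, "I_incoming")


@pytest.fixture(scope="session")
def bdna_strand():
    return make_dna(SyntheticDNASpec(n=12))


@pytest.fixture(scope="session")
def bdna_duplex():
    return make_dna(SyntheticDNASpec(n=12, duplex=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    from filaweaver import RigidTransform

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return RigidTransform(R, t)
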